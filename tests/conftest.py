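import numpy as np
import pytest

from mutmapkit.simcross import SimConfig, simulate_cross
from mutmapkit.vcfio import SampleCounts, SampleRoles, VariantRecord

ROLES = SampleRoles(
    parent_wt="parent_wt",
    mutant_line="mutant_line",
    f2_mut_pool="f2_mut_pool",
    f2_wt_pool="f2_wt_pool",
)

#: small genome for fast unit-level simulations
SMALL_CONFIG = SimConfig(
    chrom_lengths=(("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000)),
    n_ems_snps=150,
    causal_locus=("chr2", 5_000_000),
    het_blocks=(("chr1", 2_000_001, 4_000_000, 50.0),),
    seed=7,
)


@pytest.fixture
def roles() -> SampleRoles:
    return ROLES


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated cross shared across unit tests."""
    return simulate_cross(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_sim():
    """One full default-condition simulated cross."""
    return simulate_cross(SimConfig(seed=1))


def make_record(
    chrom="chr1",
    pos=100,
    qual=800.0,
    af_parent=0.0,
    af_mutant=1.0,
    af_f2mut=0.9,
    af_f2wt=0.5,
    depth=20,
    ref="G",
    alt="A",
) -> VariantRecord:
    """Build a four-sample record realizing the requested allele frequencies."""

    def counts(af: float) -> SampleCounts:
        alt_c = round(af * depth)
        return SampleCounts(depth - alt_c, alt_c, depth)

    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        samples={
            ROLES.parent_wt: counts(af_parent),
            ROLES.mutant_line: counts(af_mutant),
            ROLES.f2_mut_pool: counts(af_f2mut),
            ROLES.f2_wt_pool: counts(af_f2wt),
        },
    )


def random_records(rng: np.random.Generator, n: int) -> list[VariantRecord]:
    """Records spanning the filter's decision boundaries."""
    records = []
    pos = 0
    for _ in range(n):
        pos += int(rng.integers(1, 50_000))
        depth = int(rng.integers(0, 40))
        quals = float(rng.choice([100.0, 499.9, 500.0, 800.0, 2000.0]))
        afs = rng.choice([0.0, 0.1, 0.25, 0.5, 0.75, 0.8, 0.95, 1.0], size=4)
        records.append(
            make_record(
                pos=pos, qual=quals, af_parent=afs[0], af_mutant=afs[1],
                af_f2mut=afs[2], af_f2wt=afs[3],
                depth=depth if depth > 0 else 0,
            )
            if depth > 0
            else make_record(pos=pos, qual=quals, depth=0)
        )
    return records
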