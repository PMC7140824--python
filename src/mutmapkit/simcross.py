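"""Forward simulation of the EMS mapping cross.

The simulated pedigree: an EMS-mutagenized line carrying a recessive causal
allele is crossed to a sibling stock of the same inbred background, F1 plants
are selfed, and two phenotype-selected F2 pools (mutant and wild-type) are
sequenced together with the unmutagenized parent individual and the mutant
line itself.  Markers are the EMS-induced SNPs fixed in the mutant line plus
dense residual-heterozygosity blocks; both ride the mutant-line haplotype
through meiosis, so the mutant pool's alternate allele frequency at a marker
with recombination fraction r to the causal locus is 1 - r, and ~0.5 on
unlinked chromosomes.

Meiosis uses a Poisson crossover model without interference: the per-gamete
crossover count on a chromosome of physical length L Mb is
Poisson(L * cm_per_mb / 100), with uniformly placed breakpoints, i.e. the
Haldane map.  Read sampling is Poisson depth with binomial allele counts
perturbed by a per-base error rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .vcfio import DepthTrack, SampleCounts, SampleRoles, VariantRecord, write_vcf

log = logging.getLogger(__name__)

DEFAULT_CHROMS: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 30_000_000) for i in range(1, 11)
)
#: 2 Mb residual-heterozygosity blocks on five chromosomes, ~25x denser than
#: the genome-wide EMS background.
DEFAULT_HET_BLOCKS: tuple[tuple[str, int, int, float], ...] = (
    ("chr1", 5_000_001, 7_000_000, 100.0),
    ("chr2", 12_000_001, 14_000_000, 100.0),
    ("chr3", 20_000_001, 22_000_000, 100.0),
    ("chr5", 8_000_001, 10_000_000, 100.0),
    ("chr6", 15_000_001, 17_000_000, 100.0),
)

EMS_TRANSITIONS = (("G", "A"), ("C", "T"))
OTHER_SUBS = tuple(
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and (r, a) not in EMS_TRANSITIONS
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cross.

    Defaults mirror the study conditions: ten chromosomes, ~1200 EMS SNPs
    fixed in the mutant line, a recessive causal locus near the top of
    chromosome 4, pools of 72 mutant / 69 wild-type F2 plants, ~21x mean
    coverage.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = DEFAULT_CHROMS
    n_ems_snps: int = 1200
    ems_gc_to_at_fraction: float = 0.9
    #: None simulates the null condition: no causal locus, phenotype assigned
    #: independently of genotype with probability 1/4
    causal_locus: tuple[str, int] | None = ("chr4", 8_000_000)
    het_blocks: tuple[tuple[str, int, int, float], ...] = DEFAULT_HET_BLOCKS
    n_f2_mut: int = 72
    n_f2_wt: int = 69
    mean_coverage: float = 21.0
    seq_error: float = 0.001
    cm_per_mb: float = 0.5
    qual_mean: float = 1500.0
    qual_sd: float = 487.0
    emit_causal_site: bool = True
    seed: int = 0

    def validate(self) -> None:
        lengths = dict(self.chrom_lengths)
        if not lengths:
            raise ValueError("at least one chromosome required")
        for n, label in [
            (self.n_ems_snps, "n_ems_snps"),
            (self.n_f2_mut, "n_f2_mut"),
            (self.n_f2_wt, "n_f2_wt"),
        ]:
            if n <= 0:
                raise ValueError(f"{label} must be > 0")
        for frac, label in [
            (self.ems_gc_to_at_fraction, "ems_gc_to_at_fraction"),
            (self.seq_error, "seq_error"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.mean_coverage <= 0 or self.cm_per_mb <= 0:
            raise ValueError("mean_coverage and cm_per_mb must be > 0")
        if self.causal_locus is not None:
            cchrom, cpos = self.causal_locus
            if cchrom not in lengths or not 1 <= cpos <= lengths[cchrom]:
                raise ValueError(f"causal locus {cchrom}:{cpos} outside chromosome bounds")
        for chrom, start, end, density in self.het_blocks:
            if chrom not in lengths:
                raise ValueError(f"het block on unknown chromosome {chrom}")
            if not 1 <= start <= end <= lengths[chrom]:
                raise ValueError(f"het block {chrom}:{start}-{end} outside chromosome")
            if density < 0:
                raise ValueError("het block density must be >= 0")


@dataclass
class SiteTruth:
    chrom: str
    pos: int
    category: str  # "ems" | "het_block" | "causal"
    expected_af_f2mut: float
    realized_af_f2mut: float
    realized_af_f2wt: float


@dataclass
class SimTruth:
    """Ground truth for one simulated cross — the oracle for recovery tests."""

    sites: list[SiteTruth]
    causal_locus: tuple[str, int]
    n_f2_simulated: int
    n_mutant_phenotype: int

    def by_category(self, category: str) -> list[SiteTruth]:
        return [s for s in self.sites if s.category == category]


@dataclass
class SimOutput:
    vcf_path: Path | None
    truth_path: Path | None
    phenotype_path: Path | None
    records: list[VariantRecord]
    truth: SimTruth
    roles: SampleRoles
    config: SimConfig


def haldane_r(distance_bp: float, cm_per_mb: float) -> float:
    """Recombination fraction from physical distance under the Haldane map."""
    d_morgan = abs(distance_bp) / 1e6 * cm_per_mb / 100.0
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgan))


def _draw_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Positions, categories and alleles of all marker sites."""
    lengths = dict(cfg.chrom_lengths)
    total_len = sum(lengths.values())
    rows: list[tuple[str, int, str]] = []

    # EMS sites uniform over the genome, proportional to chromosome length
    n_per_chrom = rng.multinomial(
        cfg.n_ems_snps, [l / total_len for _, l in cfg.chrom_lengths]
    )
    for (chrom, length), n in zip(cfg.chrom_lengths, n_per_chrom):
        pos = rng.choice(length, size=min(n, length), replace=False) + 1
        rows.extend((chrom, int(p), "ems") for p in pos)

    for chrom, start, end, density in cfg.het_blocks:
        n = rng.poisson(density * (end - start + 1) / 1e6)
        pos = rng.integers(start, end + 1, size=n)
        rows.extend((chrom, int(p), "het_block") for p in np.unique(pos))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "category"])
    if cfg.causal_locus is not None:
        cchrom, cpos = cfg.causal_locus
        df = df[~((df.chrom == cchrom) & (df.pos == cpos))]
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    if cfg.emit_causal_site and cfg.causal_locus is not None:
        df = pd.concat(
            [df, pd.DataFrame([(cchrom, cpos, "causal")], columns=df.columns)],
            ignore_index=True,
        )

    # alleles: EMS spectrum is dominated by G:C -> A:T transitions
    n_sites = len(df)
    refs = np.empty(n_sites, dtype="<U1")
    alts = np.empty(n_sites, dtype="<U1")
    is_transition = rng.random(n_sites) < cfg.ems_gc_to_at_fraction
    pick_gc = rng.integers(0, 2, size=n_sites)
    pick_other = rng.integers(0, len(OTHER_SUBS), size=n_sites)
    for i, (trans, gc, oth) in enumerate(zip(is_transition, pick_gc, pick_other)):
        refs[i], alts[i] = EMS_TRANSITIONS[gc] if trans else OTHER_SUBS[oth]
    df["ref"], df["alt"] = refs, alts

    order = {name: i for i, (name, _) in enumerate(cfg.chrom_lengths)}
    df["corder"] = df["chrom"].map(order)
    df = df.sort_values(["corder", "pos"]).drop(columns="corder").reset_index(drop=True)
    return df


def _gamete_ancestry(
    positions: np.ndarray, length: int, morgans: float, rng: np.random.Generator
) -> np.ndarray:
    """Mutant-line (1) / crossing-parent (0) ancestry of one gamete at ``positions``."""
    n_xo = rng.poisson(morgans)
    phase = rng.integers(0, 2)
    if n_xo == 0:
        return np.full(len(positions), phase, dtype=np.int8)
    breaks = np.sort(rng.integers(1, length + 1, size=n_xo))
    crossings = np.searchsorted(breaks, positions, side="left")
    return ((phase + crossings) % 2).astype(np.int8)


def _simulate_f2_pools(
    cfg: SimConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Draw phenotype-selected pools; returns per-site alt-haplotype counts.

    Returns (mut_pool_counts, wt_pool_counts, n_simulated, n_mutant_phenotype);
    counts are out of 2*pool_size haplotypes.
    """
    lengths = dict(cfg.chrom_lengths)
    cchrom, cpos = cfg.causal_locus if cfg.causal_locus is not None else (None, -1)
    by_chrom: dict[str, np.ndarray] = {}
    site_index: dict[str, np.ndarray] = {}
    for chrom in lengths:
        mask = (sites["chrom"] == chrom).to_numpy()
        site_index[chrom] = np.flatnonzero(mask)
        by_chrom[chrom] = sites.loc[mask, "pos"].to_numpy()

    n_sites = len(sites)
    mut_counts = np.zeros(n_sites, dtype=np.int64)
    wt_counts = np.zeros(n_sites, dtype=np.int64)
    need_mut, need_wt = cfg.n_f2_mut, cfg.n_f2_wt
    n_sim = n_mut_pheno = 0

    while need_mut > 0 or need_wt > 0:
        n_sim += 1
        dosage = np.zeros(n_sites, dtype=np.int8)
        causal_dosage = 0
        for chrom, length in lengths.items():
            positions = by_chrom[chrom]
            morgans = length / 1e6 * cfg.cm_per_mb / 100.0
            # causal genotype needs ancestry at cpos even if absent from sites
            query = positions if chrom != cchrom else np.append(positions, cpos)
            g1 = _gamete_ancestry(query, length, morgans, rng)
            g2 = _gamete_ancestry(query, length, morgans, rng)
            if chrom == cchrom:
                causal_dosage = int(g1[-1] + g2[-1])
                g1, g2 = g1[:-1], g2[:-1]
            dosage[site_index[chrom]] = g1 + g2
        if cfg.causal_locus is None:
            is_mutant = rng.random() < 0.25  # phenocopy-only null condition
        else:
            is_mutant = causal_dosage == 2
        if is_mutant:
            n_mut_pheno += 1
            if need_mut > 0:
                mut_counts += dosage
                need_mut -= 1
        elif need_wt > 0:
            wt_counts += dosage
            need_wt -= 1
    return mut_counts, wt_counts, n_sim, n_mut_pheno


def _sample_reads(
    freq: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth and binomial alt counts at observed allele frequency."""
    depth = rng.poisson(cfg.mean_coverage, size=len(freq))
    p = freq * (1.0 - cfg.seq_error) + (1.0 - freq) * cfg.seq_error
    alt = rng.binomial(depth, p)
    return depth, alt


def simulate_cross(
    cfg: SimConfig,
    outdir: str | Path | None = None,
    roles: SampleRoles | None = None,
) -> SimOutput:
    """Simulate the four-sample sequencing experiment.

    When ``outdir`` is given, writes ``sim.vcf`` (four samples), ``truth.tsv``
    and ``phenotypes.tsv`` there; identical configs and seeds give identical
    bytes.  The in-memory records and truth are returned either way.
    """
    cfg.validate()
    if roles is None:
        roles = SampleRoles(
            parent_wt="parent_wt",
            mutant_line="mutant_line",
            f2_mut_pool="f2_mut_pool",
            f2_wt_pool="f2_wt_pool",
        )
    rng = np.random.default_rng(cfg.seed)
    sites = _draw_sites(cfg, rng)
    mut_counts, wt_counts, n_sim, n_mut_pheno = _simulate_f2_pools(cfg, sites, rng)

    n_sites = len(sites)
    freq_mut = mut_counts / (2 * cfg.n_f2_mut)
    freq_wt = wt_counts / (2 * cfg.n_f2_wt)
    # sequenced parent individual is homozygous reference at every marker;
    # the mutant line is homozygous alternate (EMS sites, causal site, and
    # het-block alleles all fixed there)
    depth_par, alt_par = _sample_reads(np.zeros(n_sites), cfg, rng)
    depth_ml, alt_ml = _sample_reads(np.ones(n_sites), cfg, rng)
    depth_fm, alt_fm = _sample_reads(freq_mut, cfg, rng)
    depth_fw, alt_fw = _sample_reads(freq_wt, cfg, rng)
    quals = np.clip(rng.normal(cfg.qual_mean, cfg.qual_sd, size=n_sites), 1.0, None)

    cchrom, cpos = cfg.causal_locus if cfg.causal_locus is not None else (None, -1)
    records: list[VariantRecord] = []
    truth_sites: list[SiteTruth] = []
    for i, row in enumerate(sites.itertuples()):
        if row.chrom == cchrom:
            exp_af = 1.0 - haldane_r(row.pos - cpos, cfg.cm_per_mb)
        else:
            exp_af = 0.5
        truth_sites.append(
            SiteTruth(
                chrom=row.chrom,
                pos=row.pos,
                category=row.category,
                expected_af_f2mut=exp_af,
                realized_af_f2mut=float(freq_mut[i]),
                realized_af_f2wt=float(freq_wt[i]),
            )
        )
        records.append(
            VariantRecord(
                chrom=row.chrom,
                pos=row.pos,
                ref=row.ref,
                alt=row.alt,
                qual=round(float(quals[i]), 2),
                samples={
                    roles.parent_wt: SampleCounts(
                        int(depth_par[i] - alt_par[i]), int(alt_par[i]), int(depth_par[i])
                    ),
                    roles.mutant_line: SampleCounts(
                        int(depth_ml[i] - alt_ml[i]), int(alt_ml[i]), int(depth_ml[i])
                    ),
                    roles.f2_mut_pool: SampleCounts(
                        int(depth_fm[i] - alt_fm[i]), int(alt_fm[i]), int(depth_fm[i])
                    ),
                    roles.f2_wt_pool: SampleCounts(
                        int(depth_fw[i] - alt_fw[i]), int(alt_fw[i]), int(depth_fw[i])
                    ),
                },
            )
        )

    truth = SimTruth(
        sites=truth_sites,
        causal_locus=cfg.causal_locus,
        n_f2_simulated=n_sim,
        n_mutant_phenotype=n_mut_pheno,
    )

    vcf_path = truth_path = pheno_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf_path = write_vcf(records, roles.as_tuple(), cfg.chrom_lengths, outdir / "sim.vcf")
        truth_path = outdir / "truth.tsv"
        pd.DataFrame(
            [
                (s.chrom, s.pos, s.category, s.expected_af_f2mut,
                 s.realized_af_f2mut, s.realized_af_f2wt)
                for s in truth_sites
            ],
            columns=["chrom", "pos", "category", "expected_af_f2mut",
                     "realized_af_f2mut", "realized_af_f2wt"],
        ).to_csv(truth_path, sep="\t", index=False)
        pheno_path = outdir / "phenotypes.tsv"
        pd.DataFrame(
            {
                "statistic": ["n_f2_simulated", "n_mutant_phenotype"],
                "value": [n_sim, n_mut_pheno],
            }
        ).to_csv(pheno_path, sep="\t", index=False)

    return SimOutput(
        vcf_path=vcf_path,
        truth_path=truth_path,
        phenotype_path=pheno_path,
        records=records,
        truth=truth,
        roles=roles,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Depth tracks and deletion planting


def simulate_depth_tracks(
    cfg: SimConfig,
    chrom: str,
    start: int,
    end: int,
    roles: SampleRoles | None = None,
    seed: int | None = None,
) -> dict[str, DepthTrack]:
    """Per-base Poisson depth tracks over [start, end] for the four roles.

    Keys are role names (``parent_wt`` etc.), matching what the deletion
    scanner expects.
    """
    lengths = dict(cfg.chrom_lengths)
    if chrom not in lengths or not 1 <= start <= end <= lengths[chrom]:
        raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome bounds")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = end - start + 1
    role_names = ["parent_wt", "mutant_line", "f2_mut_pool", "f2_wt_pool"]
    samples = roles.as_tuple() if roles is not None else role_names
    return {
        role: DepthTrack(
            sample=sample, chrom=chrom, start=start,
            depths=rng.poisson(cfg.mean_coverage, size=n),
        )
        for role, sample in zip(role_names, samples)
    }


def plant_deletion(
    tracks: dict[str, DepthTrack],
    chrom: str,
    start: int,
    end: int,
    seed: int = 0,
    residual_rate: float = 0.05,
) -> dict[str, DepthTrack]:
    """Superimpose a mutant-specific homozygous deletion on depth tracks.

    The mutant line and the mutant F2 pool drop to near-zero depth over the
    interval (a small residual models mismapped reads); the wild-type pool is
    thinned to 2/3 of its depth (under a recessive model its plants are 1/3
    homozygous wild type and 2/3 heterozygous carriers, so 2/3 of its
    chromosomes remain); the parent is untouched.
    """
    if start > end or start < 1:
        raise ValueError(f"invalid deletion interval {chrom}:{start}-{end}")
    if not any(t.chrom == chrom and t.covers(start, end) for t in tracks.values()):
        raise ValueError(
            f"deletion interval {chrom}:{start}-{end} not covered by any depth track"
        )
    rng = np.random.default_rng(seed)
    out: dict[str, DepthTrack] = {}
    for role, track in tracks.items():
        depths = track.depths.copy()
        if track.chrom == chrom and track.start <= end and start <= track.end:
            lo = max(start, track.start) - track.start
            hi = min(end, track.end) - track.start + 1
            if role in ("mutant_line", "f2_mut_pool"):
                depths[lo:hi] = rng.poisson(residual_rate, size=hi - lo)
            elif role == "f2_wt_pool":
                depths[lo:hi] = rng.binomial(depths[lo:hi], 2.0 / 3.0)
        out[role] = DepthTrack(
            sample=track.sample, chrom=track.chrom, start=track.start, depths=depths
        )
    return out
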