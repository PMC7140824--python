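import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mutmapkit.simcross import (SimConfig, haldane_r, plant_deletion, simulate_cross,
                                simulate_depth_tracks)

from .conftest import SMALL_CONFIG


def two_locus_selected_frequency(r: float) -> float:
    """Enumeration oracle: marker allele frequency in the selected mutant pool.

    Enumerates the 4x4 combinations of F1 gametes at (causal, marker) loci.
    Gamete haplotypes and probabilities: MM and ++ parental types at (1-r)/2,
    M+ and +M recombinants at r/2 each (M = mutant-line allele).  Conditioning
    on plants homozygous for the causal M allele, returns the expected
    frequency of the marker M allele among their chromosomes.
    """
    gametes = [
        ((1, 1), (1 - r) / 2),  # causal M, marker M
        ((1, 0), r / 2),
        ((0, 1), r / 2),
        ((0, 0), (1 - r) / 2),
    ]
    num = den = 0.0
    for (c1, m1), p1 in gametes:
        for (c2, m2), p2 in gametes:
            if c1 == 1 and c2 == 1:  # selected: homozygous mutant at causal locus
                num += p1 * p2 * (m1 + m2) / 2.0
                den += p1 * p2
    return num / den


class TestEnumerationOracle:
    @pytest.mark.parametrize("r", [0.0, 0.1, 0.25])
    def test_selected_pool_frequency_is_one_minus_r(self, r):
        assert two_locus_selected_frequency(r) == pytest.approx(1.0 - r, abs=1e-12)


class TestDeterminism:
    def test_identical_seed_gives_identical_bytes(self, tmp_path):
        cfg = replace(SMALL_CONFIG, seed=11)
        out1 = simulate_cross(cfg, outdir=tmp_path / "a")
        out2 = simulate_cross(cfg, outdir=tmp_path / "b")
        assert out1.vcf_path.read_bytes() == out2.vcf_path.read_bytes()
        assert out1.truth_path.read_bytes() == out2.truth_path.read_bytes()
        assert out1.phenotype_path.read_bytes() == out2.phenotype_path.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        out1 = simulate_cross(replace(SMALL_CONFIG, seed=1), outdir=tmp_path / "a")
        out2 = simulate_cross(replace(SMALL_CONFIG, seed=2), outdir=tmp_path / "b")
        assert out1.vcf_path.read_bytes() != out2.vcf_path.read_bytes()


class TestSiteAccounting:
    def test_every_site_in_exactly_one_category(self, small_sim):
        cats = {}
        for s in small_sim.truth.sites:
            key = (s.chrom, s.pos)
            assert key not in cats, "site in more than one truth category"
            cats[key] = s.category
        vcf_sites = {(r.chrom, r.pos) for r in small_sim.records}
        assert vcf_sites == set(cats)
        n_cat = sum(
            len(small_sim.truth.by_category(c)) for c in ("ems", "het_block", "causal")
        )
        assert n_cat == len(small_sim.records)
        assert len(small_sim.truth.by_category("causal")) == 1

    def test_records_sorted_by_genome_order(self, small_sim):
        order = {name: i for i, (name, _) in enumerate(SMALL_CONFIG.chrom_lengths)}
        keys = [(order[r.chrom], r.pos) for r in small_sim.records]
        assert keys == sorted(keys)


@pytest.fixture(scope="module")
def clean_sim():
    """Noise-free reads isolate the genotype construction."""
    return simulate_cross(replace(SMALL_CONFIG, seq_error=0.0, seed=3))


class TestGenotypes:
    def test_parent_reference_mutant_line_alternate(self, clean_sim, roles):
        for rec in clean_sim.records:
            assert rec.samples[roles.parent_wt].alt_count == 0
            assert rec.samples[roles.mutant_line].ref_count == 0

    def test_causal_marker_fully_alternate_in_mutant_pool(self, clean_sim):
        (causal,) = clean_sim.truth.by_category("causal")
        assert causal.expected_af_f2mut == 1.0
        assert causal.realized_af_f2mut == 1.0

    def test_unlinked_marker_mean_frequency_half(self):
        """Across seeds, unlinked-marker mutant-pool frequency centers on 0.5."""
        afs = []
        for seed in range(20):
            out = simulate_cross(replace(SMALL_CONFIG, seed=100 + seed))
            afs.extend(
                s.realized_af_f2mut
                for s in out.truth.sites
                if s.chrom != out.config.causal_locus[0]
            )
        afs = np.asarray(afs)
        # haplotype draws within a pool are correlated; bound SE by treating
        # each 144-haplotype pool mean as one binomial observation per site
        se = math.sqrt(0.25 / (2 * 72)) / math.sqrt(len(afs))
        assert abs(afs.mean() - 0.5) < 3 * se * math.sqrt(20)  # conservative factor

    def test_mutant_phenotype_fraction_consistent_with_one_quarter(self):
        n_mut = n_tot = 0
        for seed in range(10):
            out = simulate_cross(replace(SMALL_CONFIG, seed=200 + seed))
            n_mut += out.truth.n_mutant_phenotype
            n_tot += out.truth.n_f2_simulated
        ci_lo, ci_hi = stats.binom.interval(0.999, n_tot, 0.25)
        assert ci_lo <= n_mut <= ci_hi

    def test_read_noise_calibrated_to_binomial(self, small_sim, roles):
        """~95% of sites fall inside 95% binomial intervals around pool truth."""
        inside = total = 0
        for rec, s in zip(small_sim.records, small_sim.truth.sites):
            counts = rec.samples[roles.f2_mut_pool]
            depth = counts.ref_count + counts.alt_count
            if depth == 0:
                continue
            p = s.realized_af_f2mut * (1 - 0.001) + (1 - s.realized_af_f2mut) * 0.001
            lo, hi = stats.binom.interval(0.95, depth, p)
            total += 1
            inside += lo <= counts.alt_count <= hi
        assert total > 100
        assert 0.90 <= inside / total <= 1.0


def marker_position_for_r(causal_pos: int, r: float, cm_per_mb: float) -> int:
    """Invert the Haldane map: physical offset producing recombination fraction r."""
    d_morgan = -0.5 * math.log(1.0 - 2.0 * r) if r > 0 else 0.0
    return causal_pos + int(round(d_morgan * 100.0 / cm_per_mb * 1e6))


def linked_marker_frequencies(
    r_values=(0.0, 0.1, 0.25), n_seeds=20, seed0=300, probe_halfwidth=200_000
):
    """Mean realized mutant-pool frequency of markers near each target r.

    One 30 Mb chromosome at 2 cM/Mb (so r = 0.25 fits), dense EMS markers,
    noise-free reads; markers within ``probe_halfwidth`` of the exact target
    position are averaged across seeds.
    """
    cm_per_mb = 2.0
    causal = 2_000_000
    cfg = SimConfig(
        chrom_lengths=(("chrA", 30_000_000),),
        n_ems_snps=600,
        causal_locus=("chrA", causal),
        het_blocks=(),
        cm_per_mb=cm_per_mb,
        seq_error=0.0,
        emit_causal_site=True,
    )
    targets = {r: marker_position_for_r(causal, r, cm_per_mb) for r in r_values}
    sums = {r: [] for r in r_values}
    for seed in range(n_seeds):
        out = simulate_cross(replace(cfg, seed=seed0 + seed))
        for s in out.truth.sites:
            for r, pos in targets.items():
                if abs(s.pos - pos) <= probe_halfwidth:
                    sums[r].append(s.realized_af_f2mut)
    return {r: float(np.mean(v)) for r, v in sums.items()}


class TestLinkedMarkerLaw:
    def test_pool_frequency_tracks_one_minus_r(self):
        """Simulated mutant-pool frequency at r in {0, 0.1, 0.25} matches the
        1 - r law established by the two-locus enumeration oracle."""
        means = linked_marker_frequencies()
        for r, mean in means.items():
            expected = two_locus_selected_frequency(r)
            # markers within a seed share meioses, so the effective sample
            # size is the number of seeds; allow 4 SE plus bin width
            se = math.sqrt(max(r * (1 - r), 1 / 144) / 144 / 20)
            assert mean == pytest.approx(expected, abs=max(4 * se, 0.015)), (
                f"r={r}: mean {mean:.4f} vs expected {expected:.4f}"
            )


class TestDepthTracksAndDeletion:
    def test_planted_deletion_depth_signature(self):
        cfg = replace(SMALL_CONFIG, seed=5)
        tracks = simulate_depth_tracks(cfg, "chr2", 4_990_000, 5_010_000)
        start, end = 5_000_100, 5_000_475  # 376 bp
        planted = plant_deletion(tracks, "chr2", start, end, seed=5)
        sl = slice(start - 4_990_000, end - 4_990_000 + 1)
        assert planted["mutant_line"].depths[sl].mean() < 1.0
        assert planted["f2_mut_pool"].depths[sl].mean() < 1.0
        # parent untouched, wild-type pool thinned to about 2/3
        assert np.array_equal(planted["parent_wt"].depths, tracks["parent_wt"].depths)
        wt_inside = planted["f2_wt_pool"].depths[sl].mean()
        assert wt_inside == pytest.approx(2 / 3 * cfg.mean_coverage, rel=0.15)
        # flanks untouched in all samples
        for role in planted:
            assert np.array_equal(planted[role].depths[:50], tracks[role].depths[:50])

    def test_deletion_outside_tracks_rejected(self):
        tracks = simulate_depth_tracks(SMALL_CONFIG, "chr2", 1000, 2000)
        with pytest.raises(ValueError):
            plant_deletion(tracks, "chr2", 5_000_000, 5_000_100)

    def test_depth_interval_validation(self):
        with pytest.raises(ValueError):
            simulate_depth_tracks(SMALL_CONFIG, "chr2", 1, 99_000_000)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_ems_snps": 0},
            {"ems_gc_to_at_fraction": 1.5},
            {"causal_locus": ("chr9", 1000)},
            {"causal_locus": ("chr2", 99_000_000)},
            {"het_blocks": (("chr1", 5, 99_000_000, 10.0),)},
            {"mean_coverage": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            replace(SMALL_CONFIG, **kwargs).validate()

    def test_haldane_limits(self):
        assert haldane_r(0, 0.5) == 0.0
        assert haldane_r(1e12, 0.5) == pytest.approx(0.5)
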