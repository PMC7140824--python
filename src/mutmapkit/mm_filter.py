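"""Pooled allele frequencies and the MutMap variant filter.

A marker is informative for mapping when it is fixed alternate in the mutant
line (alternate allele frequency 1), absent from the unmutagenized parent
(frequency 0), and segregating at intermediate frequency (0.25-0.75) in the
wild-type F2 pool; sites below the quality floor are discarded.  "Equal to 1"
and "equal to 0" are read literally as zero opposing reads at finite depth,
with optional tolerance knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .vcfio import SampleRoles, VariantRecord

#: first-failing-clause attribution order for the rejection tally
CLAUSES = ("depth", "qual", "mutant_not_fixed", "parent_has_alt", "f2wt_band")


@dataclass(frozen=True)
class FilterConfig:
    qual_min: float = 500.0
    mutant_fixed_min: float = 1.0
    parent_absent_max: float = 0.0
    f2wt_low: float = 0.25
    f2wt_high: float = 0.75
    min_depth: int = 5

    def validate(self) -> None:
        if not 0.0 <= self.f2wt_low < self.f2wt_high <= 1.0:
            raise ValueError(
                f"require 0 <= f2wt_low < f2wt_high <= 1, got "
                f"[{self.f2wt_low}, {self.f2wt_high}]"
            )
        if self.qual_min < 0:
            raise ValueError("qual_min must be >= 0")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class FilteredVariant:
    """A variant that passed the filter, with its per-role allele frequencies."""

    record: VariantRecord
    af_parent: float
    af_mutant: float
    af_f2mut: float
    af_f2wt: float

    @property
    def chrom(self) -> str:
        return self.record.chrom

    @property
    def pos(self) -> int:
        return self.record.pos


@dataclass
class FilterResult:
    kept: list[FilteredVariant]
    tallies: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.tallies.values())


def allele_frequency(ref_count: int, alt_count: int) -> float | None:
    """Alternate-read fraction; ``None`` when the site has no informative reads."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        return None
    return alt_count / total


def _role_afs(rec: VariantRecord, roles: SampleRoles):
    out = []
    for name in roles.as_tuple():
        counts = rec.samples[name]
        out.append((allele_frequency(counts.ref_count, counts.alt_count),
                    counts.ref_count + counts.alt_count))
    return out  # [(af, informative_depth)] for parent, mutant, f2mut, f2wt


def mutmap_filter(
    variants: Iterable[VariantRecord],
    roles: SampleRoles,
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply the five-clause marker filter.

    Keeps records with qual >= qual_min, mutant-line AF >= mutant_fixed_min,
    parent AF <= parent_absent_max, f2wt_low <= wt-pool AF <= f2wt_high, and
    all four role samples at informative depth >= min_depth (both interval
    boundaries inclusive).  Rejections are tallied under the first failing
    clause in the order depth, qual, mutant, parent, f2wt.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    kept: list[FilteredVariant] = []
    tallies = {c: 0 for c in CLAUSES}
    for rec in variants:
        missing = [name for name in roles.as_tuple() if name not in rec.samples]
        if missing:
            raise KeyError(f"record {rec.chrom}:{rec.pos} lacks role sample(s) {missing}")
        (af_par, d_par), (af_mut, d_mut), (af_fm, d_fm), (af_fw, d_fw) = _role_afs(rec, roles)
        if min(d_par, d_mut, d_fm, d_fw) < cfg.min_depth:
            tallies["depth"] += 1
        elif rec.qual < cfg.qual_min:
            tallies["qual"] += 1
        elif af_mut < cfg.mutant_fixed_min:
            tallies["mutant_not_fixed"] += 1
        elif af_par > cfg.parent_absent_max:
            tallies["parent_has_alt"] += 1
        elif not (cfg.f2wt_low <= af_fw <= cfg.f2wt_high):
            tallies["f2wt_band"] += 1
        else:
            kept.append(
                FilteredVariant(
                    record=rec, af_parent=af_par, af_mutant=af_mut,
                    af_f2mut=af_fm, af_f2wt=af_fw,
                )
            )
    return FilterResult(kept=kept, tallies=tallies)


def filtered_to_rows(filtered: Sequence[FilteredVariant]) -> list[dict]:
    """Flatten to TSV-ready rows: chrom, pos, ref, alt, qual, four AFs."""
    return [
        {
            "chrom": fv.chrom,
            "pos": fv.pos,
            "ref": fv.record.ref,
            "alt": fv.record.alt,
            "qual": fv.record.qual,
            "af_parent": fv.af_parent,
            "af_mutant": fv.af_mutant,
            "af_f2mut": fv.af_f2mut,
            "af_f2wt": fv.af_f2wt,
        }
        for fv in filtered
    ]
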