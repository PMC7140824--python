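"""Coverage-based detection of mutant-specific deletions.

A homozygous deletion carried by the mutant line shows as an interval of
near-zero read depth in the mutant line and the mutant F2 pool while the
unmutagenized parent keeps normal coverage there.  The scanner thresholds
per-base depth against per-sample track means, merges nearby depleted runs,
and reports intervals with supporting depth statistics.  The wild-type F2
pool is reported but not used as a calling clause: with a recessive causal
allele it contains heterozygous carriers and only drops to ~2/3 depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vcfio import DepthTrack

REQUIRED_ROLES = ("parent_wt", "mutant_line", "f2_mut_pool")


@dataclass(frozen=True)
class ScanConfig:
    low_frac: float = 0.1  # of the sample's track mean: "depleted"
    normal_frac: float = 0.5  # of the parent's track mean: "normal"
    min_len: int = 50
    merge_gap: int = 10
    flank: int = 500  # bp of context for flank depth statistics

    def validate(self) -> None:
        if not 0.0 < self.low_frac < self.normal_frac:
            raise ValueError("require 0 < low_frac < normal_frac")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class DeletionCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    mean_depth_inside: dict[str, float] = field(default_factory=dict)
    mean_depth_flank: dict[str, float] = field(default_factory=dict)
    supporting_samples: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start_idx, end_idx) inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1]) - 1) for i in range(0, len(edges), 2)]


def merge_runs(runs: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by gaps <= merge_gap; idempotent."""
    if not runs:
        return []
    runs = sorted(runs)
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] - 1 <= merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def scan_deletions(
    tracks: dict[str, DepthTrack],
    cfg: ScanConfig | None = None,
    region: tuple[str, int, int] | None = None,
) -> list[DeletionCall]:
    """Call mutant-specific deletions from per-base depth tracks.

    ``tracks`` maps role names (parent_wt, mutant_line, f2_mut_pool, and
    optionally f2_wt_pool) to depth tracks over a common interval.  A base is
    part of a candidate deletion when it is depleted (< low_frac x track
    mean) in both mutant samples and normal (>= normal_frac x track mean) in
    the parent.  Runs merged across gaps <= merge_gap are reported when at
    least min_len long.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    for role in REQUIRED_ROLES:
        if role not in tracks:
            raise ValueError(f"missing required depth track for role {role!r}")
    ref = tracks["mutant_line"]
    if region is None:
        region = (ref.chrom, ref.start, ref.end)
    chrom, start, end = region
    for role in REQUIRED_ROLES:
        t = tracks[role]
        if t.chrom != chrom or not t.covers(start, end):
            raise ValueError(
                f"track for role {role!r} does not cover {chrom}:{start}-{end}"
            )

    def window(role: str) -> np.ndarray:
        t = tracks[role]
        return t.depths[start - t.start : end - t.start + 1]

    means = {role: float(tracks[role].depths.mean()) for role in tracks}
    depleted_ml = window("mutant_line") < cfg.low_frac * means["mutant_line"]
    depleted_fm = window("f2_mut_pool") < cfg.low_frac * means["f2_mut_pool"]
    parent_ok = window("parent_wt") >= cfg.normal_frac * means["parent_wt"]
    candidate = depleted_ml & depleted_fm & parent_ok

    calls: list[DeletionCall] = []
    for lo, hi in merge_runs(_runs(candidate), cfg.merge_gap):
        if hi - lo + 1 < cfg.min_len:
            continue
        call_start, call_end = start + lo, start + hi
        inside, flanks, support = {}, {}, []
        for role, t in tracks.items():
            d = t.depths
            i0, i1 = call_start - t.start, call_end - t.start + 1
            inside[role] = float(d[i0:i1].mean())
            left = d[max(0, i0 - cfg.flank) : i0]
            right = d[i1 : i1 + cfg.flank]
            flank_vals = np.concatenate([left, right])
            flanks[role] = float(flank_vals.mean()) if len(flank_vals) else float("nan")
            if role != "parent_wt" and inside[role] < cfg.low_frac * means[role]:
                support.append(role)
        calls.append(
            DeletionCall(
                chrom=chrom, start=call_start, end=call_end,
                mean_depth_inside=inside, mean_depth_flank=flanks,
                supporting_samples=tuple(support),
            )
        )
    return calls


@dataclass
class AmpliconPrediction:
    wt_len: int
    mut_len: int | None  # None when a primer footprint is lost
    note: str


def predict_amplicon_lengths(
    primer_left: tuple[int, int],
    primer_right: tuple[int, int],
    deletion: tuple[int, int],
) -> AmpliconPrediction:
    """PCR product lengths for a deletion genotyping assay.

    Primers are 1-based inclusive footprints on the reference; the wild-type
    product spans left primer start to right primer end.  The mutant product
    is shortened by the deletion's overlap with the amplicon, provided both
    primer footprints survive intact on the deleted allele.
    """
    l_start, l_end = primer_left
    r_start, r_end = primer_right
    d_start, d_end = deletion
    if l_start > l_end or r_start > r_end or d_start > d_end:
        raise ValueError("intervals must have start <= end")
    if l_end >= r_start:
        raise ValueError("left primer must lie left of right primer")
    wt_len = r_end - l_start + 1

    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)

    if overlaps(primer_left, deletion) or overlaps(primer_right, deletion):
        return AmpliconPrediction(wt_len, None, "no mutant product: primer footprint deleted")
    cut = overlaps((l_start, r_end), deletion)
    return AmpliconPrediction(wt_len, wt_len - cut, "ok")
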