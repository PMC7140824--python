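"""Windowed allele-frequency profiles, Loess smoothing, and peak calling.

Filtered markers are averaged in fixed non-overlapping 1 Mb tiles per
chromosome, the window means are smoothed with locally weighted quadratic
regression (tricube weights), and the candidate region is the contiguous run
of high-frequency windows around the global maximum of the smoothed
mutant-pool profile.  Under recessive phenotype selection the mutant pool's
alternate allele frequency rises towards 1 at markers linked to the causal
locus, so the peak localizes it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .mm_filter import FilteredVariant

log = logging.getLogger(__name__)


@dataclass
class WindowProfile:
    chrom: str
    window_start: int  # 1-based
    window_end: int  # inclusive
    n_variants: int
    mean_af_f2mut: float | None
    mean_af_f2wt: float | None
    smooth_af_f2mut: float | None = None
    smooth_af_f2wt: float | None = None

    @property
    def midpoint(self) -> float:
        return (self.window_start + self.window_end) / 2.0


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_value: float
    n_supporting_windows: int


@dataclass
class CandidateCall:
    """Peak-caller outcome: the interval when one was found, plus a diagnostic."""

    interval: CandidateInterval | None
    diagnostic: str

    def __bool__(self) -> bool:
        return self.interval is not None


def window_means(
    variants: Sequence[FilteredVariant],
    window_size: int = 1_000_000,
    chrom_lengths: Sequence[tuple[str, int]] | None = None,
) -> list[WindowProfile]:
    """Average pool allele frequencies in fixed tiles of ``window_size`` bp.

    Window k on a chromosome covers [1 + k*w, (k+1)*w], 1-based inclusive.
    With ``chrom_lengths`` given, every tile of every chromosome is emitted
    (empty tiles carry ``None`` means); otherwise tiles run to the last
    variant seen per chromosome.  Input must be sorted by (chrom, pos).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    last: tuple[str, int] | None = None
    seen_chroms: list[str] = []
    acc: dict[str, dict[int, list[tuple[float, float]]]] = {}
    for fv in variants:
        if last is not None and fv.chrom == last[0] and fv.pos < last[1]:
            raise ValueError(
                f"variants not sorted: {fv.chrom}:{fv.pos} after {last[0]}:{last[1]}"
            )
        if fv.chrom not in acc:
            if fv.chrom in seen_chroms:
                raise ValueError(f"variants not sorted: chromosome {fv.chrom} seen twice")
            seen_chroms.append(fv.chrom)
            acc[fv.chrom] = {}
        last = (fv.chrom, fv.pos)
        k = (fv.pos - 1) // window_size
        acc[fv.chrom].setdefault(k, []).append((fv.af_f2mut, fv.af_f2wt))

    if chrom_lengths is not None:
        chrom_iter = [(c, math.ceil(l / window_size)) for c, l in chrom_lengths]
    else:
        chrom_iter = [(c, max(acc[c]) + 1) for c in seen_chroms]

    profiles: list[WindowProfile] = []
    for chrom, n_windows in chrom_iter:
        windows = acc.get(chrom, {})
        for k in range(n_windows):
            values = windows.get(k, [])
            if values:
                mut = float(np.mean([v[0] for v in values]))
                wt = float(np.mean([v[1] for v in values]))
            else:
                mut = wt = None
            profiles.append(
                WindowProfile(
                    chrom=chrom,
                    window_start=1 + k * window_size,
                    window_end=(k + 1) * window_size,
                    n_variants=len(values),
                    mean_af_f2mut=mut,
                    mean_af_f2wt=wt,
                )
            )
    return profiles


def _loess_1d(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float,
              degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    For each evaluation point the nearest ceil(span*n) observations get
    tricube weights on their scaled distances and a degree-2 polynomial is
    fit by weighted least squares.  Exact on polynomial trends of degree
    <= 2 regardless of span.
    """
    n = len(x)
    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        dist = np.abs(x - x0)
        idx = np.argsort(dist, kind="stable")[:k]
        d = dist[idx]
        dmax = d.max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        deg = min(degree, len(idx) - 1)
        # weighted polyfit, centered at x0 for conditioning
        X = np.vander((x[idx] - x0) / dmax, deg + 1, increasing=True)
        W = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(X * W, y[idx] * W[:, 0], rcond=None)
        out[i] = coef[0]
    return out


def loess_smooth(profiles: Sequence[WindowProfile], span: float = 0.2) -> list[WindowProfile]:
    """Smooth window means per chromosome; values clamped to [0, 1].

    Windows without variants are excluded from the fit and keep ``None``
    smoothed values.  Chromosomes with fewer than three informative windows
    copy their raw means (with a warning).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    out: list[WindowProfile] = []
    chroms: list[str] = []
    for p in profiles:
        if p.chrom not in chroms:
            chroms.append(p.chrom)
    for chrom in chroms:
        chrom_profiles = [p for p in profiles if p.chrom == chrom]
        informative = [p for p in chrom_profiles if p.mean_af_f2mut is not None]
        if len(informative) < 3:
            log.warning(
                "%s: only %d informative windows, copying raw means", chrom, len(informative)
            )
            for p in chrom_profiles:
                out.append(
                    replace(p, smooth_af_f2mut=p.mean_af_f2mut, smooth_af_f2wt=p.mean_af_f2wt)
                )
            continue
        x = np.array([p.midpoint for p in informative])
        sm_mut = _loess_1d(x, np.array([p.mean_af_f2mut for p in informative]), x, span)
        sm_wt = _loess_1d(x, np.array([p.mean_af_f2wt for p in informative]), x, span)
        sm_mut = np.clip(sm_mut, 0.0, 1.0)
        sm_wt = np.clip(sm_wt, 0.0, 1.0)
        smoothed = {id(p): (m, w) for p, m, w in zip(informative, sm_mut, sm_wt)}
        for p in chrom_profiles:
            if id(p) in smoothed:
                m, w = smoothed[id(p)]
                out.append(replace(p, smooth_af_f2mut=float(m), smooth_af_f2wt=float(w)))
            else:
                out.append(replace(p))
    return out


def call_candidate_interval(
    profiles: Sequence[WindowProfile],
    peak_min: float = 0.9,
    edge: float = 0.75,
) -> CandidateCall:
    """Locate the candidate region around the smoothed mutant-pool maximum.

    The global maximum must reach ``peak_min``; the interval extends in both
    directions while the smoothed value stays >= ``edge`` (windows without
    variants stop the extension).  Ties on the maximum go to the earlier
    chromosome/position and are logged.
    """
    scored = [
        (i, p) for i, p in enumerate(profiles) if p.smooth_af_f2mut is not None
    ]
    if not scored:
        return CandidateCall(None, "no informative windows")
    max_value = max(p.smooth_af_f2mut for _, p in scored)
    if max_value < peak_min:
        return CandidateCall(
            None, f"no window >= peak_min (max {max_value:.3f} < {peak_min})"
        )
    # maximal windows grouped into contiguous runs; a plateau (smoothing can
    # saturate at 1.0 over several windows) is summarized by its center,
    # while distinct tied maxima break toward the earlier chromosome/position
    top = [(i, p) for i, p in scored if p.smooth_af_f2mut == max_value]
    run = [top[0]]
    for i, p in top[1:]:
        if i == run[-1][0] + 1 and p.chrom == run[-1][1].chrom:
            run.append((i, p))
        else:
            break
    if len(top) > len(run):
        log.info("peak tie at %.4f broken toward %s:%d", max_value,
                 run[0][1].chrom, run[0][1].window_start)
    best = run[len(run) // 2][1]

    chrom_profiles = [p for p in profiles if p.chrom == best.chrom]
    j = chrom_profiles.index(best)

    def extends(p: WindowProfile) -> bool:
        return p.smooth_af_f2mut is not None and p.smooth_af_f2mut >= edge

    lo = j
    while lo > 0 and extends(chrom_profiles[lo - 1]):
        lo -= 1
    hi = j
    while hi < len(chrom_profiles) - 1 and extends(chrom_profiles[hi + 1]):
        hi += 1
    interval = CandidateInterval(
        chrom=best.chrom,
        start=chrom_profiles[lo].window_start,
        end=chrom_profiles[hi].window_end,
        peak_pos=int(best.midpoint),
        peak_value=float(best.smooth_af_f2mut),
        n_supporting_windows=hi - lo + 1,
    )
    return CandidateCall(interval, "candidate interval found")


def homozygous_candidates(
    variants: Sequence[FilteredVariant],
    interval: CandidateInterval | None = None,
    hom_min: float = 1.0,
) -> list[FilteredVariant]:
    """Filtered variants homozygous in the mutant pool within the interval.

    With the default ``hom_min`` of 1.0 this demands zero reference reads in
    the mutant F2 pool — the causal-candidate extraction step.  Without an
    interval the whole genome is searched.
    """
    hits = [
        fv for fv in variants
        if fv.af_f2mut >= hom_min
        and (interval is None
             or (fv.chrom == interval.chrom and interval.start <= fv.pos <= interval.end))
    ]
    return sorted(hits, key=lambda fv: (fv.chrom, fv.pos))


def plot_profiles(
    profiles: Sequence[WindowProfile],
    path,
    interval: CandidateInterval | None = None,
    marker_pos: tuple[str, int] | None = None,
) -> None:
    """Per-chromosome panels of raw window means (dots) and smoothed lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms: list[str] = []
    for p in profiles:
        if p.chrom not in chroms:
            chroms.append(p.chrom)
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.6 * len(chroms)), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        ps = [p for p in profiles if p.chrom == chrom and p.mean_af_f2mut is not None]
        x = [p.midpoint / 1e6 for p in ps]
        ax.plot(x, [p.mean_af_f2mut for p in ps], ".", color="purple", ms=3, label="F2 mutant")
        ax.plot(x, [p.mean_af_f2wt for p in ps], ".", color="steelblue", ms=3, label="F2 wt")
        sm = [p for p in ps if p.smooth_af_f2mut is not None]
        ax.plot([p.midpoint / 1e6 for p in sm], [p.smooth_af_f2mut for p in sm],
                color="purple", lw=1)
        ax.plot([p.midpoint / 1e6 for p in sm], [p.smooth_af_f2wt for p in sm],
                color="steelblue", lw=1)
        if marker_pos and marker_pos[0] == chrom:
            ax.axvline(marker_pos[1] / 1e6, color="gray", lw=3, alpha=0.5)
        if interval and interval.chrom == chrom:
            ax.axvspan(interval.start / 1e6, interval.end / 1e6, color="orange", alpha=0.2)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_ylim(-0.05, 1.05)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
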