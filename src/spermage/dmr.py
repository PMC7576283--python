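"""Two independent DMR callers and the consensus filter.

The published analysis this models ran two established callers (a
smoothing-based one and a segmentation-based one) and kept regions found by
both with at least 4 CpGs and a 30% mean methylation difference. The
consensus filter is the part that must be exact; the callers here are
transparent, fully parameterized stand-ins:

* a run-based caller on kernel-smoothed methylation differences, and
* a recursive segmentation caller on the raw per-CpG difference signal,
  scored with a multiscale scan statistic and tested with a Wilcoxon
  signed-rank test of the within-segment differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import DMR, GenomicInterval, MethylomeTrack, intersect_intervals

__all__ = [
    "CallerParams",
    "smooth_track",
    "call_dmrs_rundiff",
    "call_dmrs_binseg",
    "consensus_dmrs",
]

SMOOTHED = "smoothed"
SEGMENTATION = "segmentation"


@dataclass(frozen=True)
class CallerParams:
    """Caller and consensus-filter parameters.

    ``min_cpgs`` (4) and ``min_mean_diff`` (0.30) are the consensus
    thresholds; the rest tune the two stand-in callers. ``diff_threshold``
    is the candidate-run threshold on smoothed differences and doubles as
    the minimum mean effect a segmentation segment must show.
    """

    smooth_window_bp: int = 1000
    smooth_min_cpgs: int = 5
    diff_threshold: float = 0.10
    min_cpgs: int = 4
    min_mean_diff: float = 0.30
    min_gap_bp: int = 300
    seg_max_depth: int = 32
    seg_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("diff_threshold", "min_mean_diff", "seg_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} must be in (0, 1]")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")


def _check_paired(young: MethylomeTrack, old: MethylomeTrack) -> None:
    if not young.same_positions(old):
        raise ValueError("young and old tracks must share CpG position sets")


def smooth_track(
    track: MethylomeTrack, params: CallerParams = CallerParams()
) -> dict[str, np.ndarray]:
    """Coverage-weighted boxcar smoothing of per-CpG methylation.

    The smoothed level at site i is sum(meth)/sum(total) over all sites
    within ``smooth_window_bp/2`` bp of i; if fewer than
    ``smooth_min_cpgs`` sites fall in the window it is widened to the
    nearest sites until the count is reached (or the chromosome is
    exhausted). A boxcar (uniform) kernel keeps constants invariant and
    makes the single-site limit the identity.
    """
    if track.n_sites == 0:
        raise ValueError("cannot smooth an empty track")
    out = {}
    for chrom in track.chrom_names():
        arr = track.chroms[chrom]
        out[chrom] = _smooth_chrom(
            arr.pos, arr.meth, arr.total, params.smooth_window_bp, params.smooth_min_cpgs
        )
    return out


def _smooth_chrom(pos, meth, total, window_bp: int, min_cpgs: int) -> np.ndarray:
    n = pos.size
    half = window_bp // 2
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    min_cpgs = min(min_cpgs, n)
    deficient = np.flatnonzero(hi - lo < min_cpgs)
    for i in deficient:
        a, b = int(lo[i]), int(hi[i])
        while b - a < min_cpgs:
            left_gap = pos[i] - pos[a - 1] if a > 0 else np.inf
            right_gap = pos[b] - pos[i] if b < n else np.inf
            if left_gap <= right_gap:
                a -= 1
            else:
                b += 1
        lo[i], hi[i] = a, b
    cm = np.concatenate([[0], np.cumsum(meth)])
    ct = np.concatenate([[0], np.cumsum(total)])
    return (cm[hi] - cm[lo]) / (ct[hi] - ct[lo])


def _region_stats(
    young: MethylomeTrack, old: MethylomeTrack, chrom: str, lo: int, hi: int
) -> tuple[int, float, float]:
    """CpG count and raw (unsmoothed, unweighted) group means on a site slice."""
    by = young.chroms[chrom].beta[lo:hi]
    bo = old.chroms[chrom].beta[lo:hi]
    return hi - lo, float(by.mean()), float(bo.mean())


def call_dmrs_rundiff(
    young: MethylomeTrack,
    old: MethylomeTrack,
    params: CallerParams = CallerParams(),
) -> list[DMR]:
    """Run-based caller on smoothed differences.

    Candidate regions are maximal runs of consecutive CpGs whose smoothed
    difference (old - young) exceeds ``diff_threshold`` in absolute value
    with constant sign and inter-CpG gaps of at most ``min_gap_bp``. Each
    run reports its raw group means and a score equal to the mean absolute
    smoothed difference.
    """
    _check_paired(young, old)
    sy = smooth_track(young, params)
    so = smooth_track(old, params)
    dmrs = []
    for chrom in young.chrom_names():
        pos = young.chroms[chrom].pos
        d = so[chrom] - sy[chrom]
        idx = np.flatnonzero(np.abs(d) >= params.diff_threshold)
        if idx.size == 0:
            continue
        sign = np.sign(d[idx])
        brk = (
            (np.diff(idx) != 1)
            | (sign[1:] != sign[:-1])
            | (pos[idx[1:]] - pos[idx[:-1]] > params.min_gap_bp)
        )
        for run in np.split(idx, np.flatnonzero(brk) + 1):
            lo, hi = int(run[0]), int(run[-1]) + 1
            n_cpgs, mean_y, mean_o = _region_stats(young, old, chrom, lo, hi)
            dmrs.append(
                DMR(
                    interval=GenomicInterval(chrom, int(pos[lo]), int(pos[hi - 1]) + 1),
                    n_cpgs=n_cpgs,
                    mean_young=mean_y,
                    mean_old=mean_o,
                    score=float(np.abs(d[lo:hi]).mean()),
                    callers=frozenset({SMOOTHED}),
                )
            )
    return dmrs


def _best_segment(x: np.ndarray, min_len: int) -> Optional[tuple[int, int, float]]:
    """Contiguous sub-segment maximizing |sum|/sqrt(length), length >= min_len.

    Searched over a geometric grid of window lengths with cumulative sums,
    then refined by greedy one-CpG boundary moves. Deterministic: on ties
    the shorter, leftmost window wins. Returns (start, stop, score).
    """
    n = x.size
    if n < min_len:
        return None
    cs = np.concatenate([[0.0], np.cumsum(x)])

    def score(i: int, j: int) -> float:
        return abs(cs[j] - cs[i]) / np.sqrt(j - i)

    lengths = []
    L = min_len
    while L < n:
        lengths.append(L)
        L = max(L + 1, int(L * 1.4))
    lengths.append(n)
    best = (0, min(min_len, n), -1.0)
    for L in lengths:
        s = np.abs(cs[L:] - cs[:-L]) / np.sqrt(L)
        i = int(np.argmax(s))
        if s[i] > best[2]:
            best = (i, i + L, float(s[i]))
    i, j, sc = best
    improved = True
    while improved:
        improved = False
        candidates = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
        for a, b in candidates:
            if a < 0 or b > n or b - a < min_len:
                continue
            s = score(a, b)
            if s > sc + 1e-12:
                i, j, sc = a, b, s
                improved = True
                break
    return i, j, sc


def _wilcoxon_p(d: np.ndarray) -> float:
    """Two-sided signed-rank p of within-segment differences against zero."""
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    try:
        return float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
    except ValueError:  # pragma: no cover - degenerate inputs
        return 1.0


def call_dmrs_binseg(
    young: MethylomeTrack,
    old: MethylomeTrack,
    params: CallerParams = CallerParams(),
) -> list[DMR]:
    """Recursive segmentation caller on the raw per-CpG difference signal.

    Within the current stretch, the candidate segment maximizes the scan
    statistic |sum d|/sqrt(length) (length >= ``min_cpgs``). The candidate
    is accepted if its mean difference reaches ``diff_threshold`` and the
    signed-rank test of its per-CpG differences is significant at
    ``seg_p_threshold``; the caller then recurses into both flanks, up to
    ``seg_max_depth`` levels. A rejected candidate ends the recursion in
    that stretch, which under the null happens almost immediately: the
    maximizing segment is either too diffuse (small |mean|) or too short
    for the signed-rank test.
    """
    _check_paired(young, old)
    dmrs = []
    for chrom in young.chrom_names():
        pos = young.chroms[chrom].pos
        d = old.chroms[chrom].beta - young.chroms[chrom].beta
        segments: list[tuple[int, int, float]] = []
        _binseg_recurse(d, 0, d.size, 0, params, segments)
        for lo, hi, sc in sorted(segments):
            n_cpgs, mean_y, mean_o = _region_stats(young, old, chrom, lo, hi)
            dmrs.append(
                DMR(
                    interval=GenomicInterval(chrom, int(pos[lo]), int(pos[hi - 1]) + 1),
                    n_cpgs=n_cpgs,
                    mean_young=mean_y,
                    mean_old=mean_o,
                    score=sc,
                    callers=frozenset({SEGMENTATION}),
                )
            )
    return dmrs


def _binseg_recurse(
    d: np.ndarray,
    lo: int,
    hi: int,
    depth: int,
    params: CallerParams,
    segments: list,
) -> None:
    if hi - lo < params.min_cpgs or depth >= params.seg_max_depth:
        return
    found = _best_segment(d[lo:hi], params.min_cpgs)
    if found is None:
        return
    i, j, sc = found
    i, j = lo + i, lo + j
    seg = d[i:j]
    if (
        j - i >= params.min_cpgs
        and abs(seg.mean()) >= params.diff_threshold
        and _wilcoxon_p(seg) <= params.seg_p_threshold
    ):
        segments.append((i, j, sc))
        _binseg_recurse(d, lo, i, depth + 1, params, segments)
        _binseg_recurse(d, j, hi, depth + 1, params, segments)


def consensus_dmrs(
    list_a: Sequence[DMR],
    list_b: Sequence[DMR],
    params: CallerParams = CallerParams(),
    young: Optional[MethylomeTrack] = None,
    old: Optional[MethylomeTrack] = None,
) -> list[DMR]:
    """Consensus filter: regions found by both callers, >= ``min_cpgs`` CpGs
    and >= ``min_mean_diff`` mean methylation difference.

    A consensus DMR is the intersection of any overlapping, same-direction
    pair (one region from each caller). When the source tracks are supplied
    the CpG count and raw group means are recomputed on the intersection;
    otherwise the intersection conservatively inherits the smaller CpG
    count and the average of the two callers' group means. Output is
    sorted and non-overlapping (overlapping same-direction consensus
    intervals are merged).
    """
    candidates: list[DMR] = []
    by_chrom_b: dict[str, list[DMR]] = {}
    for b in list_b:
        by_chrom_b.setdefault(b.interval.chrom, []).append(b)
    for bs in by_chrom_b.values():
        bs.sort(key=lambda r: r.interval.start)
    for a in list_a:
        for b in by_chrom_b.get(a.interval.chrom, []):
            if b.interval.start >= a.interval.end:
                break
            iv = intersect_intervals(a.interval, b.interval)
            if iv is None or a.direction != b.direction:
                continue
            candidates.append(_consensus_candidate(a, b, iv, young, old))
    kept = [
        c
        for c in candidates
        if c.n_cpgs >= params.min_cpgs and abs(c.diff) >= params.min_mean_diff
    ]
    kept.sort(key=lambda r: r.interval)
    return _merge_overlapping(kept, young, old)


def _consensus_candidate(
    a: DMR,
    b: DMR,
    iv: GenomicInterval,
    young: Optional[MethylomeTrack],
    old: Optional[MethylomeTrack],
) -> DMR:
    callers = (a.callers | b.callers) or frozenset({SMOOTHED, SEGMENTATION})
    if young is not None and old is not None:
        pos = young.chroms[iv.chrom].pos
        lo = int(np.searchsorted(pos, iv.start, side="left"))
        hi = int(np.searchsorted(pos, iv.end, side="left"))
        if hi > lo:
            n_cpgs, mean_y, mean_o = _region_stats(young, old, iv.chrom, lo, hi)
            return DMR(iv, n_cpgs, mean_y, mean_o, max(a.score, b.score), callers)
        # no CpGs inside the intersection: cannot satisfy the CpG filter
        return DMR(iv, 1, 0.0, 0.0, 0.0, callers)
    return DMR(
        iv,
        min(a.n_cpgs, b.n_cpgs),
        (a.mean_young + b.mean_young) / 2,
        (a.mean_old + b.mean_old) / 2,
        max(a.score, b.score),
        callers,
    )


def _merge_overlapping(
    dmrs: list[DMR],
    young: Optional[MethylomeTrack],
    old: Optional[MethylomeTrack],
) -> list[DMR]:
    out: list[DMR] = []
    for d in dmrs:
        if (
            out
            and out[-1].interval.overlaps(d.interval)
            and out[-1].direction == d.direction
        ):
            prev = out.pop()
            iv = prev.interval.union_span(d.interval)
            if young is not None and old is not None:
                pos = young.chroms[iv.chrom].pos
                lo = int(np.searchsorted(pos, iv.start, side="left"))
                hi = int(np.searchsorted(pos, iv.end, side="left"))
                n_cpgs, mean_y, mean_o = _region_stats(young, old, iv.chrom, lo, hi)
            else:
                n_cpgs = max(prev.n_cpgs, d.n_cpgs)
                w1, w2 = prev.n_cpgs, d.n_cpgs
                mean_y = (prev.mean_young * w1 + d.mean_young * w2) / (w1 + w2)
                mean_o = (prev.mean_old * w1 + d.mean_old * w2) / (w1 + w2)
            out.append(
                DMR(
                    iv,
                    n_cpgs,
                    mean_y,
                    mean_o,
                    max(prev.score, d.score),
                    prev.callers | d.callers,
                )
            )
        else:
            out.append(d)
    return out
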