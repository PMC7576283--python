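"""Genomic context of DMRs: neighbour genes, repeat enrichment, overlaps.

The repeat enrichment test relocates each DMR uniformly at random within
its own chromosome (lengths preserved, no inter-chromosome shuffling) and
compares the observed count of DMRs overlapping a repeat class against the
relocation null, with an add-one permutation p-value so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import DMR, GeneAnnotation, GenomicInterval, RepeatAnnotation

__all__ = [
    "EnrichmentResult",
    "assign_neighbor_genes",
    "repeat_enrichment_permutation",
    "region_overlap_count",
]


@dataclass(frozen=True)
class EnrichmentResult:
    repeat_class: str
    observed_overlap: int  # DMRs overlapping >= 1 element of the class
    expected_mean: float  # mean overlap count under the relocation null
    p_over: float
    p_under: float
    n_permutations: int


def _interval_tss_distance(iv: GenomicInterval, tss: int) -> int:
    """bp from an interval to a point; 0 when the point lies inside."""
    if tss < iv.start:
        return iv.start - tss
    if tss >= iv.end:
        return tss - (iv.end - 1)
    return 0


def assign_neighbor_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneAnnotation],
    max_dist: int = 1_000_000,
) -> dict[str, list[str]]:
    """Genes whose TSS lies within ``max_dist`` bp of each DMR.

    Both up- and downstream genes qualify (distance 0 if the TSS falls
    inside the DMR). The union of the per-DMR lists is what gets exported
    for external GO/GSEA analysis. DMRs with no gene in range map to an
    empty list.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, list[str]] = {}
    for d in dmrs:
        hits = [
            g.gene_id
            for g in by_chrom.get(d.interval.chrom, [])
            if _interval_tss_distance(d.interval, g.tss) <= max_dist
        ]
        out[d.region_id] = sorted(hits)
    return out


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    intervals.sort()
    starts, ends = [], []
    for s, e in intervals:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _overlap_any(
    starts: np.ndarray, ends: np.ndarray, s: np.ndarray, e: np.ndarray
) -> np.ndarray:
    """For query intervals [s, e): does any merged interval overlap?"""
    if starts.size == 0:
        return np.zeros(s.shape, dtype=bool)
    idx = np.searchsorted(ends, s, side="right")
    inb = idx < starts.size
    res = np.zeros(s.shape, dtype=bool)
    res[inb] = starts[idx[inb]] < e[inb]
    return res


def repeat_enrichment_permutation(
    dmrs: Sequence[DMR],
    repeats: Sequence[RepeatAnnotation],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation enrichment of DMRs in each repeat class.

    Null: every DMR is relocated uniformly within its own chromosome,
    length preserved, independently per permutation. The statistic is the
    number of DMRs overlapping at least one element of the class.
    p_over = (1 + #{perm >= observed}) / (n_perm + 1); p_under uses <=.
    """
    for d in dmrs:
        L = chrom_lengths.get(d.interval.chrom)
        if L is None:
            raise ValueError(f"no chromosome length for {d.interval.chrom}")
        if len(d.interval) > L:
            raise ValueError(
                f"DMR {d.region_id} longer than its chromosome ({L} bp)"
            )
    classes = sorted({r.repeat_class for r in repeats})
    merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for cls in classes:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in repeats:
            if r.repeat_class == cls:
                per_chrom.setdefault(r.interval.chrom, []).append(
                    (r.interval.start, r.interval.end)
                )
        merged[cls] = {c: _merge(v) for c, v in per_chrom.items()}

    chroms = [d.interval.chrom for d in dmrs]
    lengths = np.array([len(d.interval) for d in dmrs], dtype=np.int64)
    obs_starts = np.array([d.interval.start for d in dmrs], dtype=np.int64)
    rng = np.random.default_rng(seed)
    # relocated start positions: (n_perm, n_dmrs)
    highs = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64) - lengths
    perm_starts = rng.integers(0, highs + 1, size=(n_perm, len(dmrs)))

    results = []
    for cls in classes:
        obs_hits = 0
        perm_hits = np.zeros(n_perm, dtype=np.int64)
        for j, chrom in enumerate(chroms):
            starts, ends = merged[cls].get(
                chrom, (np.empty(0, np.int64), np.empty(0, np.int64))
            )
            obs_hits += int(
                _overlap_any(
                    starts,
                    ends,
                    obs_starts[j : j + 1],
                    obs_starts[j : j + 1] + lengths[j],
                )[0]
            )
            ps = perm_starts[:, j]
            perm_hits += _overlap_any(starts, ends, ps, ps + lengths[j])
        p_over = (1 + int(np.sum(perm_hits >= obs_hits))) / (n_perm + 1)
        p_under = (1 + int(np.sum(perm_hits <= obs_hits))) / (n_perm + 1)
        results.append(
            EnrichmentResult(
                repeat_class=cls,
                observed_overlap=obs_hits,
                expected_mean=float(perm_hits.mean()),
                p_over=p_over,
                p_under=p_under,
                n_permutations=n_perm,
            )
        )
    return results


def region_overlap_count(set_a: Sequence[DMR], set_b: Sequence[DMR]) -> int:
    """Number of (a, b) pairs with a positive-length intersection."""
    by_chrom: dict[str, list[DMR]] = {}
    for b in set_b:
        by_chrom.setdefault(b.interval.chrom, []).append(b)
    count = 0
    for a in set_a:
        for b in by_chrom.get(a.interval.chrom, []):
            if a.interval.overlaps(b.interval):
                count += 1
    return count
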