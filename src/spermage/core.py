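"""Core domain types for sperm methylome ageing analyses.

All internal coordinates are 0-based, half-open. Conversion to and from
1-based (cytosine reports) or other conventions happens only at format
boundaries in :mod:`spermage.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "CpGSite",
    "SiteArray",
    "MethylomeTrack",
    "DMR",
    "DonorRecord",
    "GeneAnnotation",
    "RepeatAnnotation",
    "AGE_GROUP_BINS",
    "age_group_for",
    "intersect_intervals",
]


# Age-group bins in years: group 1 = 18-25, ..., group 6 = 66 and older.
# Groups are contiguous, so 66 falls in group 6.
AGE_GROUP_BINS: tuple[tuple[float, float], ...] = (
    (18.0, 26.0),
    (26.0, 36.0),
    (36.0, 46.0),
    (46.0, 56.0),
    (56.0, 66.0),
    (66.0, float("inf")),
)


def age_group_for(age: float) -> int:
    """Return the 1-based age group for an age in years.

    Bins: 18-25, 26-35, 36-45, 46-55, 56-65, 66+ (upper edges exclusive
    except the open-ended last group).
    """
    if age < 18:
        raise ValueError(f"age {age} below study range (minimum 18)")
    for i, (lo, hi) in enumerate(AGE_GROUP_BINS, start=1):
        if lo <= age < hi:
            return i
    raise ValueError(f"age {age} outside all bins")  # pragma: no cover


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        return intersect_intervals(self, other)

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval containing both (chromosomes must match)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )


def intersect_intervals(
    a: GenomicInterval, b: GenomicInterval
) -> Optional[GenomicInterval]:
    """Half-open intersection of two intervals, or None if they do not overlap.

    Touching intervals ([1,10) and [10,20)) do not overlap. Commutative.
    """
    if a.chrom != b.chrom:
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start >= end:
        return None
    return GenomicInterval(a.chrom, start, end)


@dataclass(frozen=True)
class CpGSite:
    """One CpG dyad with bisulphite read counts.

    ``pos`` is the 0-based forward-strand position of the C of the CG dyad.
    """

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError(f"total_reads must be >= 1, got {self.total_reads}")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"meth_reads {self.meth_reads} outside [0, {self.total_reads}]"
            )

    @property
    def beta(self) -> float:
        """Methylation level: fraction of methylated reads, in [0, 1]."""
        return self.meth_reads / self.total_reads


class SiteArray:
    """Position-sorted CpG sites of one chromosome, stored as arrays."""

    __slots__ = ("pos", "meth", "total")

    def __init__(self, pos, meth, total, *, validate: bool = True):
        self.pos = np.asarray(pos, dtype=np.int64)
        self.meth = np.asarray(meth, dtype=np.int64)
        self.total = np.asarray(total, dtype=np.int64)
        if validate:
            if not (self.pos.shape == self.meth.shape == self.total.shape):
                raise ValueError("pos/meth/total length mismatch")
            if self.pos.size and np.any(np.diff(self.pos) <= 0):
                raise ValueError("positions must be strictly increasing")
            if np.any(self.total < 1):
                raise ValueError("total reads must be >= 1 at every site")
            if np.any((self.meth < 0) | (self.meth > self.total)):
                raise ValueError("meth reads outside [0, total] at some site")

    @property
    def beta(self) -> np.ndarray:
        return self.meth / self.total

    def __len__(self) -> int:
        return int(self.pos.size)


@dataclass
class MethylomeTrack:
    """Per-CpG methylation of one sample or pool, grouped by chromosome."""

    sample_id: str
    tissue: str  # 'sperm' or 'blood'
    group_label: str = ""
    chroms: dict[str, SiteArray] = field(default_factory=dict)

    TISSUES = ("sperm", "blood")

    def __post_init__(self) -> None:
        if self.tissue not in self.TISSUES:
            raise ValueError(f"tissue must be one of {self.TISSUES}, got {self.tissue!r}")

    def chrom_names(self) -> list[str]:
        return sorted(self.chroms)

    @property
    def n_sites(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def sites(self) -> Iterator[CpGSite]:
        for chrom in self.chrom_names():
            arr = self.chroms[chrom]
            for p, m, t in zip(arr.pos, arr.meth, arr.total):
                yield CpGSite(chrom, int(p), int(m), int(t))

    def same_positions(self, other: "MethylomeTrack") -> bool:
        if self.chrom_names() != other.chrom_names():
            return False
        return all(
            np.array_equal(self.chroms[c].pos, other.chroms[c].pos)
            for c in self.chroms
        )


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region between a young and an old group."""

    interval: GenomicInterval
    n_cpgs: int
    mean_young: float
    mean_old: float
    score: float = 0.0
    callers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("DMR must contain at least one CpG")
        for name, v in (("mean_young", self.mean_young), ("mean_old", self.mean_old)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def diff(self) -> float:
        """Mean methylation difference, old minus young."""
        return self.mean_old - self.mean_young

    @property
    def direction(self) -> str:
        """'hyper' if methylation increases with age, else 'hypo'."""
        return "hyper" if self.diff > 0 else "hypo"

    @property
    def region_id(self) -> str:
        return self.interval.region_id


@dataclass
class DonorRecord:
    """One study participant: age, clinical values and molecular readouts."""

    donor_id: str
    age: float
    clinical: dict[str, float] = field(default_factory=dict)
    dfi_percent: Optional[float] = None
    rtl_blood: Optional[float] = None
    rtl_sperm: Optional[float] = None

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 120:
            raise ValueError(f"age {self.age} outside plausible range [18, 120]")
        if self.dfi_percent is not None and not 0 <= self.dfi_percent <= 100:
            raise ValueError(f"dfi_percent {self.dfi_percent} outside [0, 100]")

    @property
    def age_group(self) -> int:
        return age_group_for(self.age)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat element instance with its class label."""

    repeat_class: str
    interval: GenomicInterval
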