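"""Readers and writers for the text formats the pipeline consumes.

Formats handled: Bismark-style cytosine reports (1-based TSV), bedGraph,
BED region sets, donor CSV tables and deep-bisulphite (DBS) measurement
CSVs. All writers emit tab/comma-separated, newline-terminated records with
deterministic column order; all coordinate conversion to the internal
0-based half-open convention happens here.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    DMR,
    DonorRecord,
    GenomicInterval,
    MethylomeTrack,
    SiteArray,
)

__all__ = [
    "read_cytosine_report",
    "write_cytosine_report",
    "read_bedgraph",
    "write_bedgraph",
    "read_regions_bed",
    "write_dmrs_bed",
    "read_dmrs_bed",
    "read_donor_table",
    "write_donor_table",
    "read_dbs_table",
    "write_dbs_table",
]

PathLike = Union[str, Path]

# Donor CSV columns that are not free-form clinical parameters.
_DONOR_FIXED_COLS = ("donor_id", "age", "dfi_percent", "rtl_blood", "rtl_sperm")


class ParseError(ValueError):
    """Malformed record in an input file; message names the line."""


def read_cytosine_report(
    path: PathLike,
    sample_id: str = "",
    tissue: str = "sperm",
    group_label: str = "",
) -> MethylomeTrack:
    """Read a Bismark-style cytosine report into a methylome track.

    Expected columns (tab-separated): chromosome, 1-based position, strand,
    count methylated, count unmethylated, context, [tri-context]. Only
    CG-context rows are kept. Reverse-strand CpGs are collapsed onto the
    forward-strand C of the dyad (position - 1) and counts are summed, since
    CpG methylation in pooled bisulphite data is strand-symmetric.
    Zero-coverage sites are dropped: beta is undefined there.
    """
    per_chrom: dict[str, dict[int, list[int]]] = defaultdict(dict)
    sample_id = sample_id or Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            if not context.upper().startswith("CG"):
                continue
            try:
                pos1 = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative read count")
            if pos1 < 1:
                raise ParseError(f"{path}: line {lineno}: position must be >= 1")
            pos0 = pos1 - 1  # to 0-based
            if strand == "-":
                pos0 -= 1  # collapse onto forward-strand C of the dyad
                if pos0 < 0:
                    raise ParseError(
                        f"{path}: line {lineno}: reverse-strand CpG at position 1"
                    )
            rec = per_chrom[chrom].setdefault(pos0, [0, 0])
            rec[0] += meth
            rec[1] += meth + unmeth
    chroms: dict[str, SiteArray] = {}
    for chrom, sites in per_chrom.items():
        pos = np.array(sorted(sites), dtype=np.int64)
        meth = np.array([sites[p][0] for p in pos], dtype=np.int64)
        total = np.array([sites[p][1] for p in pos], dtype=np.int64)
        keep = total > 0
        if keep.any():
            chroms[chrom] = SiteArray(pos[keep], meth[keep], total[keep])
    return MethylomeTrack(sample_id, tissue, group_label, chroms)


def write_cytosine_report(track: MethylomeTrack, path: PathLike) -> None:
    """Write a track as a forward-strand CG cytosine report (1-based)."""
    with open(path, "w") as fh:
        for chrom in track.chrom_names():
            arr = track.chroms[chrom]
            unmeth = arr.total - arr.meth
            for p, m, u in zip(arr.pos, arr.meth, unmeth):
                fh.write(f"{chrom}\t{p + 1}\t+\t{m}\t{u}\tCG\tCGN\n")


def read_bedgraph(
    path: PathLike,
    sample_id: str = "",
    tissue: str = "sperm",
    group_label: str = "",
    default_coverage: int = 1,
) -> MethylomeTrack:
    """Read a methylation bedGraph: chrom, start, end, beta[, coverage].

    Coordinates are 0-based half-open; the CpG is taken at ``start``. When a
    fifth column is present it is used as total read coverage and methylated
    counts are reconstructed by rounding beta * coverage; otherwise
    ``default_coverage`` is assumed.
    """
    per_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    sample_id = sample_id or Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 4 fields, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                beta = float(fields[3])
                cov = int(fields[4]) if len(fields) > 4 else default_coverage
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            if not 0.0 <= beta <= 1.0:
                raise ParseError(f"{path}: line {lineno}: beta {beta} outside [0,1]")
            if cov < 1:
                raise ParseError(f"{path}: line {lineno}: coverage < 1")
            per_chrom[fields[0]].append((start, int(round(beta * cov)), cov))
    chroms = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        pos, meth, total = (np.array(v, dtype=np.int64) for v in zip(*rows))
        chroms[chrom] = SiteArray(pos, meth, total)
    return MethylomeTrack(sample_id, tissue, group_label, chroms)


def write_bedgraph(track: MethylomeTrack, path: PathLike) -> None:
    """Write per-CpG beta values as bedGraph with a coverage column."""
    with open(path, "w") as fh:
        for chrom in track.chrom_names():
            arr = track.chroms[chrom]
            for p, b, t in zip(arr.pos, arr.beta, arr.total):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{b:.6g}\t{t}\n")


def write_dmrs_bed(dmrs: Sequence[DMR], path: PathLike) -> None:
    """Write DMRs as BED: chrom, start, end, region_id, n_cpgs, direction,
    diff, mean_young, mean_old, score, callers."""
    with open(path, "w") as fh:
        for d in dmrs:
            iv = d.interval
            callers = ",".join(sorted(d.callers)) or "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.region_id}\t{d.n_cpgs}\t"
                f"{d.direction}\t{d.diff:.6g}\t{d.mean_young:.6g}\t"
                f"{d.mean_old:.6g}\t{d.score:.6g}\t{callers}\n"
            )


def read_regions_bed(path: PathLike) -> list[GenomicInterval]:
    """Read the first three BED columns as genomic intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end in BED record")
            out.append(GenomicInterval(fields[0], start, end))
    return out


def read_dmrs_bed(path: PathLike) -> list[DMR]:
    """Read DMRs written by :func:`write_dmrs_bed` (coordinates round-trip)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}: line {lineno}: expected >= 9 DMR fields")
            try:
                start, end = int(f[1]), int(f[2])
                if start >= end:
                    raise ValueError("start >= end")
                callers = frozenset() if f[10] == "." else frozenset(f[10].split(","))
                out.append(
                    DMR(
                        interval=GenomicInterval(f[0], start, end),
                        n_cpgs=int(f[4]),
                        mean_young=float(f[7]),
                        mean_old=float(f[8]),
                        score=float(f[9]) if len(f) > 9 else 0.0,
                        callers=callers,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_donor_table(path: PathLike) -> list[DonorRecord]:
    """Read a donor CSV (required columns donor_id and age).

    Any column besides the fixed ones (donor_id, age, dfi_percent,
    rtl_blood, rtl_sperm) is treated as a clinical parameter; missing cells
    stay absent. The age group is derived from age, never stored.
    """
    df = pd.read_csv(path)
    for col in ("donor_id", "age"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["donor_id"].duplicated().any():
        dups = df.loc[df["donor_id"].duplicated(), "donor_id"].tolist()
        raise ValueError(f"{path}: duplicate donor_id values: {dups}")
    bad_age = df[(df["age"] < 18) | (df["age"] > 120)]
    if len(bad_age):
        raise ValueError(
            f"{path}: ages outside [18, 120] for donors "
            f"{bad_age['donor_id'].tolist()}"
        )
    clin_cols = [c for c in df.columns if c not in _DONOR_FIXED_COLS]
    donors = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        clinical = {
            c: float(rec[c]) for c in clin_cols if _opt(rec.get(c)) is not None
        }
        donors.append(
            DonorRecord(
                donor_id=str(rec["donor_id"]),
                age=float(rec["age"]),
                clinical=clinical,
                dfi_percent=_opt(rec.get("dfi_percent")),
                rtl_blood=_opt(rec.get("rtl_blood")),
                rtl_sperm=_opt(rec.get("rtl_sperm")),
            )
        )
    return donors


def write_donor_table(donors: Sequence[DonorRecord], path: PathLike) -> None:
    clin_cols = sorted({k for d in donors for k in d.clinical})
    cols = ["donor_id", "age", "dfi_percent", "rtl_blood", "rtl_sperm"] + clin_cols
    rows = []
    for d in donors:
        row = {
            "donor_id": d.donor_id,
            "age": d.age,
            "dfi_percent": d.dfi_percent,
            "rtl_blood": d.rtl_blood,
            "rtl_sperm": d.rtl_sperm,
        }
        row.update({c: d.clinical.get(c) for c in clin_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_dbs_table(path: PathLike):
    """Read DBS measurements CSV: region_id, donor_id, mean_meth, reads."""
    from .simulate import DbsMeasurement  # local import avoids a cycle

    df = pd.read_csv(path)
    for col in ("region_id", "donor_id", "mean_meth", "reads"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return [
        DbsMeasurement(
            region_id=str(r.region_id),
            donor_id=str(r.donor_id),
            mean_meth=float(r.mean_meth),
            reads=int(r.reads),
        )
        for r in df.itertuples(index=False)
    ]


def write_dbs_table(measurements, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region_id", "donor_id", "mean_meth", "reads"])
        for m in measurements:
            w.writerow([m.region_id, m.donor_id, f"{m.mean_meth:.8g}", m.reads])


def read_trajectories_tsv(path: PathLike):
    """Read embryo trajectories from long-format TSV: region_id, stage, beta.

    Stage order follows first appearance per region.
    """
    from .simulate import EmbryoTrajectory

    per_region: dict[str, list[tuple[str, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["region_id", "stage", "beta"]:
            raise ParseError(f"{path}: expected header region_id/stage/beta")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            per_region.setdefault(f[0], []).append((f[1], float(f[2])))
    return [
        EmbryoTrajectory(
            region_id=rid,
            stages=tuple(s for s, _ in rows),
            meth=tuple(b for _, b in rows),
        )
        for rid, rows in per_region.items()
    ]


def write_trajectories_tsv(trajectories, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tstage\tbeta\n")
        for t in trajectories:
            for stage, beta in zip(t.stages, t.meth):
                fh.write(f"{t.region_id}\t{stage}\t{beta:.8g}\n")
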