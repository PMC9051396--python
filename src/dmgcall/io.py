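"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED6, ENCODE narrowPeak, TSV count matrices, and the TSV sample
design table.  Every reader/writer pair round-trips bit-exactly; 0-based
half-open coordinates are used on disk and in memory alike.
"""
from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    GeneAnnotation,
    GenomicInterval,
    ParseError,
    Peak,
    SampleDesign,
    ValidationError,
    validate_design,
)


def _split_lines(path: str) -> List[List[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def read_gene_annotation(path: str, dialect: str = "bed6") -> List[GeneAnnotation]:
    """Read a gene annotation as BED6 or a headered TSV.

    BED6 columns: chrom, start, end, gene_id, score (ignored), strand.
    TSV dialect: a header naming at least gene_id, chrom, start, end, strand.
    Row order is preserved; duplicate gene ids are rejected.
    """
    genes: List[GeneAnnotation] = []
    if dialect == "bed6":
        for lineno, fields in _split_lines(path):
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, gene_id, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneAnnotation(gene_id, iv, strand))
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        needed = {"gene_id", "chrom", "start", "end", "strand"}
        if not needed.issubset(df.columns):
            raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
        for i, row in df.iterrows():
            try:
                iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
                genes.append(GeneAnnotation(str(row["gene_id"]), iv, str(row["strand"])))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate gene_id(s): {dup[:5]}")
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.gene_id}\t0\t{g.strand}\n"
            )


def read_peaks(path: str, sample_id: Optional[str] = None) -> List[Peak]:
    """Read ENCODE narrowPeak (10 columns) or BED6+1 peaks.

    Column 7 (signalValue) becomes ``fold_enrichment``; a narrowPeak summit
    of -1 maps to an absent summit.  ``sample_id`` defaults to the file stem.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    peaks: List[Peak] = []
    for lineno, fields in _split_lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
        chrom, start, end = fields[0], fields[1], fields[2]
        try:
            iv = GenomicInterval(chrom, int(start), int(end))
            fold = float(fields[6]) if len(fields) > 6 else 0.0
            summit: Optional[int] = None
            if len(fields) >= 10:
                s = int(fields[9])
                summit = None if s == -1 else s
            peaks.append(Peak(iv, sample_id, fold, summit))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str) -> None:
    """Write peaks as 10-column ENCODE narrowPeak."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"peak_{i}\t0\t.\t{p.fold_enrichment:g}\t-1\t-1\t{summit}\n"
            )


def read_count_matrix(path: str, library_sizes_path: Optional[str] = None) -> CountMatrix:
    """Read a gene-by-sample (or peak-by-sample) TSV of integer counts.

    The first column holds row ids, the header holds sample ids.  Library
    sizes come from an optional two-column sidecar TSV (sample_id, size)
    and default to column sums.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty matrix")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            raise ParseError(f"{path}: non-integer cell in column {col!r}")
    counts = df.to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValidationError(f"{path}: negative count")
    lib: Optional[np.ndarray] = None
    if library_sizes_path is not None:
        side = pd.read_csv(
            library_sizes_path, sep="\t", header=None, names=["sample_id", "size"]
        )
        mapping = dict(zip(side["sample_id"].astype(str), side["size"].astype(int)))
        try:
            lib = np.array([mapping[str(s)] for s in df.columns], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"library size missing for sample {exc}") from exc
    return CountMatrix(
        [str(r) for r in df.index], [str(c) for c in df.columns], counts, lib
    )


def write_count_matrix(matrix: CountMatrix, path: str, library_sizes_path: Optional[str] = None) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.row_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="id")
    if library_sizes_path is not None:
        with open(library_sizes_path, "w") as fh:
            for s, n in zip(matrix.sample_ids, matrix.library_sizes):
                fh.write(f"{s}\t{n}\n")


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write intervals as BED3 (or BED4/BED5 with names/scores)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            if scores is not None:
                if names is None:
                    fields.append(".")
                fields.append(f"{scores[i]:g}")
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str) -> List[GenomicInterval]:
    out = []
    for lineno, fields in _split_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


DESIGN_COLUMNS = ["sample_id", "age_group", "hemisphere", "assay", "replicate"]


def read_design(path: str) -> List[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing design columns {sorted(missing)}")
    designs = [
        SampleDesign(
            str(r.sample_id), str(r.age_group), str(r.hemisphere),
            str(r.assay), int(r.replicate),
        )
        for r in df.itertuples()
    ]
    validate_design(designs)
    return designs


def write_design(designs: Sequence[SampleDesign], path: str) -> None:
    df = pd.DataFrame(
        [(d.sample_id, d.age_group, d.hemisphere, d.assay, d.replicate) for d in designs],
        columns=DESIGN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_read_positions(path: str) -> Dict[str, np.ndarray]:
    """Read single-base read midpoints from a BED file, grouped by chrom."""
    by_chrom: Dict[str, list] = {}
    for lineno, fields in _split_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}


def write_read_positions(reads: Dict[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reads):
            for pos in reads[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
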