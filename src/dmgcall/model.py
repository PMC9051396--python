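"""Core genomic data model.

All coordinates are 0-based half-open (BED convention) throughout the
package; dialects that use 1-based coordinates are converted at the I/O
boundary and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """A value violates a model invariant."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 bp (bookended does not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's location and strand; the TSS is derived strand-aware.

    For a plus-strand gene the TSS is ``start``; for a minus-strand gene it
    is ``end - 1``, the last covered base under half-open coordinates.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class Peak:
    """A called enrichment interval with its fold enrichment over input."""

    interval: GenomicInterval
    sample_id: str = ""
    fold_enrichment: float = 0.0
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValidationError("fold_enrichment must be >= 0")


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing sample's place in the two-by-two-by-assay design."""

    sample_id: str
    age_group: str  # "13m" | "22m"
    hemisphere: str  # "ipsi" | "contra"
    assay: str  # histone mark, "input", or "rna"
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


class CountMatrix:
    """A rows-by-samples matrix of non-negative integer counts.

    Rows are genes (RNA) or merged peaks (ChIP).  ``library_sizes`` are
    total mapped reads per sample; they may exceed the in-matrix column sum
    (reads outside annotated features) but never fall below it.
    """

    def __init__(
        self,
        row_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        library_sizes: Optional[np.ndarray] = None,
    ) -> None:
        self.row_ids = list(row_ids)
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if counts.size and (
            not np.issubdtype(counts.dtype, np.integer) or (counts < 0).any()
        ):
            raise ValidationError("counts must be non-negative integers")
        if len(self.row_ids) == 0 or len(self.sample_ids) == 0:
            raise ValidationError("empty matrix")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row_ids")
        self.counts = counts.astype(np.int64)
        colsums = self.counts.sum(axis=0)
        if library_sizes is None:
            library_sizes = colsums.copy()
        library_sizes = np.asarray(library_sizes, dtype=np.int64)
        if library_sizes.shape != (len(self.sample_ids),):
            raise ValidationError("library_sizes length must match sample count")
        if (library_sizes <= 0).any():
            raise ValidationError("library_sizes must be positive")
        if (library_sizes < colsums).any():
            raise ValidationError("library_size below column sum of counts")
        self.library_sizes = library_sizes

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            self.row_ids,
            [self.sample_ids[i] for i in idx],
            self.counts[:, idx],
            self.library_sizes[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.library_sizes, other.library_sizes)
        )

    def __repr__(self) -> str:
        return (
            f"CountMatrix({len(self.row_ids)} rows x "
            f"{len(self.sample_ids)} samples)"
        )


def validate_design(designs: Sequence[SampleDesign]) -> None:
    """Check the (age_group, hemisphere, assay, replicate) keys are unique."""
    keys = [(d.age_group, d.hemisphere, d.assay, d.replicate) for d in designs]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (age_group, hemisphere, assay, replicate)")
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in design")
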