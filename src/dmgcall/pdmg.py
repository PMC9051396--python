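"""Presence/absence differential histone modification (pDMG) calling.

Candidate peaks are those with fold enrichment strictly above 4.  A gene is
mark-positive in a condition when at least one candidate peak overlaps its
promoter window, a symmetric region of +/- 5 kb around the strand-aware TSS
by default (an upstream-only window is available via ``sided``).  Genes
mark-positive specifically in the injured (ipsi) or the control (contra)
hemisphere are pDMGs — gained and lost respectively.  Replicates are pooled
before assignment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .model import GeneAnnotation, GenomicInterval, Peak

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterAssignment:
    gene_id: str
    peak_indices: Tuple[int, ...]  # indices into the input peak list


@dataclass(frozen=True)
class PDMGResult:
    mark: str
    age_group: str
    gained: frozenset  # ipsi-specific gene ids
    lost: frozenset  # control-specific gene ids
    shared: frozenset


def filter_candidate_peaks(peaks: Sequence[Peak], min_fold: float = 4.0) -> List[Peak]:
    """Keep peaks with fold enrichment strictly greater than ``min_fold``."""
    return [p for p in peaks if p.fold_enrichment > min_fold]


def promoter_window(
    gene: GeneAnnotation,
    half_width: int,
    chrom_length: Optional[int] = None,
    sided: str = "both",
) -> GenomicInterval:
    """The promoter window around (or upstream of) the strand-aware TSS.

    Symmetric mode covers [tss - half_width, tss + half_width + 1), i.e.
    half_width bases each side of the TSS base; upstream mode covers
    half_width bases 5' of the TSS plus the TSS itself.  Clipped to the
    chromosome bounds.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    tss = gene.tss
    if sided == "both":
        lo, hi = tss - half_width, tss + half_width + 1
    elif sided == "upstream":
        if gene.strand == "+":
            lo, hi = tss - half_width, tss + 1
        else:
            lo, hi = tss, tss + half_width + 1
    else:
        raise ValueError(f"unknown sided mode {sided!r}")
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return GenomicInterval(gene.chrom, lo, max(hi, lo + 1))


def _promoter_trees(
    annotation: Sequence[GeneAnnotation],
    half_width: int,
    chrom_lengths: Optional[Dict[str, int]],
    sided: str,
) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in annotation:
        L = chrom_lengths.get(g.chrom) if chrom_lengths else None
        w = promoter_window(g, half_width, L, sided)
        trees.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end, g.gene_id)
    return trees


def assign_peaks_to_promoters(
    peaks: Sequence[Peak],
    annotation: Sequence[GeneAnnotation],
    half_width: int = 5000,
    chrom_lengths: Optional[Dict[str, int]] = None,
    sided: str = "both",
) -> List[PromoterAssignment]:
    """Overlap candidate peaks with promoter windows (>= 1 bp overlap).

    A peak may support several genes; a gene appears in the output iff at
    least one peak overlaps its window.  Peaks on chromosomes absent from
    the annotation are left unassigned with a logged count.
    """
    trees = _promoter_trees(annotation, half_width, chrom_lengths, sided)
    support: Dict[str, List[int]] = {}
    unknown = 0
    for i, p in enumerate(peaks):
        tree = trees.get(p.interval.chrom)
        if tree is None:
            unknown += 1
            continue
        for hit in tree.overlap(p.interval.start, p.interval.end):
            support.setdefault(hit.data, []).append(i)
    if unknown:
        logger.warning("%d peaks on chromosomes absent from the annotation", unknown)
    return [
        PromoterAssignment(gid, tuple(sorted(idx)))
        for gid, idx in sorted(support.items())
    ]


def mark_positive_genes(
    peaks: Sequence[Peak],
    annotation: Sequence[GeneAnnotation],
    half_width: int = 5000,
    min_fold: float = 4.0,
    chrom_lengths: Optional[Dict[str, int]] = None,
    sided: str = "both",
) -> Set[str]:
    """Genes whose promoter carries >= 1 candidate peak (replicates pooled)."""
    cand = filter_candidate_peaks(peaks, min_fold)
    return {
        a.gene_id
        for a in assign_peaks_to_promoters(cand, annotation, half_width, chrom_lengths, sided)
    }


def call_pdmg(
    ipsi_genes: Set[str],
    control_genes: Set[str],
    mark: str = "",
    age_group: str = "",
) -> PDMGResult:
    """Set algebra of the two conditions: gained, lost, shared."""
    return PDMGResult(
        mark,
        age_group,
        gained=frozenset(ipsi_genes - control_genes),
        lost=frozenset(control_genes - ipsi_genes),
        shared=frozenset(ipsi_genes & control_genes),
    )
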