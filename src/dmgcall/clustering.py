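"""Genomic-locus clustering of differentially expressed genes.

Per chromosome, the average distance AD = chromosome length / number of
DEGs on that chromosome sets the gap threshold: adjacent DEGs whose real
distance is strictly below AD join one cluster, a gap of AD or more starts
a new cluster.  Distance between adjacent genes is TSS-to-TSS by default
(every other analysis here is TSS-anchored); start-to-start and midpoint
measures are available via ``position``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .model import GeneAnnotation, GenomicInterval, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusCluster:
    chrom: str
    member_gene_ids: tuple
    span: GenomicInterval


def average_distance(chrom_length: int, n_degs: int) -> float:
    """AD = chromosome length / DEG count, kept real-valued."""
    if n_degs < 1:
        raise ValidationError("n_degs must be >= 1")
    if chrom_length <= 0:
        raise ValidationError("chrom_length must be > 0")
    return chrom_length / n_degs


def cluster_adjacent_genes(positions: Sequence[float], ad: float) -> List[List[int]]:
    """Group sorted positions into runs whose consecutive gaps are < AD.

    Returns index lists partitioning the input; a gap equal to AD splits
    (the joining rule is strictly "<").
    """
    pos = np.asarray(positions, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValidationError("positions must be sorted ascending")
    clusters: List[List[int]] = []
    for i in range(len(pos)):
        if i == 0 or pos[i] - pos[i - 1] >= ad:
            clusters.append([i])
        else:
            clusters[-1].append(i)
    return clusters


def _gene_position(gene: GeneAnnotation, position: str) -> int:
    if position == "tss":
        return gene.tss
    if position == "start":
        return gene.interval.start
    if position == "midpoint":
        return (gene.interval.start + gene.interval.end) // 2
    raise ValueError(f"unknown position measure {position!r}")


def cluster_degs(
    annotation: Sequence[GeneAnnotation],
    deg_ids: Sequence[str],
    chrom_lengths: Dict[str, int],
    position: str = "tss",
) -> List[LocusCluster]:
    """Cluster the given DEGs chromosome by chromosome with the AD rule.

    Chromosomes absent from ``chrom_lengths`` (or with no DEGs) are skipped
    with a logged notice.
    """
    deg_set = set(deg_ids)
    by_chrom: Dict[str, List[GeneAnnotation]] = {}
    for g in annotation:
        if g.gene_id in deg_set:
            by_chrom.setdefault(g.chrom, []).append(g)
    clusters: List[LocusCluster] = []
    for chrom in sorted(by_chrom):
        if chrom not in chrom_lengths:
            logger.warning("chromosome %s has no known length; skipped", chrom)
            continue
        genes = sorted(by_chrom[chrom], key=lambda g: _gene_position(g, position))
        ad = average_distance(chrom_lengths[chrom], len(genes))
        for idx in cluster_adjacent_genes(
            [_gene_position(g, position) for g in genes], ad
        ):
            members = [genes[i] for i in idx]
            span = GenomicInterval(
                chrom,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
            )
            clusters.append(
                LocusCluster(chrom, tuple(m.gene_id for m in members), span)
            )
    return clusters
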