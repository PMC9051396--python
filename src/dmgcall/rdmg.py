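"""Quantitative differential histone modification (rDMG) calling.

Protocol: peaks from all samples of one mark are merged wherever their loci
overlap (transitive, >= 1 bp; bookended intervals stay separate under
half-open coordinates).  The read count of each merged peak is its density,
normalized per million mapped reads and per kb of merged-region width.
Replicate densities of a group are averaged and the input density
subtracted to give the mark enrichment; the per-replicate log enrichments
feed a two-sided equal-variance Student t-test (p < 0.05).  Genes whose
+/- 3 kb TSS window overlaps a significantly modified merged peak are
rDMGs, direction inherited from the peak.

Enrichments that are non-positive after input subtraction are floored to a
small epsilon (default 1e-3) so the log stays defined; such peaks are
flagged low-signal.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import GeneAnnotation, GenomicInterval, Peak, ValidationError
from .pdmg import promoter_window

logger = logging.getLogger(__name__)

EPSILON = 1e-3


@dataclass
class MergedPeak:
    interval: GenomicInterval
    source_ids: Tuple[int, ...] = ()
    raw_counts: Dict[str, int] = field(default_factory=dict)
    densities: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RDMGResult:
    gene_id: str
    mark: str
    contrast: str
    peak_index: int
    log_enrichment_a: float
    log_enrichment_b: float
    p_value: float
    direction: str  # gained | lost  (relative to group B over group A)


def merge_peaks_across_samples(peaks: Sequence[Peak]) -> List[MergedPeak]:
    """Union overlapping peaks from all samples into disjoint merged peaks.

    Transitive closure of pairwise >= 1 bp overlap; output sorted by
    (chrom, start), pairwise disjoint, covering exactly the union of the
    inputs.  ``source_ids`` are indices into the input sequence.
    """
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].interval.chrom,
                                                     peaks[i].interval.start,
                                                     peaks[i].interval.end))
    merged: List[MergedPeak] = []
    for i in order:
        iv = peaks[i].interval
        if (
            merged
            and merged[-1].interval.chrom == iv.chrom
            and iv.start < merged[-1].interval.end
        ):
            last = merged[-1]
            last.interval = GenomicInterval(
                iv.chrom, last.interval.start, max(last.interval.end, iv.end)
            )
            last.source_ids = last.source_ids + (i,)
        else:
            merged.append(MergedPeak(iv, (i,)))
    return merged


def count_reads_in_peaks(
    merged: Sequence[MergedPeak],
    reads_by_sample: Dict[str, Dict[str, np.ndarray]],
) -> None:
    """Fill ``raw_counts``: reads whose midpoint lies in [start, end).

    Reads on chromosomes carrying no merged peak are ignored (logged).
    """
    sorted_reads = {
        sid: {c: np.sort(np.asarray(pos)) for c, pos in per_chrom.items()}
        for sid, per_chrom in reads_by_sample.items()
    }
    peak_chroms = {m.interval.chrom for m in merged}
    for sid, per_chrom in sorted_reads.items():
        skipped = sum(len(v) for c, v in per_chrom.items() if c not in peak_chroms)
        if skipped:
            logger.info("%s: %d reads on chromosomes without peaks", sid, skipped)
        for m in merged:
            pos = per_chrom.get(m.interval.chrom)
            if pos is None:
                m.raw_counts[sid] = 0
                continue
            lo = np.searchsorted(pos, m.interval.start, side="left")
            hi = np.searchsorted(pos, m.interval.end, side="left")
            m.raw_counts[sid] = int(hi - lo)


def normalize_density(count: int, library_size: int, region_kb: float) -> float:
    """count / (library_size / 1e6) / region_kb."""
    if library_size <= 0:
        raise ValidationError("library_size must be > 0")
    if region_kb <= 0:
        raise ValidationError("region width must be > 0")
    return count / (library_size / 1e6) / region_kb


def compute_densities(
    merged: Sequence[MergedPeak],
    library_sizes: Dict[str, int],
) -> None:
    """Fill ``densities`` from raw counts, per-million and per-kb normalized."""
    for m in merged:
        kb = len(m.interval) / 1e3
        for sid, n in m.raw_counts.items():
            m.densities[sid] = normalize_density(n, library_sizes[sid], kb)


def group_enrichment(
    replicate_densities: Sequence[float],
    input_density: float,
    epsilon: float = EPSILON,
) -> Tuple[float, bool]:
    """Mean replicate density minus input; floored at epsilon if non-positive.

    Returns (enrichment, low_signal_flag).
    """
    if len(replicate_densities) == 0:
        raise ValidationError("need >= 1 replicate density")
    enr = float(np.mean(replicate_densities)) - input_density
    if enr <= 0:
        return epsilon, True
    return enr, False


def replicate_enrichments(
    replicate_densities: Sequence[float],
    input_density: float,
    epsilon: float = EPSILON,
) -> np.ndarray:
    """Per-replicate input-subtracted densities, floored at epsilon."""
    return np.maximum(np.asarray(replicate_densities, dtype=float) - input_density, epsilon)


def differential_peak_test(
    enrichments_a: Sequence[float],
    enrichments_b: Sequence[float],
) -> Tuple[float, str]:
    """Two-sided equal-variance t-test on natural-log enrichments.

    Returns (p, direction) with direction "gained" when group B's mean log
    enrichment exceeds group A's.  Zero variance on both sides gives p = 1
    for equal means and p = 0 otherwise.
    """
    la = np.log(np.asarray(enrichments_a, dtype=float))
    lb = np.log(np.asarray(enrichments_b, dtype=float))
    if la.size < 2 or lb.size < 2:
        raise ValidationError("need >= 2 replicate enrichments per side")
    direction = "gained" if lb.mean() >= la.mean() else "lost"
    if la.var() == 0 and lb.var() == 0:
        return (1.0, direction) if la.mean() == lb.mean() else (0.0, direction)
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(la, lb, equal_var=True)
    if np.isnan(p):
        return 1.0, direction
    return float(p), direction


def call_rdmg(
    significant: Sequence[Tuple],
    annotation: Sequence[GeneAnnotation],
    half_width: int = 3000,
    mark: str = "",
    contrast: str = "",
) -> List[RDMGResult]:
    """Genes whose +/- ``half_width`` TSS window overlaps a significant peak.

    ``significant`` rows are (index, MergedPeak, p, direction) optionally
    followed by the two group log enrichments.
    """
    results: List[RDMGResult] = []
    for g in annotation:
        win = promoter_window(g, half_width)
        for row in significant:
            idx, m, p, direction = row[:4]
            la, lb = (row[4], row[5]) if len(row) >= 6 else (float("nan"), float("nan"))
            if win.overlaps(m.interval):
                results.append(
                    RDMGResult(g.gene_id, mark, contrast, idx, la, lb, p, direction)
                )
    return results


def library_sizes_from_reads(
    reads_by_sample: Dict[str, Dict[str, np.ndarray]]
) -> Dict[str, int]:
    return {
        sid: max(1, sum(len(v) for v in per_chrom.values()))
        for sid, per_chrom in reads_by_sample.items()
    }


def rdmg_analysis(
    peaks_by_sample: Dict[str, List[Peak]],
    reads_by_sample: Dict[str, Dict[str, np.ndarray]],
    chip_a: Sequence[str],
    chip_b: Sequence[str],
    input_a: Sequence[str],
    input_b: Sequence[str],
    annotation: Sequence[GeneAnnotation],
    half_width: int = 3000,
    alpha: float = 0.05,
    epsilon: float = EPSILON,
    mark: str = "",
    contrast: str = "ipsi-vs-contra",
    library_sizes: Optional[Dict[str, int]] = None,
) -> Tuple[List[MergedPeak], pd.DataFrame, List[RDMGResult]]:
    """Run the full quantitative protocol for one mark and one contrast.

    ``chip_a``/``chip_b`` are the replicate ChIP sample ids of the two
    groups (e.g. contralateral vs ipsilateral); ``input_a``/``input_b``
    their matched input samples.  Returns the merged peaks (with counts and
    densities filled), a per-peak test table, and the rDMG calls.
    """
    if not input_a or not input_b:
        raise ValidationError("each group needs a matched input sample")
    all_peaks = [p for sid in list(chip_a) + list(chip_b) for p in peaks_by_sample[sid]]
    merged = merge_peaks_across_samples(all_peaks)
    samples = list(chip_a) + list(chip_b) + list(input_a) + list(input_b)
    reads = {sid: reads_by_sample.get(sid, {}) for sid in samples}
    count_reads_in_peaks(merged, reads)
    if library_sizes is None:
        library_sizes = library_sizes_from_reads(reads)
    compute_densities(merged, library_sizes)

    rows = []
    significant: List[Tuple] = []
    for idx, m in enumerate(merged):
        inp_a = float(np.mean([m.densities[s] for s in input_a]))
        inp_b = float(np.mean([m.densities[s] for s in input_b]))
        enr_a = replicate_enrichments([m.densities[s] for s in chip_a], inp_a, epsilon)
        enr_b = replicate_enrichments([m.densities[s] for s in chip_b], inp_b, epsilon)
        p, direction = differential_peak_test(enr_a, enr_b)
        mean_a, low_a = group_enrichment([m.densities[s] for s in chip_a], inp_a, epsilon)
        mean_b, low_b = group_enrichment([m.densities[s] for s in chip_b], inp_b, epsilon)
        rows.append(
            (idx, m.interval.chrom, m.interval.start, m.interval.end,
             mean_a, mean_b, low_a or low_b, p, direction)
        )
        if p < alpha:
            significant.append((idx, m, p, direction, float(np.log(mean_a)), float(np.log(mean_b))))
    table = pd.DataFrame(
        rows,
        columns=["peak_index", "chrom", "start", "end", "enrichment_a",
                 "enrichment_b", "low_signal", "p_value", "direction"],
    )
    calls = call_rdmg(significant, annotation, half_width, mark, contrast)
    return merged, table, calls
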