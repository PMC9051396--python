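"""TSS-centered read profiles and peak-location summaries.

The metaprofile bins read midpoints by their signed offset from each gene's
TSS within +/- half_width (default 5 kb); offsets of minus-strand genes are
negated so positive always means downstream of transcription.  A read
falling in the windows of several genes contributes to each by default
(multiplicity counting); single-assignment (nearest TSS) is available.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import GeneAnnotation, Peak
from .pdmg import promoter_window


@dataclass
class TSSProfile:
    mark: str
    sample_id: str
    half_width: int
    bin_width: int
    bin_values: np.ndarray  # length ceil(2*half_width / bin_width)

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each bin, relative to the TSS."""
        return -self.half_width + self.bin_width * np.arange(len(self.bin_values))


def tss_read_profile(
    reads: Dict[str, np.ndarray],
    annotation: Sequence[GeneAnnotation],
    half_width: int = 5000,
    bin_width: int = 100,
    mark: str = "",
    sample_id: str = "",
    per_million: bool = False,
    multiplicity: bool = True,
) -> TSSProfile:
    """Sum reads within [tss - half_width, tss + half_width) over all genes.

    With ``per_million`` the profile is scaled by 1e6 / total reads in the
    sample.  With ``multiplicity=False`` each read counts only toward its
    nearest TSS.
    """
    n_bins = math.ceil(2 * half_width / bin_width)
    values = np.zeros(n_bins)
    tss_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for g in annotation:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, 1 if g.strand == "+" else -1))
    total_reads = sum(len(v) for v in reads.values())
    for chrom, entries in tss_by_chrom.items():
        pos = np.sort(np.asarray(reads.get(chrom, np.array([], dtype=np.int64))))
        if pos.size == 0:
            continue
        if multiplicity:
            for tss, sign in entries:
                lo = np.searchsorted(pos, tss - half_width, side="left")
                hi = np.searchsorted(pos, tss + half_width, side="left")
                offsets = (pos[lo:hi] - tss) * sign
                idx = (offsets + half_width) // bin_width
                np.add.at(values, np.clip(idx, 0, n_bins - 1), 1)
        else:
            tss_arr = np.array([t for t, _ in entries])
            sign_arr = np.array([s for _, s in entries])
            order = np.argsort(tss_arr)
            tss_arr, sign_arr = tss_arr[order], sign_arr[order]
            j = np.clip(np.searchsorted(tss_arr, pos), 0, len(tss_arr) - 1)
            j_left = np.clip(j - 1, 0, len(tss_arr) - 1)
            nearer_left = np.abs(pos - tss_arr[j_left]) <= np.abs(pos - tss_arr[j])
            j = np.where(nearer_left, j_left, j)
            offsets = (pos - tss_arr[j]) * sign_arr[j]
            keep = np.abs(offsets) <= half_width
            keep &= offsets < half_width  # half-open on the right
            idx = (offsets[keep] + half_width) // bin_width
            np.add.at(values, np.clip(idx, 0, n_bins - 1), 1)
    if per_million and total_reads > 0:
        values = values * 1e6 / total_reads
    return TSSProfile(mark, sample_id, half_width, bin_width, values)


def peak_tss_fraction(
    peaks: Sequence[Peak],
    annotation: Sequence[GeneAnnotation],
    half_width: int = 2500,
    summit_mode: bool = False,
) -> Optional[float]:
    """Percentage of peaks within +/- half_width of any TSS.

    A peak qualifies when it overlaps some gene's window by >= 1 bp; with
    ``summit_mode`` its summit (or midpoint when absent) must lie inside.
    Returns None when there are no peaks.
    """
    if len(peaks) == 0:
        return None
    windows = [promoter_window(g, half_width) for g in annotation]
    by_chrom: Dict[str, List] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    hits = 0
    for p in peaks:
        cand = by_chrom.get(p.interval.chrom, [])
        if summit_mode:
            point = (
                p.interval.start + p.summit_offset
                if p.summit_offset is not None
                else (p.interval.start + p.interval.end) // 2
            )
            ok = any(w.start <= point < w.end for w in cand)
        else:
            ok = any(p.interval.overlaps(w) for w in cand)
        hits += ok
    return 100.0 * hits / len(peaks)
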