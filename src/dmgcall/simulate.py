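"""Synthetic ChIP/RNA experiment generator with planted ground truth.

Emulates a paired-hemisphere brain-injury design: two age groups, injured
(ipsilateral) vs control (contralateral) hemisphere, three promoter histone
marks (H3K4me3, H3K27me3, H3K9ac) plus input chromatin with two ChIP
replicates, and RNA-seq with three replicates per group.  Differential
expression is planted as a log2 fold change on a chosen fraction of genes,
preferentially drawn from a designated "inflammation" gene set; promoter
mark gains and losses are planted on true DEGs.  Every generated object is
a pure function of the configuration (including its seed), and the planted
truth is exported separately so inference stages never see it.

Noise models: negative binomial for RNA counts, Poisson for ChIP reads in
peaks, uniform placement for background peaks.  ChIP replicates share one
peak set per condition and differ only in read noise, mirroring the high
replicate concordance such experiments show.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import GeneAnnotation, GenomicInterval, CountMatrix, Peak, SampleDesign


class ConfigurationError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


MARKS = ("H3K4me3", "H3K27me3", "H3K9ac")

#: Baseline fraction of promoters carrying each mark; ordered to mirror the
#: usual TSS occupancy ranking (H3K4me3 most promoters, H3K27me3 fewest).
DEFAULT_OCCUPANCY = {"H3K4me3": 0.55, "H3K27me3": 0.15, "H3K9ac": 0.35}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_lengths: Optional[Tuple[int, ...]] = None  # default 20 Mb each
    n_genes: int = 500
    gene_length_range: Tuple[int, int] = (1_000, 5_000)
    age_groups: Tuple[str, ...] = ("13m", "22m")
    n_rna_replicates: int = 3
    n_chip_replicates: int = 2
    frac_deg: float = 0.10
    frac_deg_down: float = 0.0  # fraction of planted DEGs that go down
    lfc: float = 2.0
    nb_dispersion: float = 0.05
    mean_expression: float = 100.0
    inflammation_frac: float = 0.10
    inflammation_weight: float = 5.0
    # per mark: (fraction of DEGs with planted gain, with planted loss)
    planted_redistribution: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "H3K4me3": (0.5, 0.1),
            "H3K27me3": (0.1, 0.4),
            "H3K9ac": (0.5, 0.1),
        }
    )
    # "presence": a planted gain exists only in ipsi (and a loss only in
    # contra); "density": the peak exists in both conditions and the read
    # rate is multiplied by density_fold in the condition that gained it.
    redistribution_mode: str = "presence"
    density_fold: float = 4.0
    mark_occupancy: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    peak_width: int = 800
    peak_jitter: int = 500
    peak_background_rate: float = 3.0  # peaks per Mb, off-promoter
    fold_enrichment_range: Tuple[float, float] = (4.5, 12.0)
    background_fold_range: Tuple[float, float] = (1.0, 8.0)
    reads_per_peak_mean: float = 100.0
    input_rate: float = 10.0  # expected input reads per peak region
    # mark changes are planted only at genes whose TSS is at least this far
    # from every other TSS, so a planted presence/absence event cannot be
    # masked by (or bleed into) a neighbouring promoter window
    plant_isolation_bp: int = 8_000

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            self.chrom_lengths = tuple([20_000_000] * self.n_chroms)
        self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(self.chrom_lengths) != self.n_chroms:
            raise ConfigurationError("chrom_lengths length must equal n_chroms")
        if not (0.0 <= self.frac_deg <= 1.0):
            raise ConfigurationError("frac_deg must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for name in ("n_chroms", "n_genes", "n_rna_replicates", "n_chip_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.redistribution_mode not in ("presence", "density"):
            raise ConfigurationError("redistribution_mode must be presence|density")


@dataclass
class SimulationTruth:
    """The planted events: the oracle every recovery test is scored against."""

    true_degs: Dict[str, str] = field(default_factory=dict)  # gene -> up|down
    # (gene, mark) -> gain|loss ; absence means "none"
    true_mark_changes: Dict[Tuple[str, str], str] = field(default_factory=dict)
    inflammation_set: Set[str] = field(default_factory=set)

    def mark_gains(self, mark: str) -> Set[str]:
        return {g for (g, m), v in self.true_mark_changes.items() if m == mark and v == "gain"}

    def mark_losses(self, mark: str) -> Set[str]:
        return {g for (g, m), v in self.true_mark_changes.items() if m == mark and v == "loss"}


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stage])


def chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def simulate_genome(config: SimulationConfig) -> Tuple[List[GeneAnnotation], SimulationTruth]:
    """Place non-overlapping genes uniformly on the configured chromosomes.

    Genes are assigned to chromosomes nearly evenly, given random widths and
    strands, and packed left to right with random gaps.  Returns the
    annotation plus a truth skeleton holding only the inflammation set.
    """
    rng = _stage_rng(config, 0)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: List[GeneAnnotation] = []
    gid = 0
    lo, hi = config.gene_length_range
    for ci, (n_c, length) in enumerate(zip(per_chrom, config.chrom_lengths)):
        if n_c == 0:
            continue
        widths = rng.integers(lo, hi + 1, size=n_c)
        slack = length - int(widths.sum())
        if slack < 0:
            raise ConfigurationError(
                f"{chrom_name(ci)}: total gene span {widths.sum()} exceeds "
                f"chromosome length {length}"
            )
        gaps = np.sort(rng.integers(0, slack + 1, size=n_c))
        starts = gaps + np.concatenate([[0], np.cumsum(widths[:-1])])
        strands = rng.choice(["+", "-"], size=n_c)
        for w, s, st in zip(widths, starts, strands):
            genes.append(
                GeneAnnotation(
                    f"g{gid:05d}",
                    GenomicInterval(chrom_name(ci), int(s), int(s + w)),
                    str(st),
                )
            )
            gid += 1
    truth = SimulationTruth()
    n_inflam = int(round(config.inflammation_frac * config.n_genes))
    ids = [g.gene_id for g in genes]
    truth.inflammation_set = set(rng.choice(ids, size=n_inflam, replace=False))
    return genes, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float, size) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def rna_sample_id(age: str, hemi: str, rep: int) -> str:
    return f"rna_{age}_{hemi}_{rep}"


def chip_sample_id(mark: str, age: str, hemi: str, rep: int) -> str:
    return f"{mark}_{age}_{hemi}_{rep}"


def simulate_expression_counts(
    annotation: Sequence[GeneAnnotation],
    config: SimulationConfig,
    truth: Optional[SimulationTruth] = None,
) -> Tuple[CountMatrix, SimulationTruth]:
    """Draw NB counts with planted up-regulation in the ipsilateral group.

    Exactly ``round(frac_deg * n_genes)`` genes are flagged as DEGs, drawn
    preferentially from the inflammation set (weight
    ``inflammation_weight``).  Planted DEGs have ipsilateral mean
    ``mean_expression * 2**lfc`` (or ``2**-lfc`` for the down fraction) in
    every age group; all other gene/sample means are ``mean_expression``.
    """
    rng = _stage_rng(config, 1)
    if truth is None:
        truth = SimulationTruth()
    ids = [g.gene_id for g in annotation]
    n_deg = int(round(config.frac_deg * len(ids)))
    weights = np.array(
        [config.inflammation_weight if g in truth.inflammation_set else 1.0 for g in ids]
    )
    weights /= weights.sum()
    deg_ids = list(rng.choice(ids, size=n_deg, replace=False, p=weights)) if n_deg else []
    n_down = int(round(config.frac_deg_down * n_deg))
    truth.true_degs = {}
    for i, g in enumerate(deg_ids):
        truth.true_degs[g] = "down" if i < n_down else "up"
    if config.lfc == 0:
        truth.true_degs = {}
        deg_ids = []

    mu_contra = np.full(len(ids), config.mean_expression)
    mu_ipsi = mu_contra.copy()
    for g, direction in truth.true_degs.items():
        j = ids.index(g)
        mu_ipsi[j] = config.mean_expression * 2.0 ** (
            config.lfc if direction == "up" else -config.lfc
        )

    sample_ids: List[str] = []
    cols: List[np.ndarray] = []
    for age in config.age_groups:
        for hemi, mu in (("ipsi", mu_ipsi), ("contra", mu_contra)):
            for rep in range(1, config.n_rna_replicates + 1):
                sample_ids.append(rna_sample_id(age, hemi, rep))
                cols.append(_nb_draw(rng, mu, config.nb_dispersion, len(ids)))
    counts = np.column_stack(cols).astype(np.int64)
    return CountMatrix(ids, sample_ids, counts), truth


def _isolated_genes(
    annotation: Sequence[GeneAnnotation], min_distance: int
) -> Set[str]:
    out: Set[str] = set()
    by_chrom: Dict[str, List[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes = sorted(genes, key=lambda g: g.tss)
        for i, g in enumerate(genes):
            left_ok = i == 0 or g.tss - genes[i - 1].tss >= min_distance
            right_ok = i == len(genes) - 1 or genes[i + 1].tss - g.tss >= min_distance
            if left_ok and right_ok:
                out.add(g.gene_id)
    return out


def _plant_mark_changes(
    config: SimulationConfig,
    truth: SimulationTruth,
    rng: np.random.Generator,
    eligible: Set[str],
) -> None:
    deg_ids = sorted(set(truth.true_degs) & eligible)
    truth.true_mark_changes = {}
    for mark in MARKS:
        fg, fl = config.planted_redistribution.get(mark, (0.0, 0.0))
        n_gain = int(round(fg * len(deg_ids)))
        n_loss = int(round(fl * len(deg_ids)))
        if n_gain + n_loss > len(deg_ids):
            raise ConfigurationError(f"{mark}: gain+loss fractions exceed the DEG set")
        chosen = rng.choice(deg_ids, size=n_gain + n_loss, replace=False) if deg_ids else []
        for g in chosen[:n_gain]:
            truth.true_mark_changes[(str(g), mark)] = "gain"
        for g in chosen[n_gain:]:
            truth.true_mark_changes[(str(g), mark)] = "loss"


def simulate_mark_peaks(
    annotation: Sequence[GeneAnnotation],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> Tuple[Dict[str, List[Peak]], Dict[str, Dict[str, np.ndarray]]]:
    """Generate per-sample peak lists and read midpoints for all marks + input.

    One promoter peak geometry (position near the TSS, width, fold
    enrichment) is drawn per (gene, mark) and reused in every condition and
    replicate where the gene carries the mark, so absent planted changes the
    ipsi and contra peak sets are identical and replicates differ only in
    Poisson read noise.  Background peaks are scattered uniformly per
    (age, mark) condition at ``peak_background_rate`` per Mb.  Input samples
    receive Poisson reads at ``input_rate`` over every peak region of their
    condition.
    """
    rng = _stage_rng(config, 2)
    if not truth.true_mark_changes and any(
        f > 0 for fr in config.planted_redistribution.values() for f in fr
    ) and truth.true_degs:
        _plant_mark_changes(
            config, truth, rng, _isolated_genes(annotation, config.plant_isolation_bp)
        )
    ids = [g.gene_id for g in annotation]
    by_id = {g.gene_id: g for g in annotation}
    chrom_len = {chrom_name(i): L for i, L in enumerate(config.chrom_lengths)}
    genome_mb = sum(config.chrom_lengths) / 1e6
    mean_fold = float(np.mean(config.fold_enrichment_range))

    # one geometry per (gene, mark), shared across all conditions
    geometry: Dict[Tuple[str, str], Peak] = {}
    carriers: Dict[str, Set[str]] = {}
    for mark in MARKS:
        occ = config.mark_occupancy.get(mark, 0.0)
        base = {g for g in ids if rng.random() < occ}
        carriers[mark] = base
        for g in ids:
            gene = by_id[g]
            L = chrom_len[gene.chrom]
            center = gene.tss + int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            start = max(0, center - config.peak_width // 2)
            end = min(L, start + config.peak_width)
            start = min(start, end - 1)  # peak truncated at chromosome edge
            fold = float(rng.uniform(*config.fold_enrichment_range))
            geometry[(g, mark)] = Peak(GenomicInterval(gene.chrom, start, end), "", fold)

    peaks_by_sample: Dict[str, List[Peak]] = {}
    reads_by_sample: Dict[str, Dict[str, np.ndarray]] = {}

    def _draw_reads(peaks: List[Peak], lam: np.ndarray) -> Dict[str, np.ndarray]:
        out: Dict[str, List[np.ndarray]] = {}
        ns = rng.poisson(lam)
        for p, n in zip(peaks, ns):
            if n == 0:
                continue
            pos = rng.integers(p.interval.start, p.interval.end, size=int(n))
            out.setdefault(p.interval.chrom, []).append(pos)
        return {
            c: np.sort(np.concatenate(v)).astype(np.int64) for c, v in out.items()
        }

    for age in config.age_groups:
        condition_regions: Dict[str, List[Peak]] = {"ipsi": [], "contra": []}
        for mark in MARKS:
            gains = truth.mark_gains(mark)
            losses = truth.mark_losses(mark)
            base = carriers[mark] - gains - losses
            if config.redistribution_mode == "presence":
                present = {
                    "ipsi": base | gains,
                    "contra": base | losses,
                }
            else:  # density: peak present everywhere, rate modulated below
                present = {
                    "ipsi": base | gains | losses,
                    "contra": base | gains | losses,
                }
            # background peaks per (age, mark) condition, shared by replicates
            for hemi in ("ipsi", "contra"):
                n_bg = rng.poisson(config.peak_background_rate * genome_mb)
                bg: List[Peak] = []
                for _ in range(int(n_bg)):
                    ci = int(rng.integers(0, config.n_chroms))
                    L = config.chrom_lengths[ci]
                    s = int(rng.integers(0, max(1, L - config.peak_width)))
                    bg.append(
                        Peak(
                            GenomicInterval(chrom_name(ci), s, s + config.peak_width),
                            "",
                            float(rng.uniform(*config.background_fold_range)),
                        )
                    )
                cond_peaks = [geometry[(g, mark)] for g in sorted(present[hemi])] + bg
                lam = np.array(
                    [config.reads_per_peak_mean * p.fold_enrichment / mean_fold for p in cond_peaks]
                )
                if config.redistribution_mode == "density":
                    for i, g in enumerate(sorted(present[hemi])):
                        if (g in gains and hemi == "ipsi") or (g in losses and hemi == "contra"):
                            lam[i] *= config.density_fold
                for rep in range(1, config.n_chip_replicates + 1):
                    sid = chip_sample_id(mark, age, hemi, rep)
                    peaks_by_sample[sid] = [
                        Peak(p.interval, sid, p.fold_enrichment, p.summit_offset)
                        for p in cond_peaks
                    ]
                    reads_by_sample[sid] = _draw_reads(cond_peaks, lam)
                condition_regions[hemi].extend(cond_peaks)
        # input: uniform low-rate reads over every peak region of the condition
        for hemi in ("ipsi", "contra"):
            regions = condition_regions[hemi]
            lam = np.full(len(regions), config.input_rate)
            for rep in range(1, config.n_chip_replicates + 1):
                sid = chip_sample_id("input", age, hemi, rep)
                peaks_by_sample[sid] = []
                reads_by_sample[sid] = _draw_reads(regions, lam)
    return peaks_by_sample, reads_by_sample


def make_design(config: SimulationConfig) -> List[SampleDesign]:
    """The full sample-design table implied by the configuration."""
    designs: List[SampleDesign] = []
    for age in config.age_groups:
        for hemi in ("ipsi", "contra"):
            for rep in range(1, config.n_rna_replicates + 1):
                designs.append(
                    SampleDesign(rna_sample_id(age, hemi, rep), age, hemi, "rna", rep)
                )
            for assay in list(MARKS) + ["input"]:
                for rep in range(1, config.n_chip_replicates + 1):
                    designs.append(
                        SampleDesign(chip_sample_id(assay, age, hemi, rep), age, hemi, assay, rep)
                    )
    return designs


def export_truth(truth: SimulationTruth, path: str) -> None:
    """Write the planted truth as a TSV: kind, gene_id, mark, value."""
    with open(path, "w") as fh:
        fh.write("kind\tgene_id\tmark\tvalue\n")
        for g in sorted(truth.true_degs):
            fh.write(f"deg\t{g}\t.\t{truth.true_degs[g]}\n")
        for (g, m) in sorted(truth.true_mark_changes):
            fh.write(f"mark\t{g}\t{m}\t{truth.true_mark_changes[(g, m)]}\n")
        for g in sorted(truth.inflammation_set):
            fh.write(f"inflammation\t{g}\t.\t.\n")


def read_truth(path: str) -> SimulationTruth:
    truth = SimulationTruth()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "kind\tgene_id\tmark\tvalue":
            raise ValueError(f"{path}: unexpected truth header")
        for line in fh:
            kind, gene_id, mark, value = line.rstrip("\n").split("\t")
            if kind == "deg":
                truth.true_degs[gene_id] = value
            elif kind == "mark":
                truth.true_mark_changes[(gene_id, mark)] = value
            elif kind == "inflammation":
                truth.inflammation_set.add(gene_id)
            else:
                raise ValueError(f"{path}: unknown truth kind {kind!r}")
    return truth
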