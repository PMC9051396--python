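"""End-to-end orchestration: simulate -> DEG -> cluster -> pDMG -> rDMG ->
TSS profiles -> set association, with every table written under one output
directory and regenerable bit-identically from (config, seed).

The universe for all association tests defaults to genes with a non-zero
total RNA count (the expressed universe).
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .clustering import cluster_degs
from .expression import call_degs, results_to_frame
from .model import CountMatrix, GeneAnnotation, Peak, SampleDesign, ValidationError
from .pdmg import call_pdmg, mark_positive_genes
from .profiles import peak_tss_fraction, tss_read_profile
from .rdmg import rdmg_analysis
from .setstats import OverlapTestResult, fisher_association, hypergeometric_overlap, upset_counts
from .simulate import (
    MARKS,
    SimulationConfig,
    chip_sample_id,
    chrom_name,
    export_truth,
    make_design,
    simulate_expression_counts,
    simulate_genome,
    simulate_mark_peaks,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: Optional[SimulationConfig] = None
    # file-mode inputs (exactly one of simulation / these paths)
    annotation_path: Optional[str] = None
    counts_path: Optional[str] = None
    design_path: Optional[str] = None
    peaks_dir: Optional[str] = None  # {sample_id}.narrowPeak per ChIP sample
    reads_dir: Optional[str] = None  # {sample_id}.bed read midpoints
    chrom_lengths: Optional[Dict[str, int]] = None
    # thresholds, as applied throughout
    p_deg: float = 0.01
    fc: float = 2.0
    min_fold: float = 4.0
    pdmg_half_width: int = 5000
    rdmg_half_width: int = 3000
    tss_profile_half_width: int = 5000
    tss_fraction_half_width: int = 2500
    profile_bin_width: int = 100
    alpha_rdmg: float = 0.05
    seed: int = 0
    outdir: str = "dmgcall_out"

    def __post_init__(self) -> None:
        file_mode = self.annotation_path is not None
        if (self.simulation is None) == (not file_mode):
            raise ValidationError(
                "exactly one of a simulation config or input paths is required"
            )
        for name in ("p_deg", "fc", "min_fold", "pdmg_half_width",
                     "rdmg_half_width", "tss_profile_half_width",
                     "tss_fraction_half_width", "alpha_rdmg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.simulation is not None:
            self.simulation.seed = self.seed


@dataclass
class ReportBundle:
    manifest: Dict[str, object]
    deg_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    cluster_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    pdmg_tables: Dict[Tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    pdmg_counts: Optional[pd.DataFrame] = None
    rdmg_tables: Dict[Tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    rdmg_peak_tables: Dict[Tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    profile_tables: Dict[Tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    tss_fraction_table: Optional[pd.DataFrame] = None
    upset_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    association_table: Optional[pd.DataFrame] = None
    venn_table: Optional[pd.DataFrame] = None

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        for age, df in self.deg_tables.items():
            df.to_csv(os.path.join(outdir, f"deg_{age}.tsv"), sep="\t", index=False)
        for age, df in self.cluster_tables.items():
            df.to_csv(os.path.join(outdir, f"clusters_{age}.tsv"), sep="\t", index=False)
        for (mark, age), df in self.pdmg_tables.items():
            df.to_csv(os.path.join(outdir, f"pdmg_{mark}_{age}.tsv"), sep="\t", index=False)
        if self.pdmg_counts is not None:
            self.pdmg_counts.to_csv(os.path.join(outdir, "pdmg_counts.tsv"), sep="\t", index=False)
        for (mark, age), df in self.rdmg_tables.items():
            df.to_csv(os.path.join(outdir, f"rdmg_{mark}_{age}.tsv"), sep="\t", index=False)
        for (mark, age), df in self.rdmg_peak_tables.items():
            df.to_csv(os.path.join(outdir, f"rdmg_peaks_{mark}_{age}.tsv"), sep="\t", index=False)
        for (mark, age, hemi), df in self.profile_tables.items():
            df.to_csv(os.path.join(outdir, f"profile_{mark}_{age}_{hemi}.tsv"), sep="\t", index=False)
        if self.tss_fraction_table is not None:
            self.tss_fraction_table.to_csv(os.path.join(outdir, "tss_fraction.tsv"), sep="\t", index=False)
        for age, df in self.upset_tables.items():
            df.to_csv(os.path.join(outdir, f"upset_{age}.tsv"), sep="\t", index=False)
        if self.association_table is not None:
            self.association_table.to_csv(os.path.join(outdir, "association.tsv"), sep="\t", index=False)
        if self.venn_table is not None:
            self.venn_table.to_csv(os.path.join(outdir, "venn.tsv"), sep="\t", index=False)


def dual_gain_percentage(upregulated: Set[str], gains_a: Set[str], gains_b: Set[str]) -> float:
    """Percent of upregulated DEGs carrying gains of both marks."""
    if not upregulated:
        raise ValidationError("empty upregulated set")
    return 100.0 * len(upregulated & gains_a & gains_b) / len(upregulated)


def dual_mark_association(
    upregulated: Set[str],
    changes_a: Set[str],
    changes_b: Set[str],
    universe: Set[str],
) -> Tuple[List[List[int]], Optional[OverlapTestResult]]:
    """2x2 table of DEG status x dual-mark change status, with Fisher result.

    Returns (table, result); the result is None (explicit no-test marker)
    when a margin is degenerate, e.g. every gene in the universe is a DEG.
    """
    if not universe:
        raise ValidationError("empty universe")
    deg = upregulated & universe
    dual = changes_a & changes_b & universe
    a = len(deg & dual)
    b = len(deg - dual)
    c = len(dual - deg)
    d = len(universe - deg - dual)
    table = [[a, b], [c, d]]
    if len(deg) in (0, len(universe)) or len(dual) in (0, len(universe)):
        return table, None
    return table, fisher_association(table)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        annotation, truth = simulate_genome(sim)
        matrix, truth = simulate_expression_counts(annotation, sim, truth)
        peaks_by_sample, reads_by_sample = simulate_mark_peaks(annotation, truth, sim)
        design = make_design(sim)
        chrom_lengths = {chrom_name(i): L for i, L in enumerate(sim.chrom_lengths)}
        return annotation, matrix, design, peaks_by_sample, reads_by_sample, chrom_lengths, truth
    annotation = dio.read_gene_annotation(config.annotation_path)
    matrix = dio.read_count_matrix(config.counts_path)
    design = dio.read_design(config.design_path)
    peaks_by_sample: Dict[str, List[Peak]] = {}
    reads_by_sample: Dict[str, Dict[str, np.ndarray]] = {}
    for d in design:
        if d.assay == "rna":
            continue
        if config.peaks_dir is not None and d.assay != "input":
            path = os.path.join(config.peaks_dir, f"{d.sample_id}.narrowPeak")
            peaks_by_sample[d.sample_id] = dio.read_peaks(path, d.sample_id)
        if config.reads_dir is not None:
            path = os.path.join(config.reads_dir, f"{d.sample_id}.bed")
            if os.path.exists(path):
                reads_by_sample[d.sample_id] = dio.read_read_positions(path)
    chrom_lengths = config.chrom_lengths or {}
    return annotation, matrix, design, peaks_by_sample, reads_by_sample, chrom_lengths, None


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if hasattr(obj, "__dict__"):
            return {k: enc(v) for k, v in sorted(vars(obj).items())}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj
    blob = json.dumps(enc(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in dependency order and write the report tables."""
    os.makedirs(config.outdir, exist_ok=True)
    stage = "load-inputs"
    try:
        (annotation, matrix, design, peaks_by_sample, reads_by_sample,
         chrom_lengths, truth) = _load_inputs(config)
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "thresholds": {
                "p_deg": config.p_deg, "fc": config.fc, "min_fold": config.min_fold,
                "pdmg_half_width": config.pdmg_half_width,
                "rdmg_half_width": config.rdmg_half_width,
                "tss_profile_half_width": config.tss_profile_half_width,
                "tss_fraction_half_width": config.tss_fraction_half_width,
                "alpha_rdmg": config.alpha_rdmg,
            },
            "n_genes": len(annotation),
            "n_samples": len(design),
        }
        for k, v in manifest["thresholds"].items():
            logger.info("threshold %s = %s", k, v)
        bundle = ReportBundle(manifest=manifest)
        if truth is not None:
            export_truth(truth, os.path.join(config.outdir, "truth.tsv"))
            dio.write_gene_annotation(annotation, os.path.join(config.outdir, "annotation.bed"))
            dio.write_design(design, os.path.join(config.outdir, "design.tsv"))
            dio.write_count_matrix(matrix, os.path.join(config.outdir, "rna_counts.tsv"))

        ages = sorted({d.age_group for d in design})
        marks = [m for m in MARKS if any(d.assay == m for d in design)]

        stage = "differential-expression"
        up_by_age: Dict[str, Set[str]] = {}
        for age in ages:
            results = call_degs(
                matrix, design,
                {"age_group": age, "hemisphere": "contra"},
                {"age_group": age, "hemisphere": "ipsi"},
                p_threshold=config.p_deg, fc_threshold=config.fc,
            )
            bundle.deg_tables[age] = results_to_frame(results)
            up_by_age[age] = {r.gene_id for r in results if r.direction == "up"}

        stage = "locus-clustering"
        for age in ages:
            clusters = cluster_degs(annotation, up_by_age[age], chrom_lengths)
            bundle.cluster_tables[age] = pd.DataFrame(
                [(c.chrom, c.span.start, c.span.end, len(c.member_gene_ids),
                  ",".join(c.member_gene_ids)) for c in clusters],
                columns=["chrom", "start", "end", "n_genes", "gene_ids"],
            )

        stage = "pdmg"
        pdmg_by = {}
        count_rows = []
        for mark in marks:
            for age in ages:
                pooled = {}
                for hemi in ("ipsi", "contra"):
                    sids = [d.sample_id for d in design
                            if d.assay == mark and d.age_group == age and d.hemisphere == hemi]
                    peaks = [p for s in sids for p in peaks_by_sample.get(s, [])]
                    pooled[hemi] = mark_positive_genes(
                        peaks, annotation, config.pdmg_half_width, config.min_fold,
                        chrom_lengths or None,
                    )
                res = call_pdmg(pooled["ipsi"], pooled["contra"], mark, age)
                pdmg_by[(mark, age)] = res
                rows = (
                    [(g, "gained") for g in sorted(res.gained)]
                    + [(g, "lost") for g in sorted(res.lost)]
                    + [(g, "shared") for g in sorted(res.shared)]
                )
                bundle.pdmg_tables[(mark, age)] = pd.DataFrame(
                    rows, columns=["gene_id", "status"]
                )
                count_rows.append(
                    (mark, age, len(res.gained), len(res.lost), len(res.shared))
                )
        bundle.pdmg_counts = pd.DataFrame(
            count_rows, columns=["mark", "age_group", "gained", "lost", "shared"]
        )

        stage = "rdmg"
        rdmg_by: Dict[Tuple[str, str], Set[str]] = {}
        if reads_by_sample:
            for mark in marks:
                for age in ages:
                    def _sids(assay, hemi):
                        return [d.sample_id for d in design
                                if d.assay == assay and d.age_group == age
                                and d.hemisphere == hemi]
                    merged, table, calls = rdmg_analysis(
                        peaks_by_sample, reads_by_sample,
                        chip_a=_sids(mark, "contra"), chip_b=_sids(mark, "ipsi"),
                        input_a=_sids("input", "contra"), input_b=_sids("input", "ipsi"),
                        annotation=annotation,
                        half_width=config.rdmg_half_width, alpha=config.alpha_rdmg,
                        mark=mark, contrast="ipsi-vs-contra",
                    )
                    bundle.rdmg_peak_tables[(mark, age)] = table
                    bundle.rdmg_tables[(mark, age)] = pd.DataFrame(
                        [(c.gene_id, c.peak_index, c.p_value, c.direction) for c in calls],
                        columns=["gene_id", "peak_index", "p_value", "direction"],
                    )
                    rdmg_by[(mark, age)] = {c.gene_id for c in calls}

        stage = "tss-profiles"
        frac_rows = []
        for mark in marks:
            for age in ages:
                for hemi in ("ipsi", "contra"):
                    sids = [d.sample_id for d in design
                            if d.assay == mark and d.age_group == age and d.hemisphere == hemi]
                    pooled_reads: Dict[str, np.ndarray] = {}
                    for s in sids:
                        for c, v in reads_by_sample.get(s, {}).items():
                            pooled_reads[c] = np.concatenate([pooled_reads.get(c, np.array([], dtype=np.int64)), v])
                    prof = tss_read_profile(
                        pooled_reads, annotation,
                        config.tss_profile_half_width, config.profile_bin_width,
                        mark=mark, sample_id=f"{age}_{hemi}",
                    )
                    bundle.profile_tables[(mark, age, hemi)] = pd.DataFrame(
                        {"offset": prof.offsets, "reads": prof.bin_values}
                    )
                    per_sample = [
                        peak_tss_fraction(peaks_by_sample.get(s, []), annotation,
                                          config.tss_fraction_half_width)
                        for s in sids
                    ]
                    per_sample = [f for f in per_sample if f is not None]
                    pooled_peaks = [p for s in sids for p in peaks_by_sample.get(s, [])]
                    frac_rows.append(
                        (mark, age, hemi,
                         float(np.mean(per_sample)) if per_sample else np.nan,
                         peak_tss_fraction(pooled_peaks, annotation,
                                           config.tss_fraction_half_width)
                         if pooled_peaks else np.nan)
                    )
        bundle.tss_fraction_table = pd.DataFrame(
            frac_rows,
            columns=["mark", "age_group", "hemisphere",
                     "percent_within_tss_mean_of_samples", "percent_within_tss_pooled"],
        )

        stage = "set-association"
        expressed = {
            g for g, total in zip(matrix.row_ids, matrix.counts.sum(axis=1)) if total > 0
        }
        assoc_rows = []
        for age in ages:
            sets = {"DEG_up": up_by_age[age] & expressed}
            for mark in marks:
                res = pdmg_by[(mark, age)]
                sets[mark] = (set(res.gained) | set(res.lost)) & expressed
            up = upset_counts(sets) if len(sets) >= 2 else {}
            bundle.upset_tables[age] = pd.DataFrame(
                [("".join(map(str, pattern)), n) for pattern, n in sorted(up.items(), reverse=True)],
                columns=["pattern_" + "_".join(sets), "count"],
            )
            for m1, m2 in [("H3K4me3", "H3K9ac"), ("H3K27me3", "H3K9ac")]:
                if m1 not in marks or m2 not in marks:
                    continue
                g1 = set(pdmg_by[(m1, age)].gained) & expressed
                g2 = set(pdmg_by[(m2, age)].gained) & expressed
                c1 = (set(pdmg_by[(m1, age)].gained) | set(pdmg_by[(m1, age)].lost)) & expressed
                c2 = (set(pdmg_by[(m2, age)].gained) | set(pdmg_by[(m2, age)].lost)) & expressed
                table, fisher = dual_mark_association(
                    up_by_age[age] & expressed, c1, c2, expressed
                )
                upr = up_by_age[age] & expressed
                pct = dual_gain_percentage(upr, g1, g2) if upr else np.nan
                assoc_rows.append(
                    (age, m1, m2, table[0][0], table[0][1], table[1][0], table[1][1],
                     fisher.statistic if fisher else np.nan,
                     fisher.p_value if fisher else np.nan,
                     "ok" if fisher else "degenerate-margin", pct)
                )
        bundle.association_table = pd.DataFrame(
            assoc_rows,
            columns=["age_group", "mark_a", "mark_b", "deg_dual", "deg_only",
                     "dual_only", "neither", "odds_ratio", "fisher_p",
                     "status", "dual_gain_percent"],
        )
        if len(ages) == 2 and expressed:
            a, b = (up_by_age[ages[0]] & expressed), (up_by_age[ages[1]] & expressed)
            res = hypergeometric_overlap(len(a & b), len(a), len(b), len(expressed))
            bundle.venn_table = pd.DataFrame(
                [(ages[0], ages[1], len(a), len(b), len(a & b), len(expressed), res.p_value)],
                columns=["age_a", "age_b", "n_a", "n_b", "overlap", "universe", "hypergeom_p"],
            )

        bundle.write(config.outdir)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
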