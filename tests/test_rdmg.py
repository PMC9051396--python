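"""Peak merging, density normalization, log t-testing, and rDMG recovery."""
import math

import numpy as np
import pytest

from dmgcall.model import GeneAnnotation, GenomicInterval, Peak, ValidationError
from dmgcall.rdmg import (
    MergedPeak,
    count_reads_in_peaks,
    differential_peak_test,
    group_enrichment,
    merge_peaks_across_samples,
    normalize_density,
    rdmg_analysis,
    replicate_enrichments,
)
from dmgcall.simulate import (
    SimulationConfig,
    chip_sample_id,
    simulate_expression_counts,
    simulate_genome,
    simulate_mark_peaks,
)


def _peak(start, end, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), "s", 5.0)


def brute_force_merge(peaks):
    """O(n^2) overlap graph + connected components; returns sorted spans."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if peaks[i].interval.overlaps(peaks[j].interval):
                g.add_edge(i, j)
    spans = []
    for comp in nx.connected_components(g):
        ivs = [peaks[i].interval for i in comp]
        spans.append((ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)))
    return sorted(spans)


class TestMerge:
    def test_simple_union(self):
        merged = merge_peaks_across_samples([_peak(100, 200), _peak(150, 300)])
        assert [(m.interval.start, m.interval.end) for m in merged] == [(100, 300)]

    def test_bookended_stay_separate(self):
        merged = merge_peaks_across_samples([_peak(100, 200), _peak(200, 300)])
        assert len(merged) == 2

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            peaks = []
            for _ in range(n):
                s = int(rng.integers(0, 2_000))
                peaks.append(_peak(s, s + int(rng.integers(1, 300)),
                                   chrom=str(rng.choice(["chr1", "chr2"]))))
            merged = merge_peaks_across_samples(peaks)
            got = sorted((m.interval.chrom, m.interval.start, m.interval.end) for m in merged)
            assert got == brute_force_merge(peaks)

    def test_idempotence_and_disjointness(self):
        rng = np.random.default_rng(43)
        peaks = [_peak(int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 5_000, 200), rng.integers(1, 400, 200))]
        merged = merge_peaks_across_samples(peaks)
        again = merge_peaks_across_samples(
            [Peak(m.interval, "m", 5.0) for m in merged]
        )
        assert [m.interval for m in again] == [m.interval for m in merged]
        for a, b in zip(merged, merged[1:]):
            assert a.interval.end <= b.interval.start or a.interval.chrom != b.interval.chrom

    def test_source_ids_cover_all_inputs(self):
        peaks = [_peak(0, 10), _peak(5, 20), _peak(100, 110)]
        merged = merge_peaks_across_samples(peaks)
        assert sorted(i for m in merged for i in m.source_ids) == [0, 1, 2]


class TestCounting:
    def test_membership_and_boundary(self):
        m = [MergedPeak(GenomicInterval("chr1", 100, 200))]
        reads = {"s1": {"chr1": np.array([99, 100, 150, 199, 200, 500])}}
        count_reads_in_peaks(m, reads)
        # 100, 150, 199 inside; 99 before; 200 is the end coordinate (excluded)
        assert m[0].raw_counts["s1"] == 3

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(47)
        peaks = [_peak(int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 10_000, 30), rng.integers(1, 500, 30))]
        merged = merge_peaks_across_samples(peaks)
        pos = rng.integers(0, 11_000, size=2_000)
        reads = {"s": {"chr1": pos}}
        count_reads_in_peaks(merged, reads)
        for m in merged:
            expected = int(np.sum((pos >= m.interval.start) & (pos < m.interval.end)))
            assert m.raw_counts["s"] == expected

    def test_count_conservation_over_union(self):
        rng = np.random.default_rng(53)
        peaks = [_peak(int(s), int(s) + 200) for s in rng.integers(0, 5_000, 50)]
        merged = merge_peaks_across_samples(peaks)
        pos = rng.integers(0, 6_000, size=3_000)
        reads = {"s": {"chr1": pos}}
        count_reads_in_peaks(merged, reads)
        in_union = sum(
            1 for p in pos
            if any(m.interval.start <= p < m.interval.end for m in merged)
        )
        assert sum(m.raw_counts["s"] for m in merged) == in_union


class TestDensity:
    @pytest.mark.parametrize(
        "count,lib,kb,expected",
        [(100, 10**7, 2.0, 5.0), (0, 10**6, 1.0, 0.0)],
    )
    def test_formula(self, count, lib, kb, expected):
        assert normalize_density(count, lib, kb) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert normalize_density(100, 10**6, 2.0) == pytest.approx(
            normalize_density(200, 2 * 10**6, 2.0)
        )

    def test_zero_width_region_rejected(self):
        with pytest.raises(ValidationError):
            normalize_density(1, 100, 0.0)


class TestEnrichment:
    def test_mean_minus_input(self):
        assert group_enrichment([5, 7], 2) == (4.0, False)

    def test_floor_and_flag_when_input_dominates(self):
        enr, low = group_enrichment([1, 1], 5, epsilon=1e-3)
        assert enr == 1e-3 and low

    def test_zero_input_gives_plain_mean(self):
        assert group_enrichment([4, 6], 0) == (5.0, False)

    def test_replicate_level_flooring(self):
        out = replicate_enrichments([1.0, 10.0], 5.0, epsilon=1e-3)
        assert out[0] == 1e-3 and out[1] == 5.0


def t_test_oracle(xs, ys):
    """Textbook pooled-variance two-sample t with the symmetric tail p."""
    from scipy.stats import t as tdist

    nx, ny = len(xs), len(ys)
    mx, my = np.mean(xs), np.mean(ys)
    sp2 = (np.sum((xs - mx) ** 2) + np.sum((ys - my) ** 2)) / (nx + ny - 2)
    tstat = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * tdist.sf(abs(tstat), nx + ny - 2)


class TestDifferentialTest:
    def test_identical_sides_give_p_one(self):
        p, _ = differential_peak_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            a = rng.lognormal(0, 0.5, size=3)
            b = rng.lognormal(0.4, 0.5, size=3)
            p, _ = differential_peak_test(a, b)
            assert p == pytest.approx(t_test_oracle(np.log(a), np.log(b)), abs=1e-12)

    def test_direction_follows_mean_difference(self):
        p, d = differential_peak_test([1.0, 1.1], [4.0, 4.4])
        assert d == "gained"
        p, d = differential_peak_test([4.0, 4.4], [1.0, 1.1])
        assert d == "lost"

    def test_label_swap_preserves_p_and_flips_direction(self):
        rng = np.random.default_rng(67)
        a, b = rng.lognormal(0, 1, 2), rng.lognormal(1, 1, 2)
        pa, da = differential_peak_test(a, b)
        pb, db = differential_peak_test(b, a)
        assert pa == pytest.approx(pb, abs=1e-12)
        assert {da, db} == {"gained", "lost"}

    def test_null_type_one_error(self):
        """Log-normal null, 2v2: fraction p < 0.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(71)
        hits = 0
        n = 5_000
        for _ in range(n):
            a = rng.lognormal(0, 0.5, size=2)
            b = rng.lognormal(0, 0.5, size=2)
            p, _ = differential_peak_test(a, b)
            hits += p < 0.05
        assert 0.03 <= hits / n <= 0.07


class TestEndToEndRecovery:
    def test_planted_density_gains_recovered(self):
        """Density-mode planting (fold 4, low noise): rDMG sensitivity >= 0.9."""
        cfg = SimulationConfig(
            seed=83, n_genes=200, frac_deg=0.25, redistribution_mode="density",
            density_fold=4.0, reads_per_peak_mean=200.0, age_groups=("13m",),
            planted_redistribution={"H3K4me3": (0.5, 0.0), "H3K27me3": (0.0, 0.0),
                                    "H3K9ac": (0.0, 0.0)},
        )
        ann, truth = simulate_genome(cfg)
        _, truth = simulate_expression_counts(ann, cfg, truth)
        peaks, reads = simulate_mark_peaks(ann, truth, cfg)

        def sids(assay, hemi):
            return [chip_sample_id(assay, "13m", hemi, r) for r in (1, 2)]

        merged, table, calls = rdmg_analysis(
            peaks, reads,
            chip_a=sids("H3K4me3", "contra"), chip_b=sids("H3K4me3", "ipsi"),
            input_a=sids("input", "contra"), input_b=sids("input", "ipsi"),
            annotation=ann, mark="H3K4me3",
        )
        gained_calls = {c.gene_id for c in calls if c.direction == "gained"}
        gains = truth.mark_gains("H3K4me3")
        assert gains
        sens = len(gained_calls & gains) / len(gains)
        assert sens >= 0.9

    def test_missing_input_rejected(self):
        with pytest.raises(ValidationError):
            rdmg_analysis({}, {}, chip_a=["a"], chip_b=["b"], input_a=[], input_b=[],
                          annotation=[])
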