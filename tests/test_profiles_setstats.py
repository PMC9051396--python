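"""TSS metaprofiles, peak-near-TSS fractions, and the exact set tests."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmgcall.model import GeneAnnotation, GenomicInterval, Peak, ValidationError
from dmgcall.profiles import peak_tss_fraction, tss_read_profile
from dmgcall.setstats import (
    fisher_association,
    geneset_enrichment,
    hypergeometric_overlap,
    ks_compare_profiles,
    upset_counts,
)


def _gene(gene_id, tss, strand="+", chrom="chr1"):
    if strand == "+":
        return GeneAnnotation(gene_id, GenomicInterval(chrom, tss, tss + 1_000), strand)
    return GeneAnnotation(gene_id, GenomicInterval(chrom, tss - 999, tss + 1), strand)


class TestTSSProfile:
    def test_reads_at_tss_spike_center_bin(self):
        genes = [_gene("a", 50_000), _gene("b", 90_000)]
        reads = {"chr1": np.array([50_000, 50_000, 90_000])}
        prof = tss_read_profile(reads, genes, half_width=5_000, bin_width=100)
        center = 5_000 // 100
        assert prof.bin_values[center] == 3
        assert prof.bin_values.sum() == 3

    def test_uniform_reads_give_flat_profile(self):
        genes = [_gene("a", 100_000)]
        rng = np.random.default_rng(5)
        reads = {"chr1": rng.integers(95_000, 105_000, size=60_000)}
        prof = tss_read_profile(reads, genes, half_width=5_000, bin_width=1_000)
        expected = 60_000 / 10
        assert np.all(np.abs(prof.bin_values - expected) < 5 * math.sqrt(expected))

    def test_conservation_with_multiplicity(self):
        # two genes with overlapping windows: a read between them counts twice
        genes = [_gene("a", 50_000), _gene("b", 53_000)]
        reads = {"chr1": np.array([51_500, 40_000, 51_500])}
        prof = tss_read_profile(reads, genes, half_width=5_000, bin_width=100)
        assert prof.bin_values.sum() == 4  # each in-window read, per window

    def test_minus_strand_offsets_are_negated(self):
        plus = [_gene("p", 50_000, "+")]
        minus = [_gene("m", 50_000, "-")]
        reads = {"chr1": np.array([50_000 + 2_000])}  # 2 kb right of the TSS
        prof_p = tss_read_profile(reads, plus, 5_000, 100)
        prof_m = tss_read_profile(reads, minus, 5_000, 100)
        # right of a minus-strand TSS is upstream: the bin mirrors
        assert np.argmax(prof_p.bin_values) == (5_000 + 2_000) // 100
        assert np.argmax(prof_m.bin_values) == (5_000 - 2_000) // 100

    def test_bin_count_invariant(self):
        prof = tss_read_profile({}, [_gene("a", 10_000)], half_width=5_000, bin_width=300)
        assert len(prof.bin_values) == math.ceil(10_000 / 300)


class TestPeakTSSFraction:
    def _peaks(self, centers, width=200):
        return [
            Peak(GenomicInterval("chr1", c - width // 2, c + width // 2), "s", 5.0)
            for c in centers
        ]

    def test_all_on_tss_gives_100(self):
        genes = [_gene("a", 50_000)]
        assert peak_tss_fraction(self._peaks([50_000, 50_100]), genes) == 100.0

    def test_none_near_tss_gives_0(self):
        genes = [_gene("a", 50_000)]
        assert peak_tss_fraction(self._peaks([80_000]), genes) == 0.0

    def test_fraction_matches_brute_force(self):
        genes = [_gene("a", 50_000)]
        # 3 of 10 within +-2.5 kb
        centers = [50_000, 51_000, 52_000] + [70_000 + i * 1_000 for i in range(7)]
        assert peak_tss_fraction(self._peaks(centers), genes) == pytest.approx(30.0)

    def test_no_peaks_returns_marker(self):
        assert peak_tss_fraction([], [_gene("a", 1_000)]) is None


class TestKS:
    def test_identical_samples_statistic_zero(self):
        res = ks_compare_profiles([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_disjoint_supports_statistic_one(self):
        res = ks_compare_profiles([0, 0], [1, 1])
        assert res.statistic == 1.0

    def test_statistic_matches_cdf_scan_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 60)
        grid = np.concatenate([a, b])
        d = max(
            abs(np.mean(a <= x) - np.mean(b <= x)) for x in grid
        )
        res = ks_compare_profiles(a, b)
        assert res.statistic == pytest.approx(d, abs=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            ks_compare_profiles([], [1.0])


def hypergeom_enumeration(k, n1, n2, N):
    """P(|A & B| >= k) by exhaustive enumeration of n2-subsets."""
    universe = list(range(N))
    marked = set(range(n1))
    total = hits = 0
    for draw in itertools.combinations(universe, n2):
        total += 1
        hits += len(marked & set(draw)) >= k
    return hits / total


class TestHypergeometric:
    def test_certain_event(self):
        assert hypergeometric_overlap(5, 5, 5, 5).p_value == 1.0

    def test_full_overlap_closed_form(self):
        res = hypergeometric_overlap(5, 5, 5, 10)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_k_zero_gives_p_one(self):
        assert hypergeometric_overlap(0, 3, 4, 10).p_value == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 12), st.data())
    def test_matches_enumeration_for_small_universes(self, N, data):
        n1 = data.draw(st.integers(0, N))
        n2 = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n1 + n2 - N), min(n1, n2)))
        res = hypergeometric_overlap(k, n1, n2, N)
        assert res.p_value == pytest.approx(hypergeom_enumeration(k, n1, n2, N), abs=1e-9)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_overlap(6, 5, 5, 10)


def fisher_enumeration(table):
    """Two-sided p by summing point probabilities <= observed over all
    tables with the observed margins."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = lambda x: hypergeom.pmf(x, n, r1, c1)
    obs = pmf(a)
    return sum(
        p for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if (p := pmf(x)) <= obs * (1 + 1e-9)
    )


class TestFisher:
    def test_independence_table(self):
        res = fisher_association([[5, 5], [5, 5]])
        assert res.statistic == 1.0 and res.p_value == 1.0

    @pytest.mark.parametrize(
        "table",
        [[[10, 0], [0, 10]], [[3, 7], [6, 2]], [[0, 5], [5, 0]], [[2, 2], [8, 1]]],
    )
    def test_matches_enumeration_oracle(self, table):
        res = fisher_association(table)
        assert res.p_value == pytest.approx(fisher_enumeration(table), abs=1e-9)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            t = rng.integers(0, 20, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_association(t).p_value == pytest.approx(
                fisher_association(t.T).p_value, rel=1e-9
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_association([[0, 0], [0, 0]])


class TestUpset:
    def test_disjoint_pair(self):
        counts = upset_counts({"A": {"x"}, "B": {"y"}})
        assert counts[(1, 0)] == 1 and counts[(0, 1)] == 1 and counts[(1, 1)] == 0

    def test_identical_sets_concentrate_on_all_ones(self):
        counts = upset_counts({"A": {"x", "y"}, "B": {"x", "y"}})
        assert counts[(1, 1)] == 2
        assert sum(v for k, v in counts.items() if k != (1, 1)) == 0

    def test_counts_match_per_element_classification(self):
        rng = np.random.default_rng(19)
        universe = [f"e{i}" for i in range(60)]
        sets = {
            name: {e for e in universe if rng.random() < p}
            for name, p in (("A", 0.4), ("B", 0.3), ("C", 0.5))
        }
        counts = upset_counts(sets)
        for pattern, n in counts.items():
            expected = sum(
                1 for e in set().union(*sets.values())
                if tuple(int(e in sets[k]) for k in sets) == pattern
            )
            assert n == expected
        assert sum(counts.values()) == len(set().union(*sets.values()))


class TestGenesetEnrichment:
    def test_planted_category_ranks_first(self):
        rng = np.random.default_rng(37)
        universe = {f"g{i}" for i in range(200)}
        planted = set(rng.choice(sorted(universe), size=25, replace=False))
        target = set(rng.choice(sorted(planted), size=15, replace=False)) | set(
            rng.choice(sorted(universe - planted), size=5, replace=False)
        )
        categories = {"planted": planted}
        for j in range(5):
            categories[f"random{j}"] = set(rng.choice(sorted(universe), size=25, replace=False))
        out = geneset_enrichment(target, categories, universe)
        assert out[0][0] == "planted"

    def test_disjoint_category_p_one(self):
        universe = {"a", "b", "c", "d"}
        out = geneset_enrichment({"a"}, {"cat": {"b", "c"}}, universe)
        assert out[0][2].p_value == pytest.approx(1.0)

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            geneset_enrichment({"z"}, {}, {"a"})
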