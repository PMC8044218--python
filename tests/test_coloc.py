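import numpy as np
import pytest

from repeat_regprof.coloc import (
    coloc_enrichment_matrix,
    element_pair_counts,
    merge_tf_sites,
    pairwise_coloc_counts,
    split_by_elements,
    two_proportion_ztest,
)
from repeat_regprof.config import AnalysisConfig
from repeat_regprof.simulate import FixtureSpec, simulate_elements, simulate_tf_sites

from conftest import make_element, make_interval, make_site, random_intervals
from oracles import oracle_intersect_fraction, oracle_union_bases


class TestMergeTfSites:
    def test_same_tf_merged_to_distal_coordinates(self):
        merged = merge_tf_sites({"A": [make_site(start=0, end=100),
                                       make_site(start=50, end=150)]})
        assert [(m.start, m.end) for m in merged["A"]] == [(0, 150)]

    def test_no_cross_tf_merging(self):
        merged = merge_tf_sites({"A": [make_site(start=0, end=100, tf="A")],
                                 "B": [make_site(start=50, end=150, tf="B")]})
        assert len(merged["A"]) == 1 and len(merged["B"]) == 1

    def test_base_coverage_preserved(self, rng):
        sites = {"A": random_intervals(rng, 100)}
        merged = merge_tf_sites(sites)
        assert oracle_union_bases(merged["A"]) == oracle_union_bases(sites["A"])


class TestSplitByElements:
    def elements(self):
        return [make_element(start=10_000, end=16_000)]

    def test_majority_inside_is_derived(self):
        site = make_site(start=9_960, end=10_060)  # 60% inside
        derived, rest = split_by_elements([site], self.elements(), 0.5)
        assert derived == [site] and rest == []

    def test_no_overlap_is_rest(self):
        site = make_site(start=50_000, end=50_100)
        derived, rest = split_by_elements([site], self.elements(), 0.5)
        assert derived == [] and rest == [site]

    def test_exact_partition(self, rng):
        sites = [make_site(start=int(p), end=int(p) + 100)
                 for p in rng.integers(0, 30_000, size=200)]
        derived, rest = split_by_elements(sites, self.elements(), 0.5)
        assert len(derived) + len(rest) == len(sites)
        ids = {id(s) for s in derived} | {id(s) for s in rest}
        assert len(ids) == len(sites)


class TestElementPairCounts:
    def test_direct_counts(self):
        e1 = make_element(start=10_000, end=16_000)
        e2 = make_element(start=30_000, end=36_000)
        sites = {"A": [make_site(start=11_000, end=11_100, tf="A"),
                       make_site(start=31_000, end=31_100, tf="A")],
                 "B": [make_site(start=11_500, end=11_600, tf="B")]}
        pc = element_pair_counts([e1, e2], sites, 0.5)
        a, b = pc.tfs.index("A"), pc.tfs.index("B")
        assert pc.matrix[a, b] == 1
        assert pc.matrix[a, a] == 2
        assert pc.matrix[b, b] == 1
        assert (pc.matrix == pc.matrix.T).all()

    def test_no_shared_elements(self):
        e1 = make_element(start=10_000, end=16_000)
        e2 = make_element(start=30_000, end=36_000)
        sites = {"A": [make_site(start=11_000, end=11_100, tf="A")],
                 "B": [make_site(start=31_000, end=31_100, tf="B")]}
        pc = element_pair_counts([e1, e2], sites, 0.5)
        assert pc.matrix[0, 1] == 0

    def test_matches_set_intersection_oracle(self, rng):
        elements = [make_element(start=int(s), end=int(s) + 6_000)
                    for s in range(10_000, 100_000, 12_000)]
        sites = {tf: [make_site(start=int(p), end=int(p) + 100, tf=tf)
                      for p in rng.integers(0, 110_000, size=60)]
                 for tf in ("A", "B", "C")}
        pc = element_pair_counts(elements, sites, 0.5)
        bound = {}
        for tf in pc.tfs:
            pairs = oracle_intersect_fraction(sites[tf], elements, 0.5)
            bound[tf] = {ti for _, ti in pairs}
        for i, ti in enumerate(pc.tfs):
            for j, tj in enumerate(pc.tfs):
                assert pc.matrix[i, j] == len(bound[ti] & bound[tj])

    def test_display_transform(self):
        pc = element_pair_counts([], {"A": [], "B": []}, 0.5)
        pc.matrix = np.array([[16, 81], [81, 0]])
        np.testing.assert_allclose(pc.transformed(), [[2, 3], [3, 0]])


class TestPairwiseColoc:
    def test_gap_arithmetic_and_symmetric_counts(self):
        sites = {"A": [make_interval(start=0, end=100)],
                 "B": [make_interval(start=550, end=600)]}
        tfs, counts, totals, props = pairwise_coloc_counts(sites, 500)
        a, b = tfs.index("A"), tfs.index("B")
        assert counts[a, b] == 1 and counts[b, a] == 1

    def test_asymmetric_proportions(self):
        sites = {"A": [make_interval(start=s, end=s + 100)
                       for s in (0, 10_000, 20_000, 30_000)],
                 "B": [make_interval(start=150, end=250)]}
        tfs, counts, totals, props = pairwise_coloc_counts(sites, 500)
        a, b = tfs.index("A"), tfs.index("B")
        assert props[a, b] == pytest.approx(0.25)
        assert props[b, a] == pytest.approx(1.0)
        # identity linking counts, totals and proportions
        assert props[a, b] * totals[a] == counts[a, b]

    def test_w_zero_disjoint(self):
        sites = {"A": [make_interval(start=0, end=100)],
                 "B": [make_interval(start=100, end=200)]}
        _, counts, _, _ = pairwise_coloc_counts(sites, 0)
        assert counts[0, 1] == 0


class TestTwoProportionZtest:
    def test_equal_proportions(self):
        z, p = two_proportion_ztest(10, 100, 50, 500)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_antisymmetry_under_group_swap(self):
        z1, p1 = two_proportion_ztest(60, 100, 400, 1000)
        z2, p2 = two_proportion_ztest(400, 1000, 60, 100)
        assert z2 == pytest.approx(-z1)
        assert p1 + p2 == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        k1, n1, k2, n2 = 60, 100, 500, 1000
        phat = (k1 + k2) / (n1 + n2)
        import math
        from scipy.stats import norm
        z_expected = (k1 / n1 - k2 / n2) / math.sqrt(
            phat * (1 - phat) * (1 / n1 + 1 / n2))
        z, p = two_proportion_ztest(k1, n1, k2, n2)
        assert z == pytest.approx(z_expected, rel=1e-12)
        assert p == pytest.approx(norm.sf(z_expected), rel=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest
        z_sm, p_sm = proportions_ztest([60, 500], [100, 1000],
                                       alternative="larger")
        z, p = two_proportion_ztest(60, 100, 500, 1000)
        assert z == pytest.approx(z_sm, rel=1e-9)
        assert p == pytest.approx(p_sm, rel=1e-9)

    def test_degenerate_pooled(self):
        assert two_proportion_ztest(0, 10, 0, 10) == (0.0, 0.5)
        assert two_proportion_ztest(10, 10, 10, 10) == (0.0, 0.5)

    def test_monotone_p_in_z(self):
        zs, ps = zip(*[two_proportion_ztest(k, 100, 300, 1000)
                       for k in (10, 30, 50, 70)])
        assert list(zs) == sorted(zs)
        assert list(ps) == sorted(ps, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(1, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_ztest(11, 10, 1, 10)


class TestEnrichmentMatrix:
    def test_bonferroni_threshold_for_nine_tfs(self, config):
        tfs = [f"TF{i}" for i in range(9)]
        sites = {tf: [make_interval(start=1000 * i, end=1000 * i + 100)]
                 for i, tf in enumerate(tfs)}
        m = coloc_enrichment_matrix(sites, sites, config)
        assert m.per_test_alpha == pytest.approx(0.05 / 81)
        assert round(m.per_test_alpha, 5) == pytest.approx(6.2e-4)

    def test_identical_groups_not_significant(self, config):
        sites = {tf: [make_interval(start=s, end=s + 100)
                      for s in range(0, 40_000, 4_000)]
                 for tf in ("A", "B", "C")}
        m = coloc_enrichment_matrix(sites, sites, config)
        assert not m.significant.any()

    def test_fewer_than_two_tfs_errors(self, config):
        with pytest.raises(ValueError):
            coloc_enrichment_matrix({"A": []}, {"A": []}, config)

    def test_mismatched_tf_lists_error(self, config):
        with pytest.raises(ValueError):
            coloc_enrichment_matrix({"A": [], "B": []}, {"A": [], "C": []},
                                    config)

    def test_planted_coupling_detected(self, config):
        """Element-restricted coupling between two TFs lights up exactly the
        coupled cells of the matrix."""
        spec = FixtureSpec(tf_names=("TFA", "TFB", "TFC"),
                           coupling={("TFA", "TFB"): 0.8},
                           five_prime_enrichment=1.0,
                           rng_seed=11)
        rng = np.random.default_rng(spec.rng_seed)
        elements = simulate_elements(spec, rng)
        sites = simulate_tf_sites(spec, elements, rng)
        merged = merge_tf_sites(sites)
        element_group, rest_group = {}, {}
        for tf, ss in merged.items():
            d, r = split_by_elements(ss, elements, 0.5)
            element_group[tf], rest_group[tf] = d, r
        m = coloc_enrichment_matrix(element_group, rest_group, config)
        a, b = m.tfs.index("TFA"), m.tfs.index("TFB")
        assert m.significant[a, b]
        assert m.z[a, b] > 0
        # cells whose column is the spawned TF carry a real planted signal
        # (TFB in-element density rises), so quiet cells exclude column b
        quiet = [(i, j) for i in range(3) for j in range(3)
                 if i != j and j != b and (i, j) != (b, a)]
        assert not any(m.significant[i, j] for i, j in quiet)

    def test_stars_tiers(self, config):
        sites = {tf: [make_interval(start=1000 * i, end=1000 * i + 100)]
                 for i, tf in enumerate(("A", "B", "C"))}
        m = coloc_enrichment_matrix(sites, sites, config)
        m.p = np.array([[np.nan, 1e-3, 1e-6],
                        [5e-4, np.nan, 2e-5],
                        [0.5, 1e-7, np.nan]])
        m.per_test_alpha = 6.2e-4
        stars = m.stars()
        assert stars[0][1] == ""       # above per-test alpha
        assert stars[1][0] == "*"      # below alpha/k^2 only
        assert stars[1][2] == "**"     # below 1e-4
        assert stars[0][2] == "***"    # below 1e-5
        assert stars[0][0] == ""       # diagonal untested
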