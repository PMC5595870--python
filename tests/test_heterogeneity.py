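"""Heterogeneity index, group comparisons, and cohort-level tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from preclone import heterogeneity as het

sets = st.sets(st.integers(0, 15), max_size=12)


class TestHeterogeneityIndex:
    def test_identical_sets(self):
        assert het.heterogeneity_index({1, 2, 3}, {1, 2, 3}) == 0.0

    def test_disjoint_sets(self):
        assert het.heterogeneity_index({1, 2}, {3, 4}) == 1.0

    def test_arithmetic(self):
        a, b = set(range(10)), set(range(5, 20))  # |A∩B|=5, |A∪B|=20
        assert het.heterogeneity_index(a, b) == pytest.approx(0.75)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            het.heterogeneity_index(set(), set())

    @settings(derandomize=True, max_examples=100)
    @given(a=sets, b=sets, c=sets)
    def test_jaccard_distance_properties(self, a, b, c):
        if not (a | b):
            return
        hab = het.heterogeneity_index(a, b)
        assert 0 <= hab <= 1
        assert hab == het.heterogeneity_index(b, a)
        assert (hab == 0) == (a == b)
        if (b | c) and (a | c):
            assert hab <= het.heterogeneity_index(a, c) + \
                het.heterogeneity_index(c, b) + 1e-12


class TestPairDistances:
    def test_identical_vectors(self):
        v = np.array([1, 0, 1, 1])
        d, _ = het.pair_distances(v, v)
        assert d == 0.0

    def test_disjoint_sets_distance(self):
        a = np.array([1, 1, 1, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 1, 1, 1, 1])
        d, dens = het.pair_distances(a, b)
        assert d == pytest.approx(np.sqrt(7))
        assert dens == 0.0

    def test_intersection_density(self):
        v = np.ones(30)
        _, dens = het.pair_distances(v, v, callable_mb=30.0)
        assert dens == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            het.pair_distances(np.ones(3), np.ones(4))


class TestGroupPairs:
    def presence(self, samples, n=6):
        rng = np.random.default_rng(1)
        return pd.DataFrame(rng.random((n, len(samples))) < 0.6,
                            index=[f"m{i}" for i in range(n)], columns=samples)

    def test_group_combinatorics(self):
        pres = self.presence(["C1", "C2", "L1"])
        pairs = het.group_pairs(pres, {"C1": "ESCC", "C2": "ESCC", "L1": "LD"})
        groups = sorted(p.group for p in pairs)
        assert groups == ["C-C", "C-D", "C-D"]

    def test_hd_counts_as_dysplasia(self):
        pres = self.presence(["H1", "L1"])
        (pair,) = het.group_pairs(pres, {"H1": "HD", "L1": "LD"})
        assert pair.group == "D-D"

    def test_normals_excluded(self):
        pres = self.presence(["N1", "C1", "C2"])
        pairs = het.group_pairs(pres, {"N1": "N", "C1": "ESCC", "C2": "ESCC"})
        assert len(pairs) == 1 and pairs[0].group == "C-C"

    def test_unknown_grade_names_sample(self):
        pres = self.presence(["C1", "Q1"])
        with pytest.raises(ValueError, match="Q1"):
            het.group_pairs(pres, {"C1": "ESCC", "Q1": "weird"})


class TestKruskalWallis:
    def test_all_equal_values(self):
        h, p = het.kruskal_wallis({"a": np.ones(5), "b": np.ones(5)})
        assert h == 0.0

    def test_hand_ranked_oracle(self):
        # three small groups, H computed from hand-assigned ranks (no ties)
        groups = {"g1": np.array([1.0, 2.0, 3.0]),
                  "g2": np.array([4.0, 5.0, 6.0]),
                  "g3": np.array([7.0, 8.0, 9.0])}
        n = 9
        rank_sums = {"g1": 1 + 2 + 3, "g2": 4 + 5 + 6, "g3": 7 + 8 + 9}
        h_manual = 12 / (n * (n + 1)) * sum(
            rs**2 / 3 for rs in rank_sums.values()) - 3 * (n + 1)
        h, p = het.kruskal_wallis(groups)
        assert h == pytest.approx(h_manual)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            het.kruskal_wallis({"a": np.array([1.0]), "b": np.array([])})


class TestTrunkBias:
    def test_matches_hypergeometric_enumeration(self):
        # 2x2 [[8,0],[10,10]]: enumerate all tables with fixed margins
        table = np.array([[8, 0], [10, 10]])
        res = het.trunk_bias_test(8, 0, 10, 10)
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        probs = {k: hypergeom.pmf(k, n, r1, c1)
                 for k in range(max(0, c1 - r2), min(r1, c1) + 1)}
        p_obs = probs[8]
        p_manual = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(p_manual, rel=1e-6)

    def test_background_matched_gene_not_significant(self):
        res = het.trunk_bias_test(5, 5, 50, 50)
        assert res.p_value > 0.99

    def test_trunk_enriched_gene(self):
        res = het.trunk_bias_test(8, 0, 50, 50)
        assert res.p_value < 0.05 and res.odds_ratio > 1

    def test_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            het.trunk_bias_test(0, 0, 10, 10)


class TestCooccurrencePermutation:
    def test_perfect_association_minimum_p(self):
        flags = np.array([True] * 10 + [False] * 10)
        obs, p = het.cooccurrence_permutation(flags, flags, n_perm=9999, seed=1)
        assert obs == 10
        assert p == pytest.approx(1 / 10000)

    def test_degenerate_margin(self):
        a = np.ones(10, dtype=bool)
        b = np.array([True] * 5 + [False] * 5)
        _, p = het.cooccurrence_permutation(a, b, n_perm=500, seed=2)
        assert p == 1.0

    def test_patient_block_option_runs(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(12) < 0.5, rng.random(12) < 0.5
        pids = np.repeat(["p1", "p2", "p3"], 4)
        _, p = het.cooccurrence_permutation(a, b, n_perm=200, seed=4,
                                            patient_ids=pids)
        assert 0 < p <= 1

    def test_bad_nperm(self):
        with pytest.raises(ValueError):
            het.cooccurrence_permutation(np.ones(4, bool), np.ones(4, bool),
                                         n_perm=0)


class TestTwoHit:
    def status(self, sid, group, n_mut, loh):
        return het.TwoHitStatus(sid, group, n_mut, loh)

    def test_exclusion_rule(self):
        st_ = self.status("s1", "TD", 2, False)
        assert st_.excluded and not st_.two_hit

    def test_mutation_without_loh_not_two_hit(self):
        st_ = self.status("s1", "TD", 1, False)
        assert not st_.two_hit and not st_.excluded

    def test_hand_tallied_fixture(self):
        statuses = (
            [self.status(f"td{i}", "TD", 1, True) for i in range(14)]
            + [self.status("td_x", "TD", 2, False)]          # excluded
            + [self.status("td_y", "TD", 1, False)]
            + [self.status(f"nt{i}", "NTD", 0, False) for i in range(8)]
        )
        res, summary = het.two_hit_analysis(statuses)
        assert res.table.tolist() == [[0, 8], [14, 1]]
        td = summary[summary.group == "TD"].iloc[0]
        assert (td.two_hit, td.no_two_hit, td.excluded) == (14, 1, 1)
        assert res.p_value < 0.001

    def test_order_invariance(self):
        statuses = [self.status(f"a{i}", "TD", 1, True) for i in range(5)] + \
                   [self.status(f"b{i}", "NTD", 0, False) for i in range(5)]
        res1, _ = het.two_hit_analysis(statuses)
        res2, _ = het.two_hit_analysis(statuses[::-1])
        assert res1.table.tolist() == res2.table.tolist()
        assert res1.p_value == res2.p_value

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            het.two_hit_analysis([self.status("s", "TD", 2, False)])


class TestCnaConcordance:
    def profile(self, ratios, cuts):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": cuts[:-1], "end": cuts[1:], "depth_ratio": ratios})

    def test_identical_profiles(self):
        a = self.profile([1.0, 2.0, 0.5], [0, 10, 20, 30])
        r, _ = het.cna_concordance(a, a.copy())
        assert r == pytest.approx(1.0)

    def test_flat_profile_undefined(self):
        a = self.profile([1.0, 1.0], [0, 10, 20])
        b = self.profile([1.0, 2.0], [0, 10, 20])
        r, _ = het.cna_concordance(a, b)
        assert np.isnan(r)

    def test_anticorrelated_matches_hand_computation(self):
        a = self.profile([1.0, 2.0, 3.0], [0, 10, 20, 30])
        b = self.profile([3.0, 2.0, 1.0], [0, 10, 20, 30])
        r, n = het.cna_concordance(a, b)
        assert n == 3
        assert r == pytest.approx(-1.0)

    def test_breakpoint_harmonization(self):
        a = self.profile([1.0, 2.0], [0, 15, 30])
        b = self.profile([1.0, 2.0], [0, 20, 30])
        r, n = het.cna_concordance(a, b)
        assert n == 3  # cut points 0/15/20/30

    def test_no_shared_territory(self):
        a = self.profile([1.0], [0, 10])
        b = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10],
                          "depth_ratio": [1.0]})
        with pytest.raises(ValueError):
            het.cna_concordance(a, b)
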