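import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omicsfuse import (MarkerPanel, OmicsMatrix, cluster_eigenvectors, composite_score,
                       holm_adjust, km_curve, logrank_test, pairwise_de,
                       wilcoxon_rank_sum)
from omicsfuse.cluster import ClusterAssignment
from omicsfuse.downstream import (BASAL_MARKERS, EPITHELIAL_MARKERS,
                                  MESENCHYMAL_MARKERS, emt_score)


def _expr_with_panel(z_basal, z_mes, z_epi, n_samples=1):
    genes = BASAL_MARKERS + MESENCHYMAL_MARKERS + EPITHELIAL_MARKERS
    row = ([z_basal] * len(BASAL_MARKERS) + [z_mes] * len(MESENCHYMAL_MARKERS)
           + [z_epi] * len(EPITHELIAL_MARKERS))
    vals = np.tile(row, (n_samples, 1)).astype(float)
    return OmicsMatrix(vals, [f"s{i}" for i in range(n_samples)], genes, "expression")


class TestCompositeScore:
    def test_panel_arithmetic(self):
        # 12 basal - (7 mesenchymal + 5 epithelial) genes
        assert composite_score(_expr_with_panel(1, 1, 1))[0] == pytest.approx(0.0)
        assert composite_score(_expr_with_panel(0, 0, 0))[0] == pytest.approx(0.0)
        assert composite_score(_expr_with_panel(1, -1, -1))[0] == pytest.approx(24.0)

    def test_missing_genes_skipped_and_all_missing_rejected(self):
        m = OmicsMatrix([[1.0, 2.0]], ["s"], ["KRT14", "NOT_A_MARKER"], "expression")
        assert composite_score(m)[0] == pytest.approx(1.0)
        bare = OmicsMatrix([[1.0]], ["s"], ["NOT_A_MARKER"], "expression")
        with pytest.raises(ValueError, match="no marker-panel genes"):
            composite_score(bare)

    def test_alias_map_remaps_symbols(self):
        panel = MarkerPanel().apply_aliases({"H1F1A": "HIF1A"})
        assert "HIF1A" in panel.basal and "H1F1A" not in panel.basal

    def test_emt_score_is_mesenchymal_minus_epithelial(self):
        assert emt_score(_expr_with_panel(0, 2, 1))[0] == pytest.approx(2 * 7 - 1 * 5)


class TestWilcoxon:
    def test_exact_enumeration_small_sample(self):
        u, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)  # 2 of C(4,2)=6 splits as extreme

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p == pytest.approx(1.0)

    def test_symmetric_under_swap(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=5)
        assert wilcoxon_rank_sum(a, b)[1] == pytest.approx(wilcoxon_rank_sum(b, a)[1])

    def test_exact_p_matches_brute_force_enumeration(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        u_obs, p = wilcoxon_rank_sum(a, b)
        pooled = sorted(a + b)
        uo = min(u_obs, 9 - u_obs)  # null distribution of U is symmetric about 4.5
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            u = sum(1 for i in combo for j in range(6)
                    if j not in combo and pooled[i] > pooled[j])
            hits += (u <= uo) or (u >= 9 - uo)
            total += 1
        assert p == pytest.approx(hits / total)


class TestHolm:
    def test_worked_examples(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(holm_adjust([0.5]), [0.5])
        # brute-force stepdown: sorted (0.01,0.03,0.04) -> (0.03, 0.06, 0.06)
        np.testing.assert_allclose(holm_adjust([0.03, 0.01, 0.04]), [0.06, 0.03, 0.06])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=8))
    def test_adjusted_dominates_raw_and_matches_stepdown_definition(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        m = len(ps)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * ps[idx]))
            assert adj[idx] == pytest.approx(running, abs=1e-12)


class TestPairwiseDe:
    def _clusters(self, labels):
        labels = np.asarray(labels)
        return ClusterAssignment([f"s{i}" for i in range(len(labels))], labels,
                                 int(labels.max()), "fixed")

    def test_two_clusters_single_pair_no_correction(self, rng):
        vals = rng.normal(size=(10, 2))
        m = OmicsMatrix(vals, [f"s{i}" for i in range(10)], ["g1", "g2"], "expression")
        table = pairwise_de(m, self._clusters([1] * 5 + [2] * 5))
        assert len(table) == 2  # one pair per feature
        np.testing.assert_allclose(table["p_adj_holm"], table["p_raw"])

    def test_three_clusters_three_pairs_per_feature(self, rng):
        vals = rng.normal(size=(12, 1))
        m = OmicsMatrix(vals, [f"s{i}" for i in range(12)], ["g"], "expression")
        table = pairwise_de(m, self._clusters([1] * 4 + [2] * 4 + [3] * 4))
        assert len(table) == 3
        assert set(zip(table.group_a, table.group_b)) == {(1, 2), (1, 3), (2, 3)}

    def test_planted_shift_detected(self, rng):
        n = 40
        vals = rng.normal(size=(n, 3))
        vals[20:, 0] += 3.0  # 3 SD shift in feature g0 for cluster 2
        m = OmicsMatrix(vals, [f"s{i}" for i in range(n)],
                        ["g0", "g1", "g2"], "expression")
        table = pairwise_de(m, self._clusters([1] * 20 + [2] * 20))
        assert table.loc[table.feature_id == "g0", "p_adj_holm"].min() < 0.01


class TestKaplanMeier:
    def test_all_events_product_limit_and_median(self):
        c = km_curve([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        np.testing.assert_allclose(c.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert c.median == 3.0

    def test_censoring_shrinks_risk_set_without_drop(self):
        # times (1, 2+, 3): risk sets 3, 2, 1 -> S = 2/3, 2/3, 0
        c = km_curve([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 2 / 3, 0.0])
        np.testing.assert_allclose(c.at_risk, [3, 2, 1])

    def test_all_censored_flat_curve_undefined_median(self):
        c = km_curve([2, 4, 6], [0, 0, 0])
        np.testing.assert_allclose(c.survival, 1.0)
        assert np.isinf(c.median)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=25).round(1)
        c = km_curve(t, np.ones_like(t))
        for tt, s in zip(c.times, c.survival):
            assert s == pytest.approx((t > tt).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        g = ["A"] * 4 + ["B"] * 4
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_hand_tabulated_two_group_statistic(self):
        # A events at (1,2); B events at (3,4).  O_A - E_A = 2 - 5/6 = 7/6,
        # V = 1/4 + 2/9 = 17/36, chi2 = (7/6)^2 / (17/36) = 49/17
        chi2, df, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)
        assert df == 1

    def test_duplicating_subjects_preserves_direction_and_grows_chi2(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 1, 1]
        g = ["A", "A", "B", "B"]
        chi2_1, _, _ = logrank_test(t, e, g)
        chi2_2, _, _ = logrank_test(t * 2, e * 2, g * 2)
        assert chi2_2 > chi2_1

    def test_multigroup_degrees_of_freedom(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1] * 6
        g = ["A", "A", "B", "B", "C", "C"]
        _, df, _ = logrank_test(t, e, g)
        assert df == 2

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], ["A", "B"])
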