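"""First-principles group statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from streamresp import stats as gs


def brute_force_dunn_z(groups):
    """Independent midrank implementation of Dunn's z statistics."""
    labels = []
    values = []
    for gi, g in enumerate(groups):
        for v in g:
            labels.append(gi)
            values.append(float(v))
    values = np.array(values)
    n = len(values)
    # midranks by explicit comparison counting
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(values < values[i])
        equal = np.sum(values == values[i])
        ranks[i] = less + (equal + 1) / 2.0
    tie_term = 0.0
    for v in np.unique(values):
        t = np.sum(values == v)
        tie_term += t**3 - t
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    labels = np.array(labels)
    out = {}
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            ri = ranks[labels == i].mean()
            rj = ranks[labels == j].mean()
            ni, nj = (labels == i).sum(), (labels == j).sum()
            out[(i, j)] = (ri - rj) / np.sqrt(var_base * (1 / ni + 1 / nj))
    return out


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = gs.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == (2,)

    def test_all_constant_convention(self):
        res = gs.kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [np.round(rng.normal(0, 1, rng.integers(4, 12)), 1)
                      for _ in range(3)]
            ours = gs.kruskal_wallis(groups)
            ref = spstats.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_power_at_two_pooled_sd_shift(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            rejections += gs.kruskal_wallis([a, b]).p_value < 0.05
        assert rejections / n_rep >= 0.95

    @given(st.lists(st.floats(-50, 50).filter(lambda x: x == 0 or abs(x) > 1e-3),
                    min_size=3, max_size=8, unique=True),
           st.lists(st.floats(-50, 50).filter(lambda x: x == 0 or abs(x) > 1e-3),
                    min_size=3, max_size=8, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, a, b):
        pooled = list(np.exp(np.array(a + b) / 50.0))
        if len(set(a + b)) != len(a + b) or len(set(pooled)) != len(pooled):
            return  # monotone-invariance claim holds for no-ties data
        h1 = gs.kruskal_wallis([a, b]).statistic
        h2 = gs.kruskal_wallis([np.exp(np.array(a) / 50),
                                np.exp(np.array(b) / 50)]).statistic
        assert h1 == pytest.approx(h2, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gs.kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_null_result(self):
        table = gs.dunn_posthoc([[2.0, 2.0, 2.0], [2.0, 2.0], [2.0, 2.0, 2.0]])
        assert np.allclose(table["z"], 0.0)
        assert np.allclose(table["p_unadjusted"], 1.0)

    def test_pair_count(self):
        table = gs.dunn_posthoc([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert len(table) == 6

    def test_matches_brute_force_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        table = gs.dunn_posthoc(groups)
        oracle = brute_force_dunn_z(groups)
        for row, ((i, j), z) in zip(table.itertuples(), oracle.items()):
            assert row.z == pytest.approx(z, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        groups = [list(np.round(rng.normal(0, 1, 9), 0)) for _ in range(4)]
        table = gs.dunn_posthoc(groups)
        oracle = brute_force_dunn_z(groups)
        for row, ((i, j), z) in zip(table.itertuples(), oracle.items()):
            assert row.z == pytest.approx(z, abs=1e-12)

    def test_label_permutation_antisymmetry(self):
        a, b, c = [1.0, 4.0, 6.0], [2.0, 5.0, 9.0], [3.0, 7.0, 8.0]
        t1 = gs.dunn_posthoc({"a": a, "b": b, "c": c})
        t2 = gs.dunn_posthoc({"b": b, "a": a, "c": c})
        z_ab = t1.set_index(["group_i", "group_j"]).loc[("a", "b"), "z"]
        z_ba = t2.set_index(["group_i", "group_j"]).loc[("b", "a"), "z"]
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    @pytest.mark.parametrize("method", ["bonferroni", "holm"])
    def test_adjustments_match_statsmodels(self, method):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.2, 0.03, 0.9, 0.04, 0.012])
        ours = gs.adjust_pvalues(p, method)
        ref = multipletests(p, method="bonferroni" if method == "bonferroni" else "holm")[1]
        assert np.allclose(ours, ref)


class TestAnova:
    def test_all_identical_f_zero(self):
        res = gs.one_way_anova([[3.0, 3.0, 3.0], [3.0, 3.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_decomposed_example(self):
        res = gs.one_way_anova([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert res.statistic == pytest.approx(1.5)
        assert res.df == (1, 4)

    def test_zero_within_variance_unequal_means(self):
        res = gs.one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = [rng.normal(rng.normal(), 1, rng.integers(4, 10))
                      for _ in range(3)]
            ours = gs.one_way_anova(groups)
            ref = spstats.f_oneway(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        pooled = np.concatenate(groups)
        sst = float(np.sum((pooled - pooled.mean()) ** 2))
        ssb = sum(g.size * (g.mean() - pooled.mean()) ** 2 for g in groups)
        ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
        assert ssb + ssw == pytest.approx(sst, rel=1e-12)
        f_manual = (ssb / 2) / (ssw / (pooled.size - 3))
        assert gs.one_way_anova(groups).statistic == pytest.approx(f_manual)


class TestRmrModel:
    def test_exact_single_watershed(self):
        temp = np.linspace(8, 22, 12)
        rmr = np.exp(0.08 * temp - 0.5)
        df = pd.DataFrame({"rmr": rmr, "temp_c": temp, "watershed": "A"})
        fit = gs.fit_rmr_model(df)
        assert fit.slope_per_c == pytest.approx(0.08, abs=1e-10)
        assert fit.intercepts["A"] == pytest.approx(-0.5, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_exact_two_watershed_intercepts(self):
        temp = np.tile(np.linspace(8, 22, 8), 2)
        ws = ["A"] * 8 + ["B"] * 8
        icpt = np.where(np.array(ws) == "A", -0.5, -0.3)
        df = pd.DataFrame(
            {"rmr": np.exp(0.08 * temp + icpt), "temp_c": temp, "watershed": ws}
        )
        fit = gs.fit_rmr_model(df)
        assert fit.intercepts["A"] == pytest.approx(-0.5, abs=1e-9)
        assert fit.intercepts["B"] == pytest.approx(-0.3, abs=1e-9)

    def test_slope_recovery_with_fish_effects(self):
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            rows = []
            for ws, icpt in (("A", -0.5), ("B", -0.3)):
                for fish in range(48):
                    fish_icpt = rng.normal(0, 0.1)
                    for temp in rng.uniform(8, 22, 3):
                        rows.append(
                            {"rmr": np.exp(0.08 * temp + icpt + fish_icpt),
                             "temp_c": temp, "watershed": ws}
                        )
            fit = gs.fit_rmr_model(pd.DataFrame(rows))
            hits += abs(fit.slope_per_c - 0.08) <= 0.008
        assert hits / n_rep >= 0.90

    def test_nonpositive_rmr_rows_dropped_with_warning(self):
        temp = np.linspace(8, 22, 12)
        df = pd.DataFrame(
            {"rmr": np.r_[np.exp(0.08 * temp[:-1]), -1.0], "temp_c": temp,
             "watershed": "A"}
        )
        with pytest.warns(UserWarning):
            fit = gs.fit_rmr_model(df)
        assert fit.n == 11
        assert fit.n_dropped == 1
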