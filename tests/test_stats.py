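"""t-tests, two-way Type II ANOVA, and group summaries against hand/brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from ecmmech.stats import (holm_correction, summarize_groups, two_sample_t,
                           two_way_anova)


def pooled_t_oracle(x, y):
    # independent textbook formula
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def anova_type2_oracle(df):
    """Type II SS by nested-model residual-SS differences (lstsq on explicit
    design matrices), independent of statsmodels."""
    a = (df["age"] == df["age"].unique()[1]).to_numpy(float)
    b = (df["volume"] == df["volume"].unique()[1]).to_numpy(float)
    y = df["value"].to_numpy(float)
    one = np.ones_like(y)

    def rss(*cols):
        X = np.column_stack(cols)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    rss_full = rss(one, a, b, a * b)
    rss_ab = rss(one, a, b)
    ss = {
        "age": rss(one, b) - rss_ab,
        "volume": rss(one, a) - rss_ab,
        "age:volume": rss_ab - rss_full,
        "residual": rss_full,
    }
    df_res = len(y) - 4
    out = {}
    for term, s in ss.items():
        if term == "residual":
            out[term] = (s, df_res, None, None)
        else:
            F = (s / 1.0) / (ss["residual"] / df_res)
            from scipy.stats import f as fdist
            out[term] = (s, 1, F, float(fdist.sf(F, 1, df_res)))
    return out


class TestTwoSampleT:
    def test_identical_samples_give_t0_p1(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_separated_samples_reject_strongly(self):
        x = [1.0, 1.001, 0.999, 1.0]
        y = [11.0, 11.001, 10.999, 11.0]
        res = two_sample_t(x, y)
        assert res.p < 1e-6 and res.significant

    def test_matches_hand_computed_statistic(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = two_sample_t(x, y)
        assert res.t == pytest.approx(pooled_t_oracle(x, y), abs=1e-10)
        assert res.df == 4

    def test_zero_variance_equal_means(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0) and not res.degenerate

    def test_zero_variance_unequal_means_degenerate(self):
        res = two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert res.p == 0.0 and res.degenerate

    def test_n1_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_welch_differs_under_variance_heterogeneity(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0, 6, 20)
        assert two_sample_t(x, y).p != two_sample_t(x, y, welch=True).p


def make_design(cells):
    rows = []
    for (age, vol), values in cells.items():
        rows += [{"age": age, "volume": vol, "value": v} for v in values]
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_cell_means_give_null_table(self):
        # every cell holds {4, 6}: all cell means equal, within-cell variance > 0
        cells = {(a, v): [4.0, 6.0, 4.0, 6.0]
                 for a in ("young", "aged") for v in ("RV", "FV")}
        table = two_way_anova(make_design(cells))
        assert (table.loc[["age", "volume", "age:volume"], "F"] < 1e-10).all()
        assert (table.loc[["age", "volume", "age:volume"], "p"] > 0.999).all()

    def test_purely_additive_effects_have_zero_interaction(self):
        # cell means young-RV 1, young-FV 3, aged-RV 2, aged-FV 4: additive
        cells = {("young", "RV"): [0.0, 2.0], ("young", "FV"): [2.0, 4.0],
                 ("aged", "RV"): [1.0, 3.0], ("aged", "FV"): [3.0, 5.0]}
        table = two_way_anova(make_design(cells))
        assert table.loc["age:volume", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_unbalanced_design_matches_nested_model_oracle(self, rng):
        # 4/4/8/8 animals as in the study design
        cells = {("young", "RV"): rng.normal(0.47, 0.08, 4),
                 ("young", "FV"): rng.normal(0.36, 0.06, 4),
                 ("aged", "RV"): rng.normal(0.26, 0.06, 8),
                 ("aged", "FV"): rng.normal(0.54, 0.12, 8)}
        df = make_design(cells)
        table = two_way_anova(df)
        oracle = anova_type2_oracle(df)
        for term in ("age", "volume", "age:volume"):
            ss, dof, F, p = oracle[term]
            assert table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-8)
            assert table.loc[term, "F"] == pytest.approx(F, rel=1e-8)
            assert table.loc[term, "p"] == pytest.approx(p, rel=1e-6)
        assert table.loc["residual", "sum_sq"] == pytest.approx(oracle["residual"][0],
                                                                abs=1e-8)

    def test_balanced_design_conserves_total_ss(self, rng):
        cells = {(a, v): rng.normal(float(hash((a, v)) % 7), 1.0, 6)
                 for a in ("young", "aged") for v in ("RV", "FV")}
        df = make_design(cells)
        table = two_way_anova(df)
        total = float(((df["value"] - df["value"].mean()) ** 2).sum())
        assert table["sum_sq"].sum() == pytest.approx(total, abs=1e-10)
        assert table["df"].sum() == len(df) - 1

    def test_random_small_datasets_agree_with_oracle(self, rng):
        for _ in range(100):
            sizes = rng.integers(2, 6, size=4)
            cells = {("young", "RV"): rng.normal(0, 1, sizes[0]),
                     ("young", "FV"): rng.normal(0, 1, sizes[1]),
                     ("aged", "RV"): rng.normal(0, 1, sizes[2]),
                     ("aged", "FV"): rng.normal(0, 1, sizes[3])}
            df = make_design(cells)
            table = two_way_anova(df)
            oracle = anova_type2_oracle(df)
            for term in ("age", "volume", "age:volume"):
                assert table.loc[term, "p"] == pytest.approx(oracle[term][3],
                                                             rel=1e-6, abs=1e-12)

    def test_empty_cell_errors_naming_the_cell(self):
        cells = {("young", "RV"): [1.0, 2.0], ("young", "FV"): [2.0, 3.0],
                 ("aged", "RV"): [1.5, 2.5]}
        with pytest.raises(ValueError, match="aged.*FV|FV.*aged"):
            two_way_anova(make_design(cells))


class TestGroupSummaries:
    def test_hand_computed_mean_and_se(self):
        df = pd.DataFrame({"g": ["a"] * 3, "v": [2.0, 4.0, 6.0]})
        (s,) = summarize_groups(df, "v", "g")
        assert s.mean == 4.0
        assert s.se == pytest.approx(2.0 / math.sqrt(3), abs=1e-4)  # 1.1547

    def test_single_value_group_has_missing_se(self):
        df = pd.DataFrame({"g": ["a"], "v": [7.0]})
        (s,) = summarize_groups(df, "v", "g")
        assert s.mean == 7.0 and s.se is None

    def test_order_invariant(self, rng):
        df = pd.DataFrame({"g": ["a", "b"] * 10, "v": rng.normal(size=20)})
        a = summarize_groups(df, "v", "g")
        b = summarize_groups(df.sample(frac=1.0, random_state=0), "v", "g")
        for sa, sb in zip(a, b):
            assert sa.group == sb.group and sa.n == sb.n
            assert sa.mean == pytest.approx(sb.mean, abs=1e-12)
            assert sa.se == pytest.approx(sb.se, abs=1e-12)


def test_holm_correction_monotone_and_bounded():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = holm_correction(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.04)
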