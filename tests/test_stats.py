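"""Summary tables, Student's t comparisons, and interaction ANOVA."""

import numpy as np
import pandas as pd
import pytest

from osmodrop.stats import (interaction_anova, interaction_p, minute_groups,
                            summarize, two_group_t, two_group_t_from_summary)


def _long_table(cells, minute=5):
    """cells: {(genotype, condition): [values]} -> long-format table."""
    rows = []
    for (g, c), vals in cells.items():
        for i, v in enumerate(vals):
            rows.append({"animal_id": f"{g}_{c}_{i}", "genotype": g,
                         "condition": c, "minute": minute,
                         "turns_per_min": v})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_hand_computed_cell(self):
        tab = _long_table({("wt", "400"): [10.0, 12.0, 14.0]})
        out = summarize(tab)
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(12.0)
        assert row["sem"] == pytest.approx(2.0 / np.sqrt(3))
        assert row["n"] == 3

    def test_single_observation_sem_missing(self):
        tab = _long_table({("wt", "400"): [10.0]})
        assert np.isnan(summarize(tab).iloc[0]["sem"])

    def test_constant_cell_zero_sem(self):
        tab = _long_table({("wt", "400"): [9.0, 9.0, 9.0, 9.0]})
        assert summarize(tab).iloc[0]["sem"] == 0.0

    def test_missing_minute_rejected(self):
        tab = _long_table({("wt", "400"): [1.0, 2.0]}, minute=3)
        with pytest.raises(ValueError):
            summarize(tab, minute=5)


class TestTwoGroupT:
    def test_identical_groups(self):
        res = two_group_t([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_droplet_volume_check_from_summary(self):
        """Pre/post droplet volumes 23.6±0.31 vs 23.2±0.35 (n=8): p ≈ 0.4."""
        res = two_group_t_from_summary(23.6, 0.31, 8, 23.2, 0.35, 8)
        assert res.df == 14
        assert res.p == pytest.approx(0.38, abs=0.05)

    def test_raw_equals_own_summary(self, rng):
        x = rng.normal(20, 4, size=12)
        y = rng.normal(24, 5, size=9)
        raw = two_group_t(x, y)
        summ = two_group_t_from_summary(
            x.mean(), x.std(ddof=1) / np.sqrt(len(x)), len(x),
            y.mean(), y.std(ddof=1) / np.sqrt(len(y)), len(y))
        assert raw.t == pytest.approx(summ.t, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-10)

    def test_welch_flag(self, rng):
        x = rng.normal(0, 1, size=10)
        y = rng.normal(0, 6, size=30)
        classic = two_group_t(x, y)
        welch = two_group_t(x, y, welch=True)
        assert welch.df != classic.df

    def test_type_I_error_calibrated(self):
        """Null simulations at n=16/16: rejection rate 0.05 ± 0.01."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10_000, 16))
        y = rng.normal(size=(10_000, 16))
        from scipy.stats import ttest_ind

        p = ttest_ind(x, y, axis=1).pvalue
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_group_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            two_group_t([1.0, 1.0], [2.0, 2.0])


class TestInteractionAnova:
    @staticmethod
    def _brute_force_balanced_F(cells):
        """Cell-means two-way ANOVA for a balanced 2x2 design."""
        a_levels = sorted({a for a, _ in cells})
        b_levels = sorted({b for _, b in cells})
        n = len(next(iter(cells.values())))
        means = {k: np.mean(v) for k, v in cells.items()}
        grand = np.mean([v for vals in cells.values() for v in vals])
        a_means = {a: np.mean([means[(a, b)] for b in b_levels])
                   for a in a_levels}
        b_means = {b: np.mean([means[(a, b)] for a in a_levels])
                   for b in b_levels}
        ss_int = n * sum((means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
                         for a in a_levels for b in b_levels)
        df_int = (len(a_levels) - 1) * (len(b_levels) - 1)
        ss_err = sum(((np.asarray(v) - means[k]) ** 2).sum()
                     for k, v in cells.items())
        df_err = sum(len(v) - 1 for v in cells.values())
        return (ss_int / df_int) / (ss_err / df_err)

    def test_matches_brute_force_on_balanced_design(self, rng):
        cells = {(g, c): rng.normal(10 + 5 * (c == "400") + 2 * (g == "mut"),
                                    2, size=6).tolist()
                 for g in ("wt", "mut") for c in ("150", "400")}
        aov = interaction_anova(_long_table(cells))
        f_brute = self._brute_force_balanced_F(cells)
        assert aov.loc["genotype:condition", "F"] == pytest.approx(
            f_brute, rel=1e-10)

    def test_constructed_interaction_detected(self, rng):
        delta = 10.0
        eps = 0.01
        cells = {(g, c): (np.array([0.0, 0.0, 0.0])
                          + (delta if (g == "mut" and c == "400") else 0.0)
                          + rng.normal(0, eps, 3)).tolist()
                 for g in ("wt", "mut") for c in ("150", "400")}
        aov = interaction_anova(_long_table(cells))
        assert aov.loc["genotype:condition", "F"] > 1e4
        assert interaction_p(aov) < 1e-6

    def test_type2_equals_type1_on_balanced_design(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        cells = {(g, c): rng.normal(10, 3, size=5).tolist()
                 for g in ("wt", "mut") for c in ("150", "400")}
        tab = _long_table(cells)
        aov2 = interaction_anova(tab)
        model = smf.ols("turns_per_min ~ C(genotype) * C(condition)",
                        data=tab[tab.minute == 5]).fit()
        aov1 = sm.stats.anova_lm(model, typ=1)
        assert aov2.loc["genotype", "sum_sq"] == pytest.approx(
            aov1.loc["C(genotype)", "sum_sq"], rel=1e-8)
        assert aov2.loc["genotype:condition", "sum_sq"] == pytest.approx(
            aov1.loc["C(genotype):C(condition)", "sum_sq"], rel=1e-8)

    def test_unbalanced_design_accepted(self, rng):
        cells = {("wt", "150"): rng.normal(10, 2, 16).tolist(),
                 ("wt", "400"): rng.normal(30, 2, 12).tolist(),
                 ("mut", "150"): rng.normal(10, 2, 14).tolist(),
                 ("mut", "400"): rng.normal(30, 2, 16).tolist()}
        aov = interaction_anova(_long_table(cells))
        assert np.isfinite(interaction_p(aov))

    def test_missing_cell_rejected(self, rng):
        cells = {("wt", "150"): [1.0, 2.0], ("wt", "400"): [3.0, 4.0],
                 ("mut", "150"): [1.0, 2.0]}
        with pytest.raises(ValueError):
            interaction_anova(_long_table(cells))

    def test_additive_null_type_I_error(self):
        """No-interaction simulations: rejection rate 0.05 ± 0.015."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            cells = {(g, c): (10.0 + (5.0 if c == "400" else 0.0)
                              + (2.0 if g == "mut" else 0.0)
                              + rng.normal(0, 3, 8)).tolist()
                     for g in ("wt", "mut") for c in ("150", "400")}
            if interaction_p(interaction_anova(_long_table(cells))) < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)


class TestAdjustPvalues:
    def test_bh_monotone_and_bounded(self):
        from osmodrop.stats import adjust_pvalues

        p = np.array([0.001, 0.02, 0.04, 0.5, 0.9])
        adj = adjust_pvalues(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # BH for the smallest p with m=5: p*(m/1)
        assert adj[0] == pytest.approx(0.005)


class TestMinuteGroups:
    def test_extracts_by_factor_level(self):
        tab = _long_table({("wt", "150"): [1.0, 2.0],
                           ("wt", "400"): [5.0, 6.0]})
        g1, g2 = minute_groups(tab, "condition", ("150", "400"))
        assert g1.tolist() == [1.0, 2.0]
        assert g2.tolist() == [5.0, 6.0]
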