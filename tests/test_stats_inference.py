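"""Inferential layer: t/rank-sum tests, ANOVAs, psychometric fit."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from saccsdt.stats_inference import (
    PsychometricFit,
    bonferroni,
    independent_t_test,
    mixed_anova_2way,
    psychometric_fit,
    ranksum_test,
    rm_anova_1way,
)


class TestIndependentT:
    def test_hand_computed_example(self):
        res = independent_t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=5e-5)
        assert res.p_value == pytest.approx(0.2879, abs=5e-5)  # 0.287864
        assert res.df == 4

    def test_seven_vs_seven_gives_df_12(self):
        rng = np.random.default_rng(0)
        res = independent_t_test(rng.normal(size=7), rng.normal(size=7))
        assert res.df == 12

    def test_identical_samples(self):
        res = independent_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_unequal_means_flagged(self):
        res = independent_t_test([2.0, 2.0], [1.0, 1.0])
        assert math.isinf(res.statistic) and res.p_value == 0.0
        assert "zero pooled variance" in res.note

    @given(
        shift=st.floats(min_value=-50, max_value=50),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    def test_location_scale_behavior(self, shift, scale):
        x = np.array([1.0, 2.5, 3.0, 4.2])
        y = np.array([2.0, 3.1, 4.4])
        base = independent_t_test(x, y)
        shifted = independent_t_test(x + shift, y + shift)
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9, abs=1e-9)
        scaled = independent_t_test(x * scale, y * scale)
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            independent_t_test([1.0], [2.0, 3.0])


def _ranksum_exact_oracle(x, y):
    """Enumerate all rank assignments (no ties): two-sided p for rank-sum."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    stats = [
        sum(c) for c in itertools.combinations(range(1, n + 1), len(x))
    ]
    mean_w = len(x) * (n + 1) / 2
    extreme = sum(1 for w in stats if abs(w - mean_w) >= abs(w_obs - mean_w))
    return extreme / len(stats)


class TestRanksum:
    def test_exact_small_sample_separated(self):
        res = ranksum_test([1, 2, 3], [4, 5, 6])
        assert res.test_name == "ranksum_exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(_ranksum_exact_oracle([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize(
        "x, y",
        [([1, 4, 6], [2, 3, 5]), ([10, 20], [5, 15, 25, 35]), ([1, 2, 7, 9], [3, 5, 8])],
    )
    def test_exact_matches_enumeration_oracle(self, x, y):
        res = ranksum_test(x, y)
        assert res.test_name == "ranksum_exact"
        assert res.p_value == pytest.approx(_ranksum_exact_oracle(x, y), abs=1e-12)

    def test_identical_samples_approximation_path(self):
        res = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test_name == "ranksum_normal"  # ties force the normal path
        assert res.p_value == pytest.approx(1.0)

    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_monotone_transform_invariance(self, kind):
        x = [0.3, 1.2, 2.5, 4.0]
        y = [0.8, 1.9, 3.1]
        transform = {
            "exp": math.exp,
            "cube": lambda v: v**3,
            "affine": lambda v: 3 * v + 2,
        }[kind]
        base = ranksum_test(x, y)
        mapped = ranksum_test([transform(v) for v in x], [transform(v) for v in y])
        assert mapped.p_value == pytest.approx(base.p_value, abs=1e-12)


def _anova_projection_oracle(y, groups):
    """Sequential-projection split-plot oracle via explicit OLS fits.

    y: subjects x within-levels matrix; groups: group label per subject.
    Returns the five sums of squares (between, subjects, within,
    interaction, residual) from nested least-squares projections.
    """
    n_subj, b = y.shape
    rows = []
    for s in range(n_subj):
        for w in range(b):
            rows.append((s, groups[s], w, y[s, w]))
    yy = np.array([r[3] for r in rows])

    def rss(cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        return float(((yy - X @ beta) ** 2).sum())

    ones = np.ones(len(rows))
    g_dum = [np.array([1.0 if r[1] == g else 0.0 for r in rows]) for g in set(groups)]
    s_dum = [np.array([1.0 if r[0] == s else 0.0 for r in rows]) for s in range(n_subj)]
    w_dum = [np.array([1.0 if r[2] == w else 0.0 for r in rows]) for w in range(b)]
    gw_dum = [
        np.array([1.0 if (r[1] == g and r[2] == w) else 0.0 for r in rows])
        for g in set(groups)
        for w in range(b)
    ]
    rss_mean = rss([ones])
    rss_g = rss([ones, *g_dum])
    rss_s = rss([ones, *s_dum])  # subjects nest groups
    rss_sw = rss([ones, *s_dum, *w_dum])
    rss_sgw = rss([ones, *s_dum, *w_dum, *gw_dum])
    ss_between = rss_mean - rss_g
    ss_subj = rss_g - rss_s
    ss_within = rss_s - rss_sw
    ss_inter = rss_sw - rss_sgw
    ss_resid = rss_sgw
    return ss_between, ss_subj, ss_within, ss_inter, ss_resid


def _mixed_table(y, groups):
    rows = []
    for s, (vals, g) in enumerate(zip(y, groups)):
        for w, v in enumerate(vals):
            rows.append(
                {"session_id": s, "perturbation": g, "hemifield": f"w{w}", "value": v}
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_structure_7v7(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(14, 2))
        groups = ["control"] * 7 + ["inactivation"] * 7
        table = mixed_anova_2way(_mixed_table(y, groups))
        between = table[table["source"] == "perturbation"].iloc[0]
        assert (between["df"], table[table["source"] == "subjects_within_perturbation"]["df"].iloc[0]) == (1, 12)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(8, 3))  # 4 + 4 subjects, 3 within levels
        groups = ["a"] * 4 + ["b"] * 4
        table = mixed_anova_2way(_mixed_table(y, groups))
        oracle = _anova_projection_oracle(y, groups)
        got = [
            float(table.loc[table["source"] == src, "ss"].iloc[0])
            for src in (
                "perturbation",
                "subjects_within_perturbation",
                "hemifield",
                "perturbation x hemifield",
                "residual",
            )
        ]
        assert np.allclose(got, oracle, atol=1e-8)

    def test_ss_partition_exact(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 2))
        groups = ["a"] * 5 + ["b"] * 5
        table = mixed_anova_2way(_mixed_table(y, groups))
        assert table["ss"].sum() == pytest.approx(table.attrs["ss_total"], rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        y = rng.normal(size=(14, 2))
        groups = ["control"] * 7 + ["inactivation"] * 7
        df = _mixed_table(y, groups)
        ours = mixed_anova_2way(df)
        theirs = pg.mixed_anova(
            data=df, dv="value", within="hemifield", between="perturbation",
            subject="session_id",
        )
        for src, pg_src in [
            ("perturbation", "perturbation"),
            ("hemifield", "hemifield"),
            ("perturbation x hemifield", "Interaction"),
        ]:
            ours_f = float(ours.loc[ours["source"] == src, "F"].iloc[0])
            theirs_f = float(theirs.loc[theirs["Source"] == pg_src, "F"].iloc[0])
            assert ours_f == pytest.approx(theirs_f, rel=1e-8)

    def test_constant_values_flagged(self):
        y = np.ones((6, 2))
        groups = ["a"] * 3 + ["b"] * 3
        table = mixed_anova_2way(_mixed_table(y, groups))
        assert np.isnan(table[table["source"] == "perturbation"]["F"].iloc[0])

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(5, 2))
        groups = ["a"] * 3 + ["b"] * 2
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova_2way(_mixed_table(y, groups))
        df = _mixed_table(rng.normal(size=(4, 2)), ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova_2way(df.drop(index=0))


class TestRmAnova:
    def _table(self, y):
        rows = []
        for s, vals in enumerate(y):
            for k, v in enumerate(vals):
                rows.append({"session_id": s, "stimulus_type": f"c{k}", "value": v})
        return pd.DataFrame(rows)

    def test_df_structure_3_conditions_11_sessions(self):
        rng = np.random.default_rng(5)
        aov, _ = rm_anova_1way(self._table(rng.normal(size=(11, 3))))
        row = aov[aov["source"] == "stimulus_type"].iloc[0]
        resid = aov[aov["source"] == "residual"].iloc[0]
        assert (row["df"], resid["df"]) == (2, 20)

    def test_identical_columns_f_zero(self):
        y = np.tile(np.random.default_rng(1).normal(size=(6, 1)), (1, 3))
        aov, _ = rm_anova_1way(self._table(y))
        assert aov[aov["source"] == "stimulus_type"]["F"].iloc[0] == pytest.approx(0.0)

    def test_matches_projection_oracle_and_pingouin(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(6, 3))
        aov, _ = rm_anova_1way(self._table(y))
        # projection oracle: sequential OLS with subject then condition dummies
        n, k = y.shape
        yy = y.ravel()
        subj = np.repeat(np.eye(n), k, axis=0)
        cond = np.tile(np.eye(k), (n, 1))

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
            return float(((yy - X @ beta) ** 2).sum())

        ones = np.ones((n * k, 1))
        rss_s = rss(np.hstack([ones, subj]))
        rss_sc = rss(np.hstack([ones, subj, cond]))
        ss_cond = rss_s - rss_sc
        got = float(aov.loc[aov["source"] == "stimulus_type", "ss"].iloc[0])
        assert got == pytest.approx(ss_cond, abs=1e-8)
        assert aov["ss"].sum() == pytest.approx(aov.attrs["ss_total"], rel=1e-9)
        pg = pytest.importorskip("pingouin")
        table = self._table(y)
        theirs = pg.rm_anova(data=table, dv="value", within="stimulus_type",
                             subject="session_id")
        assert float(aov.loc[aov["source"] == "stimulus_type", "F"].iloc[0]) == pytest.approx(
            float(theirs["F"].iloc[0]), rel=1e-8
        )

    def test_bonferroni_posthocs(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(8, 3))
        y[:, 2] += 3.0
        _, post = rm_anova_1way(self._table(y))
        assert len(post) == 3
        assert (post["p_bonferroni"] >= post["p_uncorrected"]).all()
        assert (post["p_bonferroni"] <= 1.0).all()
        assert bonferroni(0.5, 3) == 1.0

    def test_incomplete_data_rejected(self):
        table = self._table(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            rm_anova_1way(table.drop(index=0))


class TestPsychometricFit:
    LEVELS = np.array([0.09, 0.25, 0.5, 0.75, 1.0])

    def test_exact_model_data_recovered(self):
        truth = PsychometricFit(mu=0.3, sigma=0.15)
        n = 1000
        expected = truth.predict(self.LEVELS) * n
        fit = psychometric_fit(self.LEVELS, expected, [n] * len(self.LEVELS))
        assert fit.mu == pytest.approx(0.3, abs=1e-6)
        assert fit.sigma == pytest.approx(0.15, abs=1e-6)

    def test_binomial_recovery_simulation(self):
        """Median |mu error| < 0.02 ratio units across seeded replicates."""
        truth = PsychometricFit(mu=0.35, sigma=0.2)
        p = truth.predict(self.LEVELS)
        errors = []
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k = rng.binomial(200, p)
            fit = psychometric_fit(self.LEVELS, k, [200] * len(self.LEVELS))
            errors.append(abs(fit.mu - 0.35))
        assert float(np.median(errors)) < 0.02

    def test_invert_brackets_target_accuracy(self):
        truth = PsychometricFit(mu=0.3, sigma=0.15)
        n = 500
        fit = psychometric_fit(self.LEVELS, truth.predict(self.LEVELS) * n,
                               [n] * len(self.LEVELS))
        x75 = fit.invert(0.75)
        preds = fit.predict(self.LEVELS)
        below = self.LEVELS[preds < 0.75].max()
        above = self.LEVELS[preds > 0.75].min()
        assert below < x75 < above
        assert fit.predict(x75) == pytest.approx(0.75, abs=1e-9)

    def test_monotone_curve(self):
        fit = PsychometricFit(mu=0.4, sigma=0.1)
        xs = np.linspace(0, 1, 50)
        assert np.all(np.diff(fit.predict(xs)) > 0)

    def test_degenerate_data_flagged(self):
        flat = psychometric_fit([0.1, 0.5, 0.9], [50, 50, 50], [100, 100, 100])
        assert (not flat.converged) or flat.sigma > 0  # boundary estimates allowed
        with pytest.raises(ValueError):
            psychometric_fit([0.1, 0.5], [50, 60], [100, 100])

    def test_invert_outside_asymptotes_rejected(self):
        fit = PsychometricFit(mu=0.3, sigma=0.1)
        with pytest.raises(ValueError):
            fit.invert(0.4)  # below the 0.5 chance floor
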