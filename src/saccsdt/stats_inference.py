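"""Inferential statistics for session-level SDT and latency measures.

Covers what the analysis needs: pooled-variance independent t-tests (7 vs. 7
sessions gives df = 12), Wilcoxon rank-sum tests (exact null distribution
for small tie-free samples), one-way repeated-measures ANOVA with Bonferroni
post-hocs, the two-way mixed (split-plot) ANOVA with within-factor hemifield
and between-factor perturbation, and the cumulative-normal psychometric fit
used to calibrate distractor difficulty from accuracy vs. G/R color ratio.

The split-plot decomposition is written out directly (balanced designs):
the between-subjects stratum tests the group factor against
subjects-within-groups, the within stratum tests the repeated factor and
the interaction against the subject-by-factor residual.  ``pingouin``
reproduces the same F ratios and serves as an independent cross-check in
the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StatResult",
    "independent_t_test",
    "ranksum_test",
    "mixed_anova_2way",
    "rm_anova_1way",
    "bonferroni",
    "PsychometricFit",
    "psychometric_fit",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: Union[float, Tuple[float, float], None]
    p_value: float
    test_name: str
    correction: str = "none"
    note: str = ""


def independent_t_test(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pooled-variance two-sample Student t-test (two-sided).

    The pooled variant is what yields df = n1 + n2 - 2, i.e. df = 12 for the
    7 control vs. 7 perturbation sessions design.  Degenerate zero-variance
    input is resolved explicitly: equal means give t = 0, p = 1; unequal
    means give an infinite t (p = 0) with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        if x.mean() == y.mean():
            return StatResult(0.0, df, 1.0, "independent_t", note="zero pooled variance")
        sign = math.copysign(1.0, x.mean() - y.mean())
        return StatResult(
            sign * math.inf, df, 0.0, "independent_t", note="zero pooled variance, unequal means"
        )
    res = stats.ttest_ind(x, y, equal_var=True)
    return StatResult(float(res.statistic), df, float(res.pvalue), "independent_t")


def ranksum_test(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample has no ties and
    combined n <= 20; otherwise the normal approximation with tie
    correction (no continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs n >= 1")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and pooled.size <= 20
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return StatResult(
        float(res.statistic),
        None,
        float(res.pvalue),
        "ranksum_exact" if exact else "ranksum_normal",
    )


def _check_long(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")


def mixed_anova_2way(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "perturbation",
    within: str = "hemifield",
    subject: str = "session_id",
) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA on a long-format session table.

    Every subject (session) must contribute every within level, and groups
    must be balanced; otherwise an unbalanced-design error is raised.
    Returns the full strata table — between effect, subjects-within-groups,
    within effect, interaction, residual — whose sums of squares partition
    the total exactly.  The between-factor F uses the subjects-within-groups
    mean square (df 1, N-2 for two groups); within and interaction Fs use
    the residual mean square.
    """
    _check_long(table, [dv, between, within, subject])
    wide = table.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: a subject is missing a within-factor cell")
    groups = wide.index.get_level_values(between)
    group_sizes = pd.Series(groups).value_counts()
    if group_sizes.min() < 2:
        raise ValueError("need >= 2 subjects per between-group")
    if group_sizes.nunique() > 1:
        raise ValueError("unbalanced design: unequal subjects per between-group")

    y = wide.to_numpy(dtype=float)  # subjects x within-levels
    n_subj, b = y.shape
    a = group_sizes.size
    n = int(group_sizes.iloc[0])
    gm = y.mean()

    subj_means = y.mean(axis=1)
    group_labels = np.asarray(groups)
    uniq = group_sizes.index.to_list()
    group_means = {g: y[group_labels == g].mean() for g in uniq}
    within_means = y.mean(axis=0)
    cell_means = {g: y[group_labels == g].mean(axis=0) for g in uniq}

    ss_total = ((y - gm) ** 2).sum()
    ss_between_subjects = b * ((subj_means - gm) ** 2).sum()
    ss_a = n * b * sum((group_means[g] - gm) ** 2 for g in uniq)
    ss_subj = ss_between_subjects - ss_a
    ss_b = a * n * ((within_means - gm) ** 2).sum()
    ss_ab = n * sum(
        ((cell_means[g] - group_means[g] - within_means + gm) ** 2).sum() for g in uniq
    )
    ss_resid = ss_total - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, a * (n - 1)
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_resid = a * (n - 1) * (b - 1)

    def _row(name, ss, df, ms_err, df_err):
        ms = ss / df if df > 0 else np.nan
        if ms_err is None or ms_err == 0 or df <= 0:
            f_val, p = np.nan, np.nan
        else:
            f_val = ms / ms_err
            p = float(stats.f.sf(f_val, df, df_err))
        return {"source": name, "ss": ss, "df": df, "ms": ms, "F": f_val, "p": p}

    ms_subj = ss_subj / df_subj if df_subj else np.nan
    ms_resid = ss_resid / df_resid if df_resid else np.nan
    rows = [
        _row(between, ss_a, df_a, ms_subj, df_subj),
        {"source": f"subjects_within_{between}", "ss": ss_subj, "df": df_subj,
         "ms": ms_subj, "F": np.nan, "p": np.nan},
        _row(within, ss_b, df_b, ms_resid, df_resid),
        _row(f"{between} x {within}", ss_ab, df_ab, ms_resid, df_resid),
        {"source": "residual", "ss": ss_resid, "df": df_resid, "ms": ms_resid,
         "F": np.nan, "p": np.nan},
    ]
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = float(ss_total)
    return out


def rm_anova_1way(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "stimulus_type",
    subject: str = "session_id",
    posthoc: bool = True,
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """One-way repeated-measures ANOVA plus Bonferroni paired-t post-hocs.

    F has df (k-1, (k-1)(n-1)); with k = 3 stimulus types and 11 sessions
    that is df (2, 20).  Post-hoc pairwise paired t-tests are Bonferroni
    corrected for the k(k-1)/2 comparisons.
    """
    _check_long(table, [dv, within, subject])
    wide = table.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete within-subject data")
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - gm) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - gm) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df_cond, ss_err / df_err
    if ms_err == 0:
        f_val = 0.0 if ms_cond == 0 else math.inf
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        f_val = ms_cond / ms_err
        p = float(stats.f.sf(f_val, df_cond, df_err))
    anova = pd.DataFrame(
        [
            {"source": within, "ss": ss_cond, "df": df_cond, "ms": ms_cond, "F": f_val, "p": p},
            {"source": "subjects", "ss": ss_subj, "df": n - 1, "ms": ss_subj / (n - 1),
             "F": np.nan, "p": np.nan},
            {"source": "residual", "ss": ss_err, "df": df_err, "ms": ms_err,
             "F": np.nan, "p": np.nan},
        ]
    )
    anova.attrs["ss_total"] = float(ss_total)

    posthocs = None
    if posthoc:
        pairs = list(itertools.combinations(wide.columns, 2))
        rows = []
        for lvl_a, lvl_b in pairs:
            res = stats.ttest_rel(wide[lvl_a], wide[lvl_b])
            rows.append(
                {
                    "level_a": lvl_a,
                    "level_b": lvl_b,
                    "t": float(res.statistic),
                    "df": n - 1,
                    "p_uncorrected": float(res.pvalue),
                    "p_bonferroni": bonferroni(float(res.pvalue), len(pairs)),
                }
            )
        posthocs = pd.DataFrame(rows)
    return anova, posthocs


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value for m comparisons, capped at 1."""
    return min(1.0, p * m)


@dataclass
class PsychometricFit:
    """Cumulative-normal accuracy model over distractor G/R color ratio.

    ``accuracy(x) = lower + (upper - lower) * Phi((x - mu) / sigma)``:
    accuracy rises from the chance floor (a go/stay discrimination, so
    lower defaults to 0.5) toward the upper asymptote as the distractor
    color moves away from the target color (ratio -> 1).  Set
    ``increasing=False`` to flip the orientation for similarity-scaled
    predictors.
    """

    mu: float
    sigma: float
    lower: float = 0.5
    upper: float = 1.0
    increasing: bool = True
    converged: bool = True
    note: str = ""

    def predict(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        frac = stats.norm.cdf(z if self.increasing else -z)
        return self.lower + (self.upper - self.lower) * frac

    def invert(self, target_accuracy: float) -> float:
        """Predictor level at which the fitted curve crosses an accuracy."""
        frac = (target_accuracy - self.lower) / (self.upper - self.lower)
        if not (0.0 < frac < 1.0):
            raise ValueError("target accuracy outside the fitted asymptotes")
        z = stats.norm.ppf(frac)
        return float(self.mu + self.sigma * (z if self.increasing else -z))


def psychometric_fit(
    levels: Sequence[float],
    n_correct: Sequence[float],
    n_total: Sequence[int],
    lower: float = 0.5,
    upper: float = 1.0,
    increasing: bool = True,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-normal fit to binomial accuracy data.

    Needs >= 3 levels.  Degenerate (non-monotone or flat) data still return
    boundary estimates, flagged via ``converged=False`` and ``note``.
    """
    x = np.asarray(levels, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 stimulus levels")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= n_correct <= n_total")

    span = x.max() - x.min()
    if span == 0:
        raise ValueError("levels must not be identical")

    def nll(params: np.ndarray) -> float:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        fit = PsychometricFit(mu, sigma, lower, upper, increasing)
        p = np.clip(fit.predict(x), 1e-9, 1 - 1e-9)
        return float(-(k * np.log(p) + (n - k) * np.log(1 - p)).sum())

    obs = k / n
    mid = (lower + upper) / 2.0
    order = np.argsort(x)
    mu0 = float(np.interp(mid, obs[order] if increasing else obs[order][::-1],
                          x[order] if increasing else x[order][::-1]))
    starts = [(mu0, math.log(span / 4.0)), (float(x.mean()), math.log(span / 2.0))]
    best = None
    for start in starts:
        res = optimize.minimize(
            nll,
            np.asarray(start),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000, "maxfev": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    sigma = math.exp(log_sigma)
    note = ""
    converged = bool(best.success)
    if not (x.min() - 2 * span <= mu <= x.max() + 2 * span) or sigma > 10 * span:
        converged = False
        note = "degenerate data: boundary estimates"
    return PsychometricFit(float(mu), float(sigma), lower, upper, increasing,
                           converged=converged, note=note)
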