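"""Signal Detection Theory metrics: hit/false-alarm rates, d', criterion.

Sensitivity d' = z(hit rate) - z(false-alarm rate) measures how well targets
are discriminated from distractors; the response criterion
c = -0.5 * (z(hit rate) + z(false-alarm rate)) measures the tendency to
select a stimulus in a given hemifield regardless of its identity.  With the
contralesional cell, positive criterion shifts mean "less contra".

Extreme rates (0 or 1) make the z-transform infinite; the default
log-linear correction adds 0.5 to both cells of the affected target or
distractor pair, and every corrected value is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SDTCounts",
    "SDTMetrics",
    "inverse_normal_cdf",
    "rates",
    "dprime",
    "criterion",
    "metrics_from_counts",
    "metrics_table",
    "go_stay_bias",
    "GO_STAY_THRESHOLD_DOUBLE_DIFFERENT",
]

# Neutral go/stay boundary for target-distractor displays: with staying and
# going equally frequent, hit rate = false-alarm rate = 0.25 and the pooled
# criterion equals -z(0.25) = 0.6745 (printed as 0.67).
GO_STAY_THRESHOLD_DOUBLE_DIFFERENT: float = float(-norm.ppf(0.25))


@dataclass(frozen=True)
class SDTCounts:
    """Hit/miss/CR/FA tallies for one analysis cell."""

    hits: int
    misses: int
    correct_rejections: int
    false_alarms: int
    cell: Optional[dict] = None

    def __post_init__(self) -> None:
        for v in (self.hits, self.misses, self.correct_rejections, self.false_alarms):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_target(self) -> int:
        return self.hits + self.misses

    @property
    def n_distractor(self) -> int:
        return self.correct_rejections + self.false_alarms


@dataclass(frozen=True)
class SDTMetrics:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    corrected: bool
    cell: Optional[dict] = None


def inverse_normal_cdf(p: float) -> float:
    """Standard normal quantile z(p); defined only on the open unit interval."""
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError("inverse normal CDF requires 0 < p < 1; apply a rate correction first")
    return float(norm.ppf(p))


def rates(
    counts: SDTCounts, correction: str = "log_linear"
) -> Tuple[float, float, bool]:
    """Hit and false-alarm rates, with optional extreme-rate correction.

    Under ``log_linear``, 0.5 is added to both cells of a pair (hits+misses
    or FA+CR) only when that pair's raw rate is exactly 0 or 1; the returned
    flag records whether any correction was applied.  Zero denominators
    raise (the rate is undefined).
    """
    if correction not in ("none", "log_linear"):
        raise ValueError("correction must be 'none' or 'log_linear'")
    if counts.n_target == 0:
        raise ValueError("hit rate undefined: no target trials in cell")
    if counts.n_distractor == 0:
        raise ValueError("false-alarm rate undefined: no distractor trials in cell")
    hit_rate = counts.hits / counts.n_target
    fa_rate = counts.false_alarms / counts.n_distractor
    corrected = False
    if correction == "log_linear":
        if hit_rate in (0.0, 1.0):
            hit_rate = (counts.hits + 0.5) / (counts.n_target + 1.0)
            corrected = True
        if fa_rate in (0.0, 1.0):
            fa_rate = (counts.false_alarms + 0.5) / (counts.n_distractor + 1.0)
            corrected = True
    return hit_rate, fa_rate, corrected


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity index z(H) - z(F).

    The sign convention makes better-than-chance discrimination positive
    (H > F gives d' > 0), matching the worked before/after example values
    0.77 / 0.84.
    """
    return inverse_normal_cdf(hit_rate) - inverse_normal_cdf(fa_rate)


def criterion(hit_rate: float, fa_rate: float) -> float:
    """Response criterion -0.5 * (z(H) + z(F)); positive = fewer selections."""
    return -0.5 * (inverse_normal_cdf(hit_rate) + inverse_normal_cdf(fa_rate))


def metrics_from_counts(
    counts: SDTCounts, correction: str = "log_linear"
) -> SDTMetrics:
    h, f, corrected = rates(counts, correction)
    return SDTMetrics(
        hit_rate=h,
        fa_rate=f,
        dprime=dprime(h, f),
        criterion=criterion(h, f),
        corrected=corrected,
        cell=counts.cell,
    )


def metrics_table(counts_df: pd.DataFrame, correction: str = "log_linear") -> pd.DataFrame:
    """Append rate/d'/criterion columns to a counts table.

    Expects columns ``hits, misses, correct_rejections, false_alarms``; all
    other columns are treated as cell keys and preserved.
    """
    rows = []
    for _, row in counts_df.iterrows():
        m = metrics_from_counts(
            SDTCounts(
                hits=int(row["hits"]),
                misses=int(row["misses"]),
                correct_rejections=int(row["correct_rejections"]),
                false_alarms=int(row["false_alarms"]),
            ),
            correction=correction,
        )
        rows.append(
            {
                "hit_rate": m.hit_rate,
                "fa_rate": m.fa_rate,
                "dprime": m.dprime,
                "criterion": m.criterion,
                "corrected": m.corrected,
            }
        )
    return pd.concat([counts_df.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


def go_stay_bias(
    pooled_counts: SDTCounts,
    stimulus_type: str,
    correction: str = "log_linear",
) -> Tuple[float, str]:
    """Non-hemifield-selective go/stay bias from hemifield-pooled counts.

    Returns the pooled criterion and a "go"/"stay" label.  For
    target-distractor (double-different) displays the neutral boundary is
    0.6745 (stored at full precision; printed 0.67), the criterion at which
    staying and going are equally frequent; for single and double-same
    displays the boundary is 0.
    """
    h, f, _ = rates(pooled_counts, correction)
    c = criterion(h, f)
    threshold = (
        GO_STAY_THRESHOLD_DOUBLE_DIFFERENT
        if stimulus_type == "double_different"
        else 0.0
    )
    return c, ("stay" if c > threshold else "go")


def round_report(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, as used in reported tables (e.g. -0.14, 0.42)."""
    factor = 10**ndigits
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)
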