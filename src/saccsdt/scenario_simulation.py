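"""Numerical hypothesis scenarios: response bias vs. perceptual deficit.

A scenario fixes the before-perturbation proportions of hits/misses (target
trials) and correct rejections/false alarms (distractor trials) for one
analysis cell, applies signed deltas representing one hypothesis, and
reports the implied rates, d' and criterion before and after.  The default
design uses 100 target and 100 distractor trials (200 total).

The worked anchor: before hits 0.70 / CR 0.60, a response-bias effect of
-0.2 on both hit and false-alarm proportions gives after-rates 0.50 / 0.20,
moving the criterion from -0.14 to 0.42 while d' moves only slightly
(0.78 -> 0.84) — a spatial bias, not a sensitivity change.

Templates encode the qualitative hypothesis predictions per stimulus type
and difficulty, including the floor effect: when the before false-alarm
rate is already near zero a bias-induced decrease cannot manifest, and the
criterion shift is accompanied by a spurious d' drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .sdt_metrics import SDTCounts, SDTMetrics, metrics_from_counts

__all__ = [
    "Scenario",
    "ScenarioResult",
    "apply_scenario",
    "hypothesis_template",
    "sdt_landscape",
    "DEFAULT_EFFECT_DELTA",
    "FA_FLOOR",
]

# Default inactivation-induced change in selection proportion.
DEFAULT_EFFECT_DELTA = 0.2
# Below this before-FA the false-alarm rate is treated as at floor.
FA_FLOOR = 0.05


@dataclass(frozen=True)
class Scenario:
    """Before-proportions plus signed effect deltas for one hemifield cell.

    ``before`` and ``effect`` use keys ``hit`` and ``fa``; misses and
    correct rejections are the complements.  ``after`` proportions are
    ``clip(before + effect)`` into [0, 1]; clipping emits a warning.
    """

    before: Dict[str, float]
    effect: Dict[str, float] = field(default_factory=lambda: {"hit": 0.0, "fa": 0.0})
    n_target_trials: int = 100
    n_distractor_trials: int = 100
    hypothesis_tag: str = "custom"

    def __post_init__(self) -> None:
        for key in ("hit", "fa"):
            if key not in self.before:
                raise ValueError(f"before proportions need key {key!r}")
            if not (0.0 <= self.before[key] <= 1.0):
                raise ValueError(f"before[{key!r}] outside [0, 1]")
        if self.n_target_trials < 1 or self.n_distractor_trials < 1:
            raise ValueError("trial counts must be positive")

    @property
    def n_total(self) -> int:
        return self.n_target_trials + self.n_distractor_trials

    @property
    def after(self) -> Dict[str, float]:
        out = {}
        for key in ("hit", "fa"):
            raw = self.before[key] + self.effect.get(key, 0.0)
            clipped = min(1.0, max(0.0, raw))
            if clipped != raw:
                warnings.warn(
                    f"scenario effect drives {key} proportion to {raw:.3f}; "
                    f"clipped to {clipped:.1f}",
                    stacklevel=2,
                )
            out[key] = clipped
        return out


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    before: SDTMetrics
    after: SDTMetrics
    counts_before: SDTCounts
    counts_after: SDTCounts

    def table(self) -> Dict[str, Tuple[float, float]]:
        """(before, after) pairs in the printed-table layout."""
        sc = self.scenario
        aft = sc.after
        return {
            "hits": (sc.before["hit"], aft["hit"]),
            "misses": (1 - sc.before["hit"], 1 - aft["hit"]),
            "correct_rejections": (1 - sc.before["fa"], 1 - aft["fa"]),
            "false_alarms": (sc.before["fa"], aft["fa"]),
            "hit_rate": (self.before.hit_rate, self.after.hit_rate),
            "fa_rate": (self.before.fa_rate, self.after.fa_rate),
            "criterion": (self.before.criterion, self.after.criterion),
            "dprime": (self.before.dprime, self.after.dprime),
        }


def _largest_remainder(p: float, n: int) -> int:
    """Trials for a proportion of an n-trial pool, conserving the total.

    With two complementary cells, rounding the first by largest remainder
    and giving the rest to the complement conserves n exactly.
    """
    exact = p * n
    base = int(np.floor(exact))
    return base + (1 if exact - base >= 0.5 else 0)


def _to_counts(hit_p: float, fa_p: float, n_t: int, n_d: int) -> SDTCounts:
    hits = _largest_remainder(hit_p, n_t)
    fas = _largest_remainder(fa_p, n_d)
    return SDTCounts(
        hits=hits,
        misses=n_t - hits,
        correct_rejections=n_d - fas,
        false_alarms=fas,
    )


def apply_scenario(scenario: Scenario, correction: str = "log_linear") -> ScenarioResult:
    """Convert proportions to trial counts and compute SDT metrics.

    Counts are exact when proportion x n is integral, otherwise rounded by
    largest remainder (complement cell absorbs the slack, conserving the
    per-pool totals).
    """
    n_t, n_d = scenario.n_target_trials, scenario.n_distractor_trials
    before = _to_counts(scenario.before["hit"], scenario.before["fa"], n_t, n_d)
    aft = scenario.after
    after = _to_counts(aft["hit"], aft["fa"], n_t, n_d)
    return ScenarioResult(
        scenario=scenario,
        before=metrics_from_counts(before, correction),
        after=metrics_from_counts(after, correction),
        counts_before=before,
        counts_after=after,
    )


# Default before-proportions per difficulty (control performance).
_BEFORE = {
    "difficult": {"hit": 0.70, "fa": 0.40},
    "easy": {"hit": 0.90, "fa": 0.02},
}

_STIMULUS_TYPES = ("single", "double_same", "double_different")
_HYPOTHESES = ("response_bias", "perceptual_deficit")


def hypothesis_template(
    stimulus_type: str,
    difficulty: str,
    hypothesis: str,
    hemifield: str = "contra",
    delta: float = DEFAULT_EFFECT_DELTA,
    before: Optional[Dict[str, float]] = None,
) -> Scenario:
    """Parameterized qualitative prediction for one hypothesis and cell.

    Response bias (contra): equal decreases of hit and false-alarm
    proportions; when the before-FA is at floor (< ``FA_FLOOR``) the FA
    delta is 0, which produces the predicted spurious d' drop alongside the
    criterion shift.  Perceptual deficit (contra): hit decrease plus FA
    increase, i.e. a d' drop with little criterion change.

    Ipsilesional companions exist only for double displays: under response
    bias the contralesional selection loss reappears as ipsilesional hit and
    FA increases (FA again floor-limited for easy discrimination); under a
    perceptual deficit single/double-same ipsi cells are unaffected, while
    for double-different displays the across-hemifield coupling makes the
    ipsi cell mirror the deficit (fewer ipsi targets selected, more ipsi
    distractors selected).
    """
    if stimulus_type not in _STIMULUS_TYPES:
        raise ValueError(f"unknown stimulus_type {stimulus_type!r}")
    if difficulty not in _BEFORE:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    if hypothesis not in _HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if hemifield not in ("contra", "ipsi"):
        raise ValueError(f"unknown hemifield {hemifield!r}")

    base = dict(before if before is not None else _BEFORE[difficulty])
    at_floor = base["fa"] < FA_FLOOR

    if hemifield == "contra":
        if hypothesis == "response_bias":
            effect = {"hit": -delta, "fa": 0.0 if at_floor else -delta}
        else:
            effect = {"hit": -delta, "fa": +delta}
    else:
        if stimulus_type == "single":
            effect = {"hit": 0.0, "fa": 0.0}
        elif hypothesis == "response_bias":
            effect = {"hit": +delta, "fa": 0.0 if at_floor else +delta}
        elif stimulus_type == "double_different":
            effect = {"hit": -delta, "fa": +delta}
        else:
            effect = {"hit": 0.0, "fa": 0.0}

    return Scenario(
        before=base,
        effect=effect,
        hypothesis_tag=hypothesis,
    )


def sdt_landscape(grid_resolution: int = 99) -> Dict[str, np.ndarray]:
    """Criterion and d' over the open (false-alarm, hit) unit square.

    Returns ``{"fa": ..., "hit": ..., "criterion": ..., "dprime": ...}``
    where the matrices are indexed ``[hit, fa]`` (false-alarm rate on the
    x-axis / columns, hit rate on the y-axis / rows).
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    from scipy.stats import norm

    edges = np.linspace(0.0, 1.0, grid_resolution + 2)[1:-1]
    z = norm.ppf(edges)
    z_hit = z[:, None]
    z_fa = z[None, :]
    return {
        "fa": edges,
        "hit": edges,
        "criterion": -0.5 * (z_hit + z_fa),
        "dprime": z_hit - z_fa,
    }
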