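"""Seeded synthetic sessions for the color-discrimination saccade task.

The monkey raw data are not distributed with this package, so analyses are
exercised on generated sessions that reproduce the statistical structure the
pipeline assumes: the 13 display configurations in pseudorandom order,
per-condition choice probabilities with a parameterizable unilateral
perturbation effect (a spatial response-criterion shift and/or a perceptual
sensitivity change), truncated-normal saccade latencies with optional
contralesional slowing, and optional raw gaze traces with raised-cosine
saccade kinematics for the velocity-threshold detector.

Default choice probabilities are fixed once to a realistic control
performance (difficult-single anchor: hit rate 0.70, false-alarm rate 0.40;
easy false alarms near zero); see docs/methods.md.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .saccade_detection import EyeTrace
from .task_model import (
    Difficulty,
    Role,
    Side,
    StimulusCondition,
    StimulusType,
    TaskGeometry,
    TaskTiming,
    enumerate_conditions,
)

log = logging.getLogger("saccsdt.synthetic_data")

__all__ = [
    "Response",
    "Pairing",
    "ChoicePolicy",
    "LatencyModel",
    "InactivationEffect",
    "SessionParams",
    "GazeKinematics",
    "Trial",
    "default_control_policy",
    "effective_policy",
    "generate_trial_sequence",
    "simulate_choices",
    "generate_session",
    "generate_gaze_trace",
    "trials_to_frame",
]


class Response(str, Enum):
    SELECT_LEFT = "select_left"
    SELECT_RIGHT = "select_right"
    STAY = "stay"
    ABORTED = "aborted"


class Pairing(str, Enum):
    SAME_ROW = "same_row"
    DIAGONAL = "diagonal"


_RESP_IDX = [Response.SELECT_LEFT, Response.SELECT_RIGHT, Response.STAY]


@dataclass
class ChoicePolicy:
    """Per-condition probabilities over (select_left, select_right, stay).

    ``probs`` maps a condition key (see :class:`StimulusCondition.key`) to a
    length-3 probability vector.  Empty sides must carry zero probability;
    vectors must sum to 1 (tolerance 1e-12).
    """

    probs: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for key, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,):
                raise ValueError(f"policy for {key} must have 3 entries")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"policy for {key} is not a probability vector")
            clean[key] = p
        self.probs = clean

    def for_condition(self, condition: StimulusCondition) -> np.ndarray:
        key = condition.key
        if key not in self.probs:
            raise KeyError(f"policy missing condition {key!r}")
        p = self.probs[key]
        for side, idx in ((Side.LEFT, 0), (Side.RIGHT, 1)):
            if condition.stimulus(side) is None and p[idx] != 0:
                raise ValueError(f"policy for {key} selects an empty side")
        return p


@dataclass(frozen=True)
class LatencyModel:
    """Truncated-normal saccade-latency model (milliseconds).

    Separate means for saccades into the contra- and ipsilesional hemifield;
    the response window caps latencies at 500 ms.
    """

    mean_contra: float = 180.0
    mean_ipsi: float = 180.0
    sd: float = 30.0
    min_latency: float = 100.0
    max_latency: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.min_latency < self.max_latency <= 500.0):
            raise ValueError("need 0 < min_latency < max_latency <= 500 ms")

    def draw(self, n: int, contra: bool, rng: np.random.Generator) -> np.ndarray:
        mean = self.mean_contra if contra else self.mean_ipsi
        a = (self.min_latency - mean) / self.sd
        b = (self.max_latency - mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class InactivationEffect:
    """Behavioral effect of the unilateral perturbation.

    criterion_shift
        Probability mass removed from contralesional selection and moved to
        (ipsilesional selection, stay) in a fixed split (default 50/50; all
        to stay when the ipsilesional side is empty).
    sensitivity_change
        Mixing weight toward the policy of the condition whose contralesional
        stimulus role is swapped (target <-> difficulty-matched distractor),
        degrading perceptual discriminability without a spatial bias.
    """

    criterion_shift: float = 0.0
    sensitivity_change: float = 0.0
    ipsi_split: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.ipsi_split <= 1):
            raise ValueError("ipsi_split must be in [0, 1]")
        if not (0 <= self.sensitivity_change <= 1):
            raise ValueError("sensitivity_change must be in [0, 1]")


@dataclass
class SessionParams:
    """Everything needed to generate one synthetic session."""

    policy: Optional[ChoicePolicy] = None
    latency: LatencyModel = field(default_factory=LatencyModel)
    n_trials_per_condition: int = 75
    seed: int = 0
    perturbation: str = "control"  # "control" | "inactivation"
    effect: InactivationEffect = field(default_factory=InactivationEffect)
    inactivated_side: Side = Side.LEFT
    abort_prob: float = 0.0
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    timing: TaskTiming = field(default_factory=TaskTiming)

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.perturbation not in ("control", "inactivation"):
            raise ValueError("perturbation must be 'control' or 'inactivation'")
        if not (0 <= self.abort_prob < 1):
            raise ValueError("abort_prob must be in [0, 1)")
        self.inactivated_side = Side(self.inactivated_side)
        if self.policy is None:
            self.policy = default_control_policy()

    @property
    def contra_side(self) -> Side:
        """Screen side of the contralesional hemifield."""
        return self.inactivated_side.opposite

    def rng(self, stage: int) -> np.random.Generator:
        # stage-indexed child streams so stages stay independent
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class Trial:
    """One trial: display, geometry, and (after simulation) the outcome."""

    condition: StimulusCondition
    positions: Dict[Side, Tuple[float, float]]
    vertical_pairing: Optional[Pairing]
    go_time: float
    response: Optional[Response] = None
    latency: Optional[float] = None  # ms from go signal
    rewarded: Optional[bool] = None

    @property
    def selected_side(self) -> Optional[Side]:
        if self.response is Response.SELECT_LEFT:
            return Side.LEFT
        if self.response is Response.SELECT_RIGHT:
            return Side.RIGHT
        return None

    def validate(self) -> None:
        if self.response is Response.STAY and self.latency is not None:
            raise ValueError("stay trials carry no latency")
        if self.selected_side is not None and not (0 < (self.latency or 0) <= 500):
            raise ValueError("selection latency must lie in (0, 500] ms")


def default_control_policy(
    conditions: Optional[Sequence[StimulusCondition]] = None,
) -> ChoicePolicy:
    """Control-session choice probabilities.

    The difficult single-stimulus entries realize hit rate 0.70 and
    false-alarm rate 0.40; easy distractors are rarely selected (false
    alarms near zero); double-target displays are almost always followed by
    a saccade, split evenly between sides.
    """
    conds = conditions if conditions is not None else enumerate_conditions()
    # (P(select the stimulus side), P(select other side), P(stay)) templates
    single = {
        Role.TARGET: (0.70, 0.0, 0.30),
        Role.DISTRACTOR_EASY: (0.02, 0.0, 0.98),
        Role.DISTRACTOR_DIFFICULT: (0.40, 0.0, 0.60),
    }
    double_same = {
        Role.TARGET: (0.45, 0.45, 0.10),
        Role.DISTRACTOR_EASY: (0.01, 0.01, 0.98),
        Role.DISTRACTOR_DIFFICULT: (0.20, 0.20, 0.60),
    }
    # (P(select target side), P(select distractor side), P(stay))
    double_different = {
        Role.DISTRACTOR_EASY: (0.90, 0.02, 0.08),
        Role.DISTRACTOR_DIFFICULT: (0.75, 0.15, 0.10),
    }

    probs: Dict[str, np.ndarray] = {}
    for cond in conds:
        p = np.zeros(3)
        if cond.stimulus_type is StimulusType.SINGLE:
            side = Side.LEFT if cond.left is not None else Side.RIGHT
            sel, _, stay = single[cond.stimulus(side).role]
            p[0 if side is Side.LEFT else 1] = sel
            p[2] = stay
        elif cond.stimulus_type is StimulusType.DOUBLE_SAME:
            a, b, stay = double_same[cond.left.role]
            p[:] = (a, b, stay)
        else:
            tside = cond.target_side
            dstim = cond.stimulus(tside.opposite)
            tsel, dsel, stay = double_different[dstim.role]
            p[0 if tside is Side.LEFT else 1] = tsel
            p[1 if tside is Side.LEFT else 0] = dsel
            p[2] = stay
        probs[cond.key] = p
    return ChoicePolicy(probs)


def _swap_partner_key(cond: StimulusCondition, contra: Side) -> Optional[str]:
    """Condition key with the contralesional stimulus role swapped.

    Targets pair with the difficulty-matched distractor (the difficult one
    for target-only displays); distractors pair with the target.  Conditions
    without a contralesional stimulus have no partner.
    """
    stim = cond.stimulus(contra)
    if stim is None:
        return None
    other = cond.stimulus(contra.opposite)
    if stim.is_target:
        if other is not None and not other.is_target:
            new_role = other.role  # difficulty set by the ipsi distractor
        elif cond.difficulty is Difficulty.EASY:
            new_role = Role.DISTRACTOR_EASY
        else:
            new_role = Role.DISTRACTOR_DIFFICULT
    else:
        new_role = Role.TARGET

    if cond.stimulus_type is StimulusType.SINGLE:
        return f"single/{new_role.value}/{contra.value}"
    if cond.stimulus_type is StimulusType.DOUBLE_SAME:
        # contra stimulus becomes different from ipsi -> double_different
        if new_role is Role.TARGET:
            tside = "target_left" if contra is Side.LEFT else "target_right"
            return f"double_different/{cond.left.role.value}/{tside}"
        tside = "target_left" if contra is Side.RIGHT else "target_right"
        return f"double_different/{new_role.value}/{tside}"
    # double_different: swapping makes both sides identical
    if new_role is Role.TARGET:
        return "double_same/target"
    return f"double_same/{new_role.value}"


def effective_policy(params: SessionParams) -> ChoicePolicy:
    """Policy actually sampled from, with the perturbation effect applied.

    Control sessions return the base policy unchanged.  For inactivation
    sessions the criterion shift moves up to ``criterion_shift`` probability
    from contralesional selection to (ipsi, stay); shortfalls (not enough
    contralesional mass, e.g. on rarely selected easy distractors) are
    clipped and the clip event logged.  The
    sensitivity change then mixes each affected condition's vector with its
    role-swapped partner's.
    """
    base = params.policy
    if params.perturbation == "control" or (
        params.effect.criterion_shift == 0 and params.effect.sensitivity_change == 0
    ):
        return base

    contra = params.contra_side
    c_idx = 0 if contra is Side.LEFT else 1
    i_idx = 1 - c_idx
    conds = {c.key: c for c in enumerate_conditions()}
    out: Dict[str, np.ndarray] = {}

    mixed: Dict[str, np.ndarray] = {}
    lam = params.effect.sensitivity_change
    for key, p in base.probs.items():
        cond = conds[key]
        partner = _swap_partner_key(cond, contra) if lam > 0 else None
        if partner is not None and partner in base.probs:
            mixed[key] = (1 - lam) * p + lam * base.probs[partner]
        else:
            mixed[key] = p.copy()

    shift = params.effect.criterion_shift
    for key, p in mixed.items():
        cond = conds[key]
        p = p.copy()
        if shift > 0 and cond.stimulus(contra) is not None:
            move = min(shift, p[c_idx])
            if move < shift:
                log.info("criterion_shift clipped to %.3f for %s", move, key)
            p[c_idx] -= move
            if cond.stimulus(contra.opposite) is not None:
                p[i_idx] += move * params.effect.ipsi_split
                p[2] += move * (1 - params.effect.ipsi_split)
            else:
                p[2] += move
        out[key] = p
    return ChoicePolicy(out)


def _pairings(n: int) -> List[Pairing]:
    half = n // 2
    return [Pairing.SAME_ROW] * (n - half) + [Pairing.DIAGONAL] * half


def generate_trial_sequence(
    params: SessionParams,
    conditions: Optional[Sequence[StimulusCondition]] = None,
) -> List[Trial]:
    """Stimulus sequence for one session (no responses yet).

    Each of the 13 conditions appears exactly ``n_trials_per_condition``
    times in a seeded pseudorandom order.  Double-stimulus trials use
    same-row and diagonal pairings in equal proportions (odd counts give the
    extra trial to same-row); elevations are drawn uniformly.
    """
    conds = list(conditions) if conditions is not None else enumerate_conditions()
    rng = params.rng(0)
    geom, timing = params.geometry, params.timing
    n = params.n_trials_per_condition

    trials: List[Trial] = []
    for cond in conds:
        if cond.stimulus_type is StimulusType.SINGLE:
            pairings: List[Optional[Pairing]] = [None] * n
        else:
            pairings = list(_pairings(n))
        for pairing in pairings:
            slots: Dict[Side, int] = {}
            if pairing is None:
                side = Side.LEFT if cond.left is not None else Side.RIGHT
                slots[side] = int(rng.integers(3))
            elif pairing is Pairing.SAME_ROW:
                k = int(rng.integers(3))
                slots[Side.LEFT] = slots[Side.RIGHT] = k
            else:  # diagonal: upper-left/lower-right or lower-left/upper-right
                if rng.integers(2):
                    slots[Side.LEFT], slots[Side.RIGHT] = 2, 0
                else:
                    slots[Side.LEFT], slots[Side.RIGHT] = 0, 2
            positions = {s: geom.position(s, k) for s, k in slots.items()}
            hold = rng.uniform(timing.fixation_hold_min, timing.fixation_hold_max)
            go_time = 0.2 + hold  # fixation acquisition margin + hold period
            trials.append(Trial(cond, positions, pairing, go_time))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def simulate_choices(
    params: SessionParams, trials: Sequence[Trial]
) -> List[Trial]:
    """Fill responses, latencies and reward flags on a stimulus sequence.

    Responses are drawn per condition from the effect-adjusted policy;
    latencies from the truncated-normal model with the contra/ipsi mean
    selected by the chosen side.  With ``abort_prob`` > 0, aborted trials
    are kept (flagged) and an identical stimulus is re-queued at a random
    later point, so completed counts per condition still match.
    """
    policy = effective_policy(params)
    rng = params.rng(1)
    contra = params.contra_side

    def _resolve(t: Trial, r: Response, latencies: Dict[bool, List[float]]) -> None:
        t.response = r
        side = t.selected_side
        if side is not None:
            t.latency = latencies[side is contra].pop()
            stim = t.condition.stimulus(side)
            t.rewarded = bool(stim is not None and stim.is_target)
        else:
            t.latency = None
            has_target = any(
                s is not None and s.is_target for s in (t.condition.left, t.condition.right)
            )
            t.rewarded = not has_target

    out: List[Trial] = [
        Trial(t.condition, dict(t.positions), t.vertical_pairing, t.go_time)
        for t in trials
    ]

    if params.abort_prob > 0:
        pending, done = list(out), []
        while pending:
            t = pending.pop(0)
            if rng.random() < params.abort_prob:
                t.response = Response.ABORTED
                t.rewarded = False
                done.append(t)
                requeue = Trial(t.condition, dict(t.positions), t.vertical_pairing, t.go_time)
                pending.insert(int(rng.integers(len(pending) + 1)), requeue)
                continue
            p = policy.for_condition(t.condition)
            r = _RESP_IDX[int(rng.choice(3, p=p))]
            lat = {
                True: list(params.latency.draw(1, contra=True, rng=rng)),
                False: list(params.latency.draw(1, contra=False, rng=rng)),
            }
            _resolve(t, r, lat)
            done.append(t)
        return done

    # fast path: draw responses per condition group, latencies in bulk
    by_key: Dict[str, List[Trial]] = {}
    for t in out:
        by_key.setdefault(t.condition.key, []).append(t)
    choices: List[Tuple[Trial, Response]] = []
    for key, group in by_key.items():
        p = policy.for_condition(group[0].condition)
        draws = rng.choice(3, size=len(group), p=p)
        choices.extend((t, _RESP_IDX[int(d)]) for t, d in zip(group, draws))
    n_contra = sum(1 for _, r in choices if _side_of(r) is contra)
    n_select = sum(1 for _, r in choices if r is not Response.STAY)
    latencies = {
        True: list(params.latency.draw(n_contra, contra=True, rng=rng)),
        False: list(params.latency.draw(n_select - n_contra, contra=False, rng=rng)),
    }
    for t, r in choices:
        _resolve(t, r, latencies)
    return out


def _side_of(r: Response) -> Optional[Side]:
    if r is Response.SELECT_LEFT:
        return Side.LEFT
    if r is Response.SELECT_RIGHT:
        return Side.RIGHT
    return None


def generate_session(params: SessionParams) -> List[Trial]:
    """Convenience: sequence + choices in one call."""
    return simulate_choices(params, generate_trial_sequence(params))


@dataclass(frozen=True)
class GazeKinematics:
    """Saccade kinematics for the gaze-trace generator.

    The raised-cosine velocity profile integrates to amplitude
    ``peak_velocity * duration / 2``; when the distance to the selected
    stimulus differs from that amplitude the profile is rescaled so the eye
    lands on the stimulus (duration kept, peak velocity adjusted).
    """

    peak_velocity: float = 800.0  # deg/s
    duration_ms: float = 50.0
    noise_sd: float = 0.0  # deg, white position noise


def generate_gaze_trace(
    trial: Trial,
    kinematics: GazeKinematics = GazeKinematics(),
    seed: int = 0,
    geometry: Optional[TaskGeometry] = None,
    timing: Optional[TaskTiming] = None,
    sample_rate: float = 220.0,
) -> EyeTrace:
    """Synthesize a 220 Hz gaze trace for one completed trial.

    Fixation-hold samples precede the go signal; selection trials contain a
    single saccade with a symmetric raised-cosine velocity profile starting
    at ``go_time + latency`` and landing on the selected stimulus, followed
    by a target-hold epoch.  Stay trials are fixation plus noise throughout.
    """
    geom = geometry or TaskGeometry()
    tim = timing or TaskTiming()
    rng = np.random.default_rng(seed)
    fx, fy = geom.fixation

    side = trial.selected_side
    dur = kinematics.duration_ms / 1000.0
    if side is not None:
        if trial.latency is None:
            raise ValueError("selection trial lacks a latency")
        onset = trial.go_time + trial.latency / 1000.0
        t_end = onset + dur + tim.target_hold
    else:
        onset = None
        t_end = trial.go_time + tim.response_window + 0.2
    t = np.arange(0.0, t_end, 1.0 / sample_rate)

    x = np.full_like(t, fx)
    y = np.full_like(t, fy)
    if side is not None:
        tx, ty = trial.positions[side]
        amp = math.hypot(tx - fx, ty - fy)
        peak = 2.0 * amp / dur
        if peak <= 200.0:
            warnings.warn(
                f"implied peak velocity {peak:.0f} deg/s is at/below the "
                "200 deg/s detection threshold; the saccade may go undetected",
                stacklevel=2,
            )
        tau = np.clip(t - onset, 0.0, dur)
        # integral of the raised-cosine velocity profile, normalized to [0, 1]
        frac = tau / dur - np.sin(2 * np.pi * tau / dur) / (2 * np.pi)
        x = fx + (tx - fx) * frac
        y = fy + (ty - fy) * frac
    if kinematics.noise_sd > 0:
        x = x + rng.normal(0.0, kinematics.noise_sd, size=t.shape)
        y = y + rng.normal(0.0, kinematics.noise_sd, size=t.shape)
    return EyeTrace(t=t, x=x, y=y, nominal_rate=sample_rate)


def trials_to_frame(trials: Sequence[Trial], session_id: int = 0,
                    perturbation: str = "control") -> pd.DataFrame:
    """Flatten trials into the canonical tidy trial table.

    One row per trial; the column dictionary ships in docs/methods.md.
    """
    rows = []
    for i, t in enumerate(trials):
        left, right = t.condition.left, t.condition.right
        lp = t.positions.get(Side.LEFT)
        rp = t.positions.get(Side.RIGHT)
        rows.append(
            {
                "session_id": session_id,
                "perturbation": perturbation,
                "trial_index": i,
                "condition": t.condition.key,
                "stimulus_type": t.condition.stimulus_type.value,
                "difficulty": t.condition.difficulty.value,
                "left_role": left.role.value if left else None,
                "right_role": right.role.value if right else None,
                "vertical_pairing": t.vertical_pairing.value if t.vertical_pairing else None,
                "left_x": lp[0] if lp else np.nan,
                "left_y": lp[1] if lp else np.nan,
                "right_x": rp[0] if rp else np.nan,
                "right_y": rp[1] if rp else np.nan,
                "go_time": t.go_time,
                "response": t.response.value if t.response else None,
                "latency_ms": t.latency if t.latency is not None else np.nan,
                "rewarded": t.rewarded,
            }
        )
    return pd.DataFrame(rows)
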