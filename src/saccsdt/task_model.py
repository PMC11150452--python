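"""Combinatorial structure of the color-discrimination saccade task.

A red target and one of two distractors (an easy yellow one and a difficult
orange one, parameterized by their green/red RGB channel ratio) are shown
alone or in pairs across the two hemifields, giving 13 distinct stimulus
display configurations.  This module encodes the stimulus identities, the
display geometry (radial array at 20 deg eccentricity) and the canonical
enumeration of conditions shared by every other module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Optional, Sequence, Tuple

__all__ = [
    "Role",
    "StimulusType",
    "Difficulty",
    "Side",
    "StimulusIdentity",
    "StimulusCondition",
    "TaskGeometry",
    "TaskTiming",
    "gr_ratio",
    "default_identities",
    "enumerate_conditions",
    "peripheral_positions",
    "load_task_config",
    "TARGET_RGB",
    "EASY_DISTRACTOR_RGB",
    "DIFFICULT_DISTRACTOR_RGB_M1",
    "DIFFICULT_DISTRACTOR_RGB_M2",
]


class Role(str, Enum):
    TARGET = "target"
    DISTRACTOR_EASY = "distractor_easy"
    DISTRACTOR_DIFFICULT = "distractor_difficult"


class StimulusType(str, Enum):
    SINGLE = "single"
    DOUBLE_SAME = "double_same"
    DOUBLE_DIFFERENT = "double_different"


class Difficulty(str, Enum):
    EASY = "easy"
    DIFFICULT = "difficult"
    TARGET_ONLY = "target_only"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


# Stimulus colors (RGB, 0-255).  The difficult distractor differs per animal.
TARGET_RGB: Tuple[int, int, int] = (128, 0, 0)
EASY_DISTRACTOR_RGB: Tuple[int, int, int] = (60, 60, 0)
DIFFICULT_DISTRACTOR_RGB_M1: Tuple[int, int, int] = (128, 11, 0)
DIFFICULT_DISTRACTOR_RGB_M2: Tuple[int, int, int] = (128, 23, 0)

# Luminance metadata (cd/m^2); recorded only, no photometric model.
LUMINANCE_DIM = 11
LUMINANCE_BRIGHT = 35


def gr_ratio(color: Sequence[int]) -> Fraction:
    """Green/red RGB channel ratio of a stimulus color, as an exact rational.

    The ratio parameterizes target/distractor color similarity: the red
    target has ratio 0, the yellow (easy) distractor ratio 1, and difficult
    orange distractors lie in between.  Reporting layers round to 2 decimals.

    Raises
    ------
    ValueError
        If the red channel is zero (the ratio is undefined).
    """
    r, g = int(color[0]), int(color[1])
    if r == 0:
        raise ValueError("G/R ratio undefined: red channel is zero")
    return Fraction(g, r)


@dataclass(frozen=True)
class StimulusIdentity:
    """One of the three stimulus colors, tagged by its task role."""

    role: Role
    color: Tuple[int, int, int]

    def __post_init__(self) -> None:
        ratio = self.gr_ratio
        if self.role is Role.TARGET and ratio != 0:
            raise ValueError("target must have zero green channel (G/R = 0)")
        if self.role is Role.DISTRACTOR_EASY and ratio != 1:
            raise ValueError("easy distractor must have G/R = 1")
        if self.role is Role.DISTRACTOR_DIFFICULT and not (0 < ratio < 1):
            raise ValueError("difficult distractor needs 0 < G/R < 1")

    @property
    def gr_ratio(self) -> Fraction:
        return gr_ratio(self.color)

    @property
    def is_target(self) -> bool:
        return self.role is Role.TARGET


def default_identities(
    difficult_rgb: Tuple[int, int, int] = DIFFICULT_DISTRACTOR_RGB_M1,
) -> dict:
    """Default target / easy / difficult stimulus identities."""
    return {
        Role.TARGET: StimulusIdentity(Role.TARGET, TARGET_RGB),
        Role.DISTRACTOR_EASY: StimulusIdentity(Role.DISTRACTOR_EASY, EASY_DISTRACTOR_RGB),
        Role.DISTRACTOR_DIFFICULT: StimulusIdentity(
            Role.DISTRACTOR_DIFFICULT, tuple(difficult_rgb)
        ),
    }


def _difficulty_for(roles: Sequence[Role]) -> Difficulty:
    if Role.DISTRACTOR_DIFFICULT in roles:
        return Difficulty.DIFFICULT
    if Role.DISTRACTOR_EASY in roles:
        return Difficulty.EASY
    return Difficulty.TARGET_ONLY


@dataclass(frozen=True)
class StimulusCondition:
    """One of the 13 display configurations (what is shown on each side)."""

    stimulus_type: StimulusType
    left: Optional[StimulusIdentity]
    right: Optional[StimulusIdentity]

    def __post_init__(self) -> None:
        n_set = (self.left is not None) + (self.right is not None)
        if self.stimulus_type is StimulusType.SINGLE:
            if n_set != 1:
                raise ValueError("single condition must set exactly one side")
        else:
            if n_set != 2:
                raise ValueError("double condition must set both sides")
            if self.stimulus_type is StimulusType.DOUBLE_SAME:
                if self.left.role is not self.right.role:
                    raise ValueError("double_same requires identical roles")
            else:
                n_targets = self.left.is_target + self.right.is_target
                if n_targets != 1:
                    raise ValueError("double_different requires exactly one target")

    @property
    def difficulty(self) -> Difficulty:
        return _difficulty_for([s.role for s in (self.left, self.right) if s is not None])

    def stimulus(self, side: Side) -> Optional[StimulusIdentity]:
        return self.left if side is Side.LEFT else self.right

    @property
    def target_side(self) -> Optional[Side]:
        """Side holding a target; for double-target displays returns None
        (both sides are targets), as for no-target displays."""
        left_t = self.left is not None and self.left.is_target
        right_t = self.right is not None and self.right.is_target
        if left_t and right_t:
            return None
        if left_t:
            return Side.LEFT
        if right_t:
            return Side.RIGHT
        return None

    @property
    def key(self) -> str:
        """Stable string key, e.g. ``single/target/left`` or
        ``double_different/distractor_easy/target_right``."""
        if self.stimulus_type is StimulusType.SINGLE:
            side = Side.LEFT if self.left is not None else Side.RIGHT
            return f"single/{self.stimulus(side).role.value}/{side.value}"
        if self.stimulus_type is StimulusType.DOUBLE_SAME:
            return f"double_same/{self.left.role.value}"
        distractor = self.right if self.left.is_target else self.left
        tside = "target_left" if self.left.is_target else "target_right"
        return f"double_different/{distractor.role.value}/{tside}"

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return self.key


_ROLE_ORDER = [Role.TARGET, Role.DISTRACTOR_EASY, Role.DISTRACTOR_DIFFICULT]


def enumerate_conditions(identities: Optional[dict] = None) -> list:
    """Enumerate all 13 display configurations in canonical order.

    Order is deterministic: singles, then double-same, then double-different;
    within each block targets before distractors (easy before difficult) and
    left before right.  The ordering itself is a convention of this package
    (condition indices stay stable across runs); the set of configurations is
    fixed by the task: 3 identities x 2 sides singles, 3 identical pairs, and
    2 target-distractor pairings x 2 target sides.
    """
    ids = identities if identities is not None else default_identities()
    out = []
    for role in _ROLE_ORDER:
        stim = ids[role]
        out.append(StimulusCondition(StimulusType.SINGLE, stim, None))
        out.append(StimulusCondition(StimulusType.SINGLE, None, stim))
    for role in _ROLE_ORDER:
        stim = ids[role]
        out.append(StimulusCondition(StimulusType.DOUBLE_SAME, stim, stim))
    for drole in [Role.DISTRACTOR_EASY, Role.DISTRACTOR_DIFFICULT]:
        d = ids[drole]
        t = ids[Role.TARGET]
        out.append(StimulusCondition(StimulusType.DOUBLE_DIFFERENT, t, d))
        out.append(StimulusCondition(StimulusType.DOUBLE_DIFFERENT, d, t))
    return out


@dataclass(frozen=True)
class TaskGeometry:
    """Spatial layout: radial stimulus array around central fixation.

    ``polar_angles`` are degrees relative to the horizontal meridian; the
    same three elevations are used in each hemifield (6 peripheral positions
    total).  ``array_x_offset`` shifts the whole array (fixation included)
    horizontally, as used to equalize baseline left/right choice behavior.
    """

    eccentricity: float = 20.0
    polar_angles: Tuple[float, ...] = (-20.0, 0.0, 20.0)
    window_radius: float = 5.0
    fixation_position: Tuple[float, float] = (0.0, 0.0)
    array_x_offset: float = 0.0

    @property
    def fixation(self) -> Tuple[float, float]:
        """Fixation position with the array offset applied."""
        return (self.fixation_position[0] + self.array_x_offset, self.fixation_position[1])

    def position(self, side: Side, slot: int) -> Tuple[float, float]:
        """Stimulus position for one hemifield and elevation slot (0..2)."""
        theta = math.radians(self.polar_angles[slot])
        dx = self.eccentricity * math.cos(theta)
        dy = self.eccentricity * math.sin(theta)
        if side is Side.LEFT:
            dx = -dx
        fx, fy = self.fixation_position
        return (fx + dx + self.array_x_offset, fy + dy)


@dataclass(frozen=True)
class TaskTiming:
    """Trial event timing constants, in seconds."""

    fixation_acquire_max: float = 0.5
    fixation_hold_min: float = 0.5
    fixation_hold_max: float = 0.9
    response_window: float = 0.5
    target_hold: float = 0.5
    intertrial_interval: float = 2.0


def peripheral_positions(geometry: TaskGeometry = TaskGeometry()) -> list:
    """All six peripheral positions (left slots first, then right)."""
    return [geometry.position(side, k) for side in (Side.LEFT, Side.RIGHT) for k in range(3)]


def load_task_config(path) -> dict:
    """Load and validate a JSON task-config file.

    Schema (all keys optional, defaults above): ``colors`` with
    ``target``/``distractor_easy``/``distractor_difficult`` RGB triples,
    ``geometry`` with TaskGeometry fields, ``timing`` with TaskTiming fields.
    Returns ``{"identities": ..., "geometry": ..., "timing": ...}``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - {"colors", "geometry", "timing"}
    if unknown:
        raise ValueError(f"unknown task-config keys: {sorted(unknown)}")

    colors = raw.get("colors", {})
    difficult = tuple(colors.get("distractor_difficult", DIFFICULT_DISTRACTOR_RGB_M1))
    identities = default_identities(difficult_rgb=difficult)
    if "target" in colors:
        identities[Role.TARGET] = StimulusIdentity(Role.TARGET, tuple(colors["target"]))
    if "distractor_easy" in colors:
        identities[Role.DISTRACTOR_EASY] = StimulusIdentity(
            Role.DISTRACTOR_EASY, tuple(colors["distractor_easy"])
        )

    geo_kwargs = dict(raw.get("geometry", {}))
    for key in ("polar_angles", "fixation_position"):
        if key in geo_kwargs:
            geo_kwargs[key] = tuple(geo_kwargs[key])
    geometry = TaskGeometry(**geo_kwargs)
    timing = TaskTiming(**raw.get("timing", {}))
    if timing.fixation_hold_min > timing.fixation_hold_max:
        raise ValueError("fixation_hold_min must be <= fixation_hold_max")
    return {"identities": identities, "geometry": geometry, "timing": timing}
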