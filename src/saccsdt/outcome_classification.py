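"""Per-hemifield outcome labeling and tallying of completed trials.

Each completed trial yields one label per hemifield that contains a
stimulus, pooled across the three positions within the hemifield: a target
there gives a hit (selected) or miss (not selected); a distractor gives a
false alarm (selected) or correct rejection (not selected); an empty
hemifield is not applicable.  Hemifields are labeled contra-/ipsilesional
relative to the inactivated hemisphere.  The same rule is applied uniformly
to single and double displays, so e.g. selecting the ipsilesional distractor
of a target-distractor pair scores a contralesional miss plus an
ipsilesional false alarm, and staying on a double-distractor display scores
two correct rejections.

Analysis cells contrast each distractor difficulty with the (shared) target
trials, so target-only displays contribute their hit/miss counts to both
the easy and the difficult cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .sdt_metrics import SDTCounts
from .synthetic_data import Response, Trial, trials_to_frame
from .task_model import Side

__all__ = [
    "Hemifield",
    "Outcome",
    "OutcomeLabel",
    "AbortedTrialError",
    "classify_trial",
    "classify_trials",
    "tally_counts",
    "sdt_cells",
    "pooled_counts",
    "accuracy",
    "accuracy_table",
]


class Hemifield(str, Enum):
    CONTRA = "contra"
    IPSI = "ipsi"


class Outcome(str, Enum):
    HIT = "hit"
    MISS = "miss"
    CORRECT_REJECTION = "correct_rejection"
    FALSE_ALARM = "false_alarm"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class OutcomeLabel:
    hemifield: Hemifield
    label: Outcome


class AbortedTrialError(ValueError):
    """Raised when an aborted (excluded) trial is classified."""


def _label_for(role: Optional[str], selected: bool) -> Outcome:
    if role is None:
        return Outcome.NOT_APPLICABLE
    if role == "target":
        return Outcome.HIT if selected else Outcome.MISS
    return Outcome.FALSE_ALARM if selected else Outcome.CORRECT_REJECTION


def classify_trial(
    trial: Trial, inactivated_side: Union[Side, str]
) -> Tuple[OutcomeLabel, OutcomeLabel]:
    """Label one completed trial, returning (contra, ipsi) outcome labels."""
    if trial.response is None or trial.response is Response.ABORTED:
        raise AbortedTrialError("aborted/unfinished trials are excluded from classification")
    inact = Side(inactivated_side)
    contra_side = inact.opposite
    out = []
    for hemi, side in ((Hemifield.CONTRA, contra_side), (Hemifield.IPSI, inact)):
        stim = trial.condition.stimulus(side)
        role = stim.role.value if stim is not None else None
        if role is not None and role != "target":
            role = "distractor"
        out.append(OutcomeLabel(hemi, _label_for(role, trial.selected_side is side)))
    return tuple(out)


def classify_trials(
    trials: Union[pd.DataFrame, Sequence[Trial]],
    inactivated_side: Union[Side, str],
) -> pd.DataFrame:
    """Long-format outcome table: one row per (completed trial, occupied hemifield).

    Accepts a tidy trial table or a sequence of :class:`Trial`.  Aborted
    trials are excluded (reported via the returned frame's ``attrs``
    ``n_excluded``).
    """
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    inact = Side(inactivated_side)
    contra_side = inact.opposite

    completed = frame[frame["response"].isin(["select_left", "select_right", "stay"])]
    n_excluded = len(frame) - len(completed)

    pieces = []
    for hemi, side in ((Hemifield.CONTRA, contra_side), (Hemifield.IPSI, inact)):
        role = completed[f"{side.value}_role"]
        occupied = completed[role.notna()].copy()
        role = role[role.notna()]
        selected = occupied["response"] == f"select_{side.value}"
        is_target = role == "target"
        label = np.where(
            is_target,
            np.where(selected, Outcome.HIT.value, Outcome.MISS.value),
            np.where(selected, Outcome.FALSE_ALARM.value, Outcome.CORRECT_REJECTION.value),
        )
        occupied["hemifield"] = hemi.value
        occupied["outcome"] = label
        pieces.append(occupied)
    out = pd.concat(pieces, ignore_index=True)
    out.attrs["n_excluded"] = int(n_excluded)
    return out


_DEFAULT_KEYS = ("session_id", "perturbation", "stimulus_type", "difficulty")


def tally_counts(
    trials: Union[pd.DataFrame, Sequence[Trial]],
    inactivated_side: Union[Side, str],
    group_keys: Sequence[str] = _DEFAULT_KEYS,
) -> pd.DataFrame:
    """Exact hit/miss/CR/FA counts per analysis cell.

    Cells are ``group_keys`` x hemifield; empty cells simply do not appear
    (downstream treats them as zero).  The number of excluded (aborted)
    trials is reported in ``attrs['n_excluded']``.
    """
    outcomes = classify_trials(trials, inactivated_side)
    keys = [*group_keys, "hemifield"]
    table = (
        outcomes.groupby(keys, observed=True)["outcome"]
        .value_counts()
        .unstack(fill_value=0)
        .reset_index()
    )
    for col, name in (
        (Outcome.HIT.value, "hits"),
        (Outcome.MISS.value, "misses"),
        (Outcome.CORRECT_REJECTION.value, "correct_rejections"),
        (Outcome.FALSE_ALARM.value, "false_alarms"),
    ):
        table[name] = table[col] if col in table else 0
        if col in table and col != name:
            table = table.drop(columns=[col])
    table.attrs["n_excluded"] = outcomes.attrs["n_excluded"]
    return table[[*keys, "hits", "misses", "correct_rejections", "false_alarms"]]


_COUNT_COLS = ["hits", "misses", "correct_rejections", "false_alarms"]


def sdt_cells(tally: pd.DataFrame) -> pd.DataFrame:
    """SDT analysis cells with target-only displays folded into each difficulty.

    For every (easy, difficult) cell the hit/miss counts of the
    difficulty-tagged rows (target-distractor displays) are combined with
    those of the matching target-only rows (single target / double target),
    since each distractor difficulty is contrasted against the same target
    trials.
    """
    if "difficulty" not in tally.columns:
        raise ValueError("tally must retain the 'difficulty' grouping key")
    other = [
        c for c in tally.columns if c not in (*_COUNT_COLS, "difficulty")
    ]
    pieces = []
    t_only = tally[tally["difficulty"] == "target_only"]
    for diff in ("easy", "difficult"):
        part = tally[tally["difficulty"] == diff]
        donated = t_only.assign(difficulty=diff)
        merged = (
            pd.concat([part, donated], ignore_index=True)
            .groupby([*other, "difficulty"], observed=True)[_COUNT_COLS]
            .sum()
            .reset_index()
        )
        pieces.append(merged)
    return pd.concat(pieces, ignore_index=True)[[*other, "difficulty", *_COUNT_COLS]]


def pooled_counts(cells: pd.DataFrame, over: Sequence[str] = ("hemifield",)) -> pd.DataFrame:
    """Sum counts over one or more cell keys (e.g. pool hemifields)."""
    keys = [c for c in cells.columns if c not in (*_COUNT_COLS, *over)]
    return cells.groupby(keys, observed=True)[_COUNT_COLS].sum().reset_index()


def accuracy(rewarded: Iterable[bool], completed: Optional[int] = None) -> float:
    """Proportion of correct (rewarded) trials among completed trials."""
    rewarded = list(rewarded)
    n = completed if completed is not None else len(rewarded)
    if n == 0:
        raise ValueError("accuracy undefined: no completed trials in cell")
    return sum(bool(r) for r in rewarded) / n


def accuracy_table(
    trials: Union[pd.DataFrame, Sequence[Trial]],
    group_keys: Sequence[str] = ("session_id", "perturbation", "stimulus_type"),
) -> pd.DataFrame:
    """Trial-level accuracy per stimulus type x difficulty (hemifields pooled).

    A trial is correct iff it was rewarded, evaluated once per trial (not
    per hemifield), matching reward delivery.  Target-only trials count
    toward both difficulty levels.
    """
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    completed = frame[frame["response"].isin(["select_left", "select_right", "stay"])]
    rows = []
    for diff in ("easy", "difficult"):
        part = completed[completed["difficulty"].isin([diff, "target_only"])]
        grouped = part.groupby(list(group_keys), observed=True)["rewarded"]
        for key, vals in grouped:
            key = key if isinstance(key, tuple) else (key,)
            rows.append(
                {
                    **dict(zip(group_keys, key)),
                    "difficulty": diff,
                    "n_trials": len(vals),
                    "accuracy": accuracy(vals),
                }
            )
    return pd.DataFrame(rows)
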