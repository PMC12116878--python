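"""Domain types, validation, and tidy CSV I/O for trial-level data.

The study design has two phases per task set.  In the preference-judgment
phase (internally guided decision-making, IDM) a participant repeatedly
chooses the preferred of two abstract shapes with no feedback; a stimulus's
*chosen frequency* across its presentations operationalises preference.  In
the gambling phase (externally guided decision-making, EDM) three fixed
stimulus pairs are each presented 50 times and the chosen stimulus pays a
0/1 reward from an independent Bernoulli schedule (0.70 vs 0.30 within each
pair).

Trial indices are 1-based on disk (trial *t* of a task) and kept 1-based in
the records; anything positional downstream converts explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "TaskType",
    "PairId",
    "Stimulus",
    "PrefTrial",
    "GambleTrial",
    "Rating",
    "ParticipantDataset",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "read_study",
    "write_study",
    "chosen_frequency",
    "label_preference_extremes",
]


class SchemaError(ValueError):
    """A CSV is missing a required column or carries an unknown token."""


class ValidationError(ValueError):
    """A row violates a record invariant (reported with its row number)."""


class Role(str, Enum):
    """What a stimulus is, relative to the preference phase and the reward schedule.

    ``pref_high`` / ``pref_low`` are the most- and least-chosen IDM stimuli
    (assigned from observed chosen frequencies, never a priori);
    ``novel_high`` / ``novel_low`` are stimuli first seen in the gambling
    phase, at the 0.70 / 0.30 reward probability; ``idm_only`` stimuli never
    enter the gambling phase.
    """

    PREF_HIGH = "pref_high"
    PREF_LOW = "pref_low"
    NOVEL_HIGH = "novel_high"
    NOVEL_LOW = "novel_low"
    IDM_ONLY = "idm_only"


class TaskType(str, Enum):
    """Gambling-task condition: the IDM-preferred stimulus carries the 0.70
    (``pref_high_prob``) or the 0.30 (``pref_low_prob``) reward probability."""

    PREF_HIGH_PROB = "pref_high_prob"
    PREF_LOW_PROB = "pref_low_prob"


class PairId(str, Enum):
    HIGH_PREF_PAIR = "high_pref_pair"
    LOW_PREF_PAIR = "low_pref_pair"
    NOVEL_PAIR = "novel_pair"


#: initial-value class used by the RL models ("high" / "low" / "novel")
ROLE_CLASS: Mapping[Role, str] = {
    Role.PREF_HIGH: "high",
    Role.PREF_LOW: "low",
    Role.NOVEL_HIGH: "novel",
    Role.NOVEL_LOW: "novel",
}


@dataclass(frozen=True)
class Stimulus:
    """An option in the study.

    ``reward_prob`` is its Bernoulli reward probability in the gambling
    phase (``None`` for stimuli that never reach it).
    """

    stimulus_id: str
    role: Role
    reward_prob: float | None = None

    def __post_init__(self) -> None:
        if self.role is Role.IDM_ONLY:
            if self.reward_prob is not None:
                raise ValidationError(
                    f"stimulus {self.stimulus_id}: idm_only stimuli have no reward_prob"
                )
        else:
            if self.reward_prob is None or not 0.0 <= self.reward_prob <= 1.0:
                raise ValidationError(
                    f"stimulus {self.stimulus_id}: reward_prob must be in [0, 1], "
                    f"got {self.reward_prob!r}"
                )

    @property
    def value_class(self) -> str:
        """Initial-value class for the RL models: 'high', 'low' or 'novel'."""
        if self.role is Role.IDM_ONLY:
            raise ValueError("idm_only stimuli have no initial-value class")
        return ROLE_CLASS[self.role]


def _check_pair(left: str, right: str, chosen: str, where: str) -> None:
    if left == right:
        raise ValidationError(f"{where}: left_stim equals right_stim ({left!r})")
    if chosen not in (left, right):
        raise ValidationError(
            f"{where}: chosen_stim {chosen!r} not in pair ({left!r}, {right!r})"
        )


@dataclass(frozen=True)
class PrefTrial:
    """One forced preference choice between two shapes (no feedback)."""

    participant_id: str
    task_set: int
    block: int
    trial_index: int
    left_stim: str
    right_stim: str
    chosen_stim: str

    def __post_init__(self) -> None:
        where = f"pref trial {self.participant_id}/{self.task_set}/{self.trial_index}"
        if self.task_set not in (1, 2):
            raise ValidationError(f"{where}: task_set must be 1 or 2")
        if self.block < 1 or self.trial_index < 1:
            raise ValidationError(f"{where}: block and trial_index are 1-based")
        _check_pair(self.left_stim, self.right_stim, self.chosen_stim, where)

    @property
    def rejected_stim(self) -> str:
        return self.right_stim if self.chosen_stim == self.left_stim else self.left_stim


@dataclass(frozen=True)
class GambleTrial:
    """One gambling choice with its observed 0/1 reward."""

    participant_id: str
    task_type: TaskType
    pair_id: PairId
    trial_index: int
    left_stim: str
    right_stim: str
    chosen_stim: str
    reward: int

    def __post_init__(self) -> None:
        where = (
            f"gamble trial {self.participant_id}/{self.task_type.value}/{self.trial_index}"
        )
        if self.trial_index < 1:
            raise ValidationError(f"{where}: trial_index is 1-based")
        _check_pair(self.left_stim, self.right_stim, self.chosen_stim, where)
        if self.reward not in (0, 1):
            raise ValidationError(f"{where}: reward must be 0 or 1, got {self.reward!r}")

    @property
    def rejected_stim(self) -> str:
        return self.right_stim if self.chosen_stim == self.left_stim else self.left_stim


@dataclass(frozen=True)
class Rating:
    """Post-task subjective preference on a 5-point Likert scale."""

    participant_id: str
    task_set: int
    stimulus_id: str
    rating: int

    def __post_init__(self) -> None:
        if self.task_set not in (1, 2):
            raise ValidationError(
                f"rating {self.participant_id}/{self.stimulus_id}: task_set must be 1 or 2"
            )
        if self.rating not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"rating {self.participant_id}/{self.stimulus_id}: "
                f"rating must be an integer in 1..5, got {self.rating!r}"
            )


@dataclass
class ParticipantDataset:
    """All records of one participant, gambling trials sorted by (task_type, trial_index)."""

    participant_id: str
    pref_trials: list[PrefTrial] = field(default_factory=list)
    gamble_trials: list[GambleTrial] = field(default_factory=list)
    ratings: list[Rating] = field(default_factory=list)
    #: task type the participant performed first (counterbalancing flag)
    first_task: TaskType | None = None

    def validate(self) -> "ParticipantDataset":
        """Check ordering/gaplessness invariants; returns self for chaining."""
        self.gamble_trials.sort(key=lambda t: (t.task_type.value, t.trial_index))
        for task in TaskType:
            idx = [t.trial_index for t in self.gamble_trials if t.task_type is task]
            if idx and idx != list(range(1, len(idx) + 1)):
                raise ValidationError(
                    f"{self.participant_id}/{task.value}: trial_index not gapless 1..n"
                )
        for task_set in (1, 2):
            idx = [t.trial_index for t in self.pref_trials if t.task_set == task_set]
            if idx and sorted(idx) != list(range(1, len(idx) + 1)):
                raise ValidationError(
                    f"{self.participant_id}/set{task_set}: pref trial_index not gapless 1..n"
                )
        return self

    def gamble_trials_for(self, task: TaskType) -> list[GambleTrial]:
        return [t for t in self.gamble_trials if t.task_type is task]


# ---------------------------------------------------------------------------
# CSV I/O

PREF_COLUMNS = [
    "participant_id", "task_set", "block", "trial_index",
    "left_stim", "right_stim", "chosen_stim",
]
GAMBLE_COLUMNS = [
    "participant_id", "task_type", "pair_id", "trial_index",
    "left_stim", "right_stim", "chosen_stim", "reward",
]
RATING_COLUMNS = ["participant_id", "task_set", "stimulus_id", "rating"]
STIMULUS_COLUMNS = ["participant_id", "task_type", "stimulus_id", "role", "reward_prob"]

_SCHEMAS = {
    "pref": PREF_COLUMNS,
    "gamble": GAMBLE_COLUMNS,
    "ratings": RATING_COLUMNS,
    "stimuli": STIMULUS_COLUMNS,
}


def _read_csv(path: str | Path, schema: str) -> pd.DataFrame:
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _to_int(value: str, column: str, row: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ValidationError(f"row {row}: column {column!r} is not an integer: {value!r}") from exc


def read_trials(path: str | Path, schema: str) -> dict[str, ParticipantDataset]:
    """Read one CSV (``schema`` in {'pref', 'gamble', 'ratings'}) into per-participant datasets.

    Row order is preserved within participant/task; every record invariant is
    checked and violations are reported with the offending (1-based, header
    excluded) row number.
    """
    df = _read_csv(path, schema)
    datasets: dict[str, ParticipantDataset] = {}

    def _ds(pid: str) -> ParticipantDataset:
        return datasets.setdefault(pid, ParticipantDataset(participant_id=pid))

    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            if schema == "pref":
                _ds(row.participant_id).pref_trials.append(
                    PrefTrial(
                        participant_id=row.participant_id,
                        task_set=_to_int(row.task_set, "task_set", i),
                        block=_to_int(row.block, "block", i),
                        trial_index=_to_int(row.trial_index, "trial_index", i),
                        left_stim=row.left_stim,
                        right_stim=row.right_stim,
                        chosen_stim=row.chosen_stim,
                    )
                )
            elif schema == "gamble":
                try:
                    task_type = TaskType(row.task_type)
                    pair_id = PairId(row.pair_id)
                except ValueError as exc:
                    raise SchemaError(f"row {i}: {exc}") from exc
                _ds(row.participant_id).gamble_trials.append(
                    GambleTrial(
                        participant_id=row.participant_id,
                        task_type=task_type,
                        pair_id=pair_id,
                        trial_index=_to_int(row.trial_index, "trial_index", i),
                        left_stim=row.left_stim,
                        right_stim=row.right_stim,
                        chosen_stim=row.chosen_stim,
                        reward=_to_int(row.reward, "reward", i),
                    )
                )
            else:  # ratings
                _ds(row.participant_id).ratings.append(
                    Rating(
                        participant_id=row.participant_id,
                        task_set=_to_int(row.task_set, "task_set", i),
                        stimulus_id=row.stimulus_id,
                        rating=_to_int(row.rating, "rating", i),
                    )
                )
        except ValidationError as exc:
            if str(exc).startswith("row "):
                raise
            raise ValidationError(f"row {i}: {exc}") from exc

    for ds in datasets.values():
        ds.validate()
    return datasets


def _pref_frame(trials: Iterable[PrefTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.participant_id, t.task_set, t.block, t.trial_index,
             t.left_stim, t.right_stim, t.chosen_stim)
            for t in trials
        ],
        columns=PREF_COLUMNS,
    )


def _gamble_frame(trials: Iterable[GambleTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.participant_id, t.task_type.value, t.pair_id.value, t.trial_index,
             t.left_stim, t.right_stim, t.chosen_stim, t.reward)
            for t in trials
        ],
        columns=GAMBLE_COLUMNS,
    )


def _rating_frame(ratings: Iterable[Rating]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.participant_id, r.task_set, r.stimulus_id, r.rating) for r in ratings],
        columns=RATING_COLUMNS,
    )


def write_trials(path: str | Path, datasets: Mapping[str, ParticipantDataset], schema: str) -> None:
    """Write one CSV for all participants; inverse of :func:`read_trials`."""
    ordered = [datasets[pid] for pid in sorted(datasets)]
    if schema == "pref":
        frame = _pref_frame(t for ds in ordered for t in ds.pref_trials)
    elif schema == "gamble":
        frame = _gamble_frame(t for ds in ordered for t in ds.gamble_trials)
    elif schema == "ratings":
        frame = _rating_frame(r for ds in ordered for r in ds.ratings)
    else:
        raise SchemaError(f"unknown schema {schema!r}")
    frame.to_csv(path, index=False, lineterminator="\n")


def read_study(directory: str | Path) -> dict[str, ParticipantDataset]:
    """Read pref_trials.csv, gamble_trials.csv and ratings.csv from a directory,
    merging them into one dataset per participant."""
    directory = Path(directory)
    datasets = read_trials(directory / "pref_trials.csv", "pref")
    for schema, fname in (("gamble", "gamble_trials.csv"), ("ratings", "ratings.csv")):
        extra = read_trials(directory / fname, schema)
        for pid, ds in extra.items():
            tgt = datasets.setdefault(pid, ParticipantDataset(participant_id=pid))
            tgt.gamble_trials.extend(ds.gamble_trials)
            tgt.ratings.extend(ds.ratings)
    for ds in datasets.values():
        ds.validate()
    return datasets


def write_study(directory: str | Path, datasets: Mapping[str, ParticipantDataset]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trials(directory / "pref_trials.csv", datasets, "pref")
    write_trials(directory / "gamble_trials.csv", datasets, "gamble")
    write_trials(directory / "ratings.csv", datasets, "ratings")


# ---------------------------------------------------------------------------
# Preference summaries

def chosen_frequency(pref_trials: Sequence[PrefTrial]) -> dict[str, float]:
    """Proportion of its presentations in which each stimulus was chosen.

    Stimuli that never appear are simply absent; a stimulus presented but
    never chosen maps to 0.0.
    """
    presented: dict[str, int] = {}
    chosen: dict[str, int] = {}
    for t in pref_trials:
        for s in (t.left_stim, t.right_stim):
            presented[s] = presented.get(s, 0) + 1
            chosen.setdefault(s, 0)
        chosen[t.chosen_stim] += 1
    return {s: chosen[s] / presented[s] for s in presented}


def label_preference_extremes(
    freqs: Mapping[str, float], tie_break: str = "error"
) -> tuple[str, str]:
    """Most- and least-chosen stimulus ids from a chosen-frequency map.

    Ties at the maximum or minimum raise by default; with
    ``tie_break='lexicographic'`` the smallest stimulus id wins
    deterministically (useful in large simulation sweeps).
    """
    if len(freqs) < 2:
        raise ValueError("need at least two stimuli to label extremes")
    if tie_break not in ("error", "lexicographic"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    fmax = max(freqs.values())
    fmin = min(freqs.values())
    top = sorted(s for s, f in freqs.items() if f == fmax)
    bottom = sorted(s for s, f in freqs.items() if f == fmin)
    if tie_break == "error" and (len(top) > 1 or len(bottom) > 1):
        raise ValueError(
            f"tie in chosen frequencies (max: {top}, min: {bottom}); "
            "pass tie_break='lexicographic' to break deterministically"
        )
    high = top[0]
    low = next(s for s in bottom if s != high)
    return high, low
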