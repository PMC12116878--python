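"""The four preference-seeded Q-learning models.

All four share the same learning machinery on a two-armed bandit:

* delta-rule value update for the chosen option only,
  ``Q_i(t+1) = Q_i(t) + alpha * (r(t) - Q_i(t))``, the rejected option's
  value untouched;
* softmax (logistic) choice between the pair's two values,
  ``P(chosen) = 1 / (1 + exp(-beta * (Q_chosen - Q_rejected)))``.

They differ only in how initial values are seeded from the preference
phase.  Each stimulus belongs to an initial-value class — ``high`` (the
IDM-preferred stimulus), ``low`` (the least chosen), or ``novel`` — and
each model maps classes to free initial-value parameters (eta slots):

========  =======  =======  =======  ============
model     high     low      novel    distinct etas
RL1       eta      eta      eta      1
RL2       eta1     eta2     eta2     2
RL3       eta1     eta2     eta1     2
RL4       eta1     eta2     eta3     3
========  =======  =======  =======  ============

RL1 is the no-preference-transfer null; RL2 seeds only the preferred
stimulus; RL3 seeds only the non-preferred stimulus apart; RL4 frees all
three classes.  With tied eta slots every model collapses onto RL1, which
the likelihood tests exploit.

With rewards in {0, 1} and initial values in [0, 1], every update is a
convex combination, so Q stays in [0, 1] throughout (closure); the
implementation relies on this rather than clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .core_data import GambleTrial, PairId, Role, Stimulus, TaskType

__all__ = [
    "ModelSpec",
    "ParamSet",
    "QState",
    "QTrajectory",
    "MODELS",
    "get_model",
    "init_values",
    "update_q",
    "choice_prob",
    "session_loglik",
    "simulate_session",
    "q_trajectory",
    "encode_session",
    "loglik_arrays",
    "trajectory_frame",
]


@dataclass(frozen=True)
class ModelSpec:
    """One of the four models: a name plus the class -> eta-slot map."""

    name: str
    slot_of_class: Mapping[str, int]  # {"high": i, "low": j, "novel": k}

    @property
    def n_etas(self) -> int:
        return len(set(self.slot_of_class.values()))

    @property
    def n_params(self) -> int:
        """alpha, beta, then the eta slots."""
        return 2 + self.n_etas

    @property
    def param_names(self) -> list[str]:
        if self.n_etas == 1:
            etas = ["eta"]
        else:
            etas = [f"eta{i + 1}" for i in range(self.n_etas)]
        return ["alpha", "beta", *etas]


MODELS: dict[str, ModelSpec] = {
    "RL1": ModelSpec("RL1", {"high": 0, "low": 0, "novel": 0}),
    "RL2": ModelSpec("RL2", {"high": 0, "low": 1, "novel": 1}),
    "RL3": ModelSpec("RL3", {"high": 0, "low": 1, "novel": 0}),
    "RL4": ModelSpec("RL4", {"high": 0, "low": 1, "novel": 2}),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; expected one of {sorted(MODELS)}") from None


@dataclass(frozen=True)
class ParamSet:
    """alpha (learning rate), beta (inverse temperature), and the eta initial values.

    alpha and every eta live in [0, 1]; beta is non-negative with its upper
    bound left to the run configuration (the printed bound beta <= 1 is kept
    as the default there but is deliberately configurable).
    """

    alpha: float
    beta: float
    etas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not all(0.0 <= e <= 1.0 for e in self.etas):
            raise ValueError(f"every eta must be in [0, 1], got {self.etas}")

    def for_model(self, model: ModelSpec) -> "ParamSet":
        if len(self.etas) != model.n_etas:
            raise ValueError(
                f"{model.name} needs {model.n_etas} eta value(s), got {len(self.etas)}"
            )
        return self

    def as_vector(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, *self.etas], dtype=np.float64)

    @classmethod
    def from_vector(cls, theta: Sequence[float]) -> "ParamSet":
        return cls(alpha=float(theta[0]), beta=float(theta[1]),
                   etas=tuple(float(e) for e in theta[2:]))


@dataclass
class QState:
    """Current values per stimulus and the trial counter."""

    q: dict[str, float]
    t: int = 0


@dataclass
class QTrajectory:
    """Per-stimulus value series over the presentations of its pair.

    ``series[s]`` has one entry per trial of s's pair plus the leading
    initial value, so ``series[s][0]`` is Q before the first trial and
    ``series[s][-1]`` the value after the pair's last trial.
    """

    series: dict[str, list[float]]

    def initial(self, stimulus_id: str) -> float:
        return self.series[stimulus_id][0]

    def final(self, stimulus_id: str) -> float:
        return self.series[stimulus_id][-1]


# ---------------------------------------------------------------------------
# Elementary operations

def update_q(q: float, reward: int, alpha: float) -> float:
    """Delta-rule update for a chosen option: q + alpha * (reward - q)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return q + alpha * (reward - q)


def choice_prob(q_chosen: float, q_rejected: float, beta: float) -> float:
    """Softmax probability of the chosen option given the pair's two values."""
    if not (math.isfinite(q_chosen) and math.isfinite(q_rejected)):
        raise ValueError("values must be finite")
    if not (math.isfinite(beta) and beta >= 0.0):
        raise ValueError(f"beta must be finite and >= 0, got {beta}")
    x = beta * (q_chosen - q_rejected)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def _log_choice_prob(x: float) -> float:
    """log(1 / (1 + exp(-x))), numerically stable for large |x|."""
    if x >= 0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


def init_values(model: ModelSpec, params: ParamSet, stimuli: Sequence[Stimulus]) -> QState:
    """Seed each gambling stimulus's initial value from its eta slot."""
    params.for_model(model)
    q: dict[str, float] = {}
    for s in stimuli:
        if s.role is Role.IDM_ONLY:
            continue
        cls = s.value_class
        if cls not in model.slot_of_class:
            raise KeyError(f"model {model.name} does not map class {cls!r}")
        q[s.stimulus_id] = params.etas[model.slot_of_class[cls]]
    return QState(q=q, t=0)


# ---------------------------------------------------------------------------
# Array encoding + numba likelihood core

@njit(cache=True)
def _loglik_core(chosen, other, reward, slot_of_stim, alpha, beta, etas):  # pragma: no cover
    n_stim = slot_of_stim.shape[0]
    q = np.empty(n_stim)
    for i in range(n_stim):
        q[i] = etas[slot_of_stim[i]]
    total = 0.0
    for t in range(chosen.shape[0]):
        c = chosen[t]
        x = beta * (q[c] - q[other[t]])
        if x >= 0.0:
            total += -np.log1p(np.exp(-x))
        else:
            total += x - np.log1p(np.exp(x))
        q[c] = q[c] + alpha * (reward[t] - q[c])
    return total


@dataclass(frozen=True)
class EncodedSession:
    """Trials of one gambling task as integer arrays, ready for the likelihood core."""

    stim_ids: tuple[str, ...]
    slot_of_stim: np.ndarray  # eta-slot index per stimulus
    chosen: np.ndarray
    other: np.ndarray
    reward: np.ndarray


def encode_session(
    model: ModelSpec, trials: Sequence[GambleTrial], stimuli: Sequence[Stimulus]
) -> EncodedSession:
    """Map a task's trials onto index arrays.

    ``stimuli`` carries the role of every stimulus the trials reference;
    the two gambling tasks use disjoint stimuli, so sessions are encoded
    (and values evolve) per task.
    """
    by_id = {s.stimulus_id: s for s in stimuli}
    ids: list[str] = []
    index: dict[str, int] = {}
    for t in trials:
        for sid in (t.left_stim, t.right_stim):
            if sid not in index:
                if sid not in by_id:
                    raise KeyError(f"trial references unknown stimulus {sid!r}")
                index[sid] = len(ids)
                ids.append(sid)
    slot = np.array(
        [model.slot_of_class[by_id[sid].value_class] for sid in ids], dtype=np.int64
    )
    chosen = np.array([index[t.chosen_stim] for t in trials], dtype=np.int64)
    other = np.array([index[t.rejected_stim] for t in trials], dtype=np.int64)
    reward = np.array([t.reward for t in trials], dtype=np.float64)
    return EncodedSession(tuple(ids), slot, chosen, other, reward)


def loglik_arrays(encoded: EncodedSession, theta: np.ndarray) -> float:
    """Log-likelihood of one encoded task at parameter vector theta = (alpha, beta, etas...)."""
    return float(
        _loglik_core(
            encoded.chosen, encoded.other, encoded.reward, encoded.slot_of_stim,
            theta[0], theta[1], np.asarray(theta[2:], dtype=np.float64),
        )
    )


def session_loglik(
    model: ModelSpec,
    params: ParamSet,
    trials: Sequence[GambleTrial],
    stimuli: Sequence[Stimulus],
) -> float:
    """Summed log choice probability over an ordered gambling session.

    Trials must be ordered by (task_type, trial_index); the three pairs of a
    task interleave freely and share one evolving value table.  Values are
    seeded per task (the two tasks' stimuli are disjoint, so their values
    never interact).
    """
    params.for_model(model)
    total = 0.0
    theta = params.as_vector()
    for task in TaskType:
        task_trials = [t for t in trials if t.task_type is task]
        if not task_trials:
            continue
        if [t.trial_index for t in task_trials] != list(range(1, len(task_trials) + 1)):
            raise ValueError(f"{task.value}: trials not ordered gapless by trial_index")
        total += loglik_arrays(encode_session(model, task_trials, stimuli), theta)
    return total


# ---------------------------------------------------------------------------
# Simulation and trajectories

def simulate_session(
    model: ModelSpec,
    params: ParamSet,
    schedule,  # GambleSchedule (synthetic_data); duck-typed to avoid a cycle
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> list[GambleTrial]:
    """Generate one gambling session by running the model forward.

    Choices are drawn from the softmax probabilities; each trial the reward
    of *both* pair members is drawn independently at that stimulus's reward
    probability, but only the chosen one's realisation is revealed (recorded)
    and learned from — the counterfactual draw is discarded.
    """
    params.for_model(model)
    state = init_values(model, params, schedule.stimuli)
    prob = {s.stimulus_id: s.reward_prob for s in schedule.stimuli}
    trials: list[GambleTrial] = []
    counters: dict[PairId, int] = {}
    for pair_id, left, right in schedule.presentations:
        p_left = choice_prob(state.q[left], state.q[right], params.beta)
        chose_left = rng.random() < p_left
        chosen, rejected = (left, right) if chose_left else (right, left)
        r_chosen = int(rng.random() < prob[chosen])
        _ = rng.random() < prob[rejected]  # counterfactual draw, never revealed
        counters[pair_id] = counters.get(pair_id, 0) + 1
        trials.append(
            GambleTrial(
                participant_id=participant_id,
                task_type=schedule.task_type,
                pair_id=pair_id,
                trial_index=len(trials) + 1,
                left_stim=left,
                right_stim=right,
                chosen_stim=chosen,
                reward=r_chosen,
            )
        )
        state.q[chosen] = update_q(state.q[chosen], r_chosen, params.alpha)
    return trials


def q_trajectory(
    model: ModelSpec,
    params: ParamSet,
    trials: Sequence[GambleTrial],
    stimuli: Sequence[Stimulus],
) -> QTrajectory:
    """Replay a session and record each stimulus's value after every trial of its pair."""
    params.for_model(model)
    series: dict[str, list[float]] = {}
    for task in TaskType:
        task_trials = [t for t in trials if t.task_type is task]
        if not task_trials:
            continue
        state = init_values(
            model, params,
            [s for s in stimuli
             if s.stimulus_id in {x for t in task_trials for x in (t.left_stim, t.right_stim)}],
        )
        for sid in state.q:
            series[sid] = [state.q[sid]]
        for t in task_trials:
            state.q[t.chosen_stim] = update_q(state.q[t.chosen_stim], t.reward, params.alpha)
            series[t.left_stim].append(state.q[t.left_stim])
            series[t.right_stim].append(state.q[t.right_stim])
    return QTrajectory(series=series)


def trajectory_frame(
    participant_id: str,
    task_type: TaskType,
    trajectory: QTrajectory,
    stimuli: Sequence[Stimulus],
) -> pd.DataFrame:
    """Tidy export: participant_id, task_type, stimulus_id, trial_of_pair, q_value.

    ``trial_of_pair`` 0 is the initial value.
    """
    ids = {s.stimulus_id for s in stimuli}
    rows = [
        (participant_id, task_type.value, sid, k, q)
        for sid, values in trajectory.series.items()
        if sid in ids
        for k, q in enumerate(values)
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "task_type", "stimulus_id", "trial_of_pair", "q_value"]
    )
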