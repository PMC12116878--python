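"""Synthetic studies with the two-phase preference/gambling design.

Each participant completes two task sets with disjoint stimuli.  A task set
is: a 105-trial preference-judgment phase over 7 shapes (every one of the
C(7,2)=21 unordered pairs once per block, 5 blocks, so each shape appears
30 times), then a 150-trial gambling phase over 3 fixed pairs presented 50
times each with independent 0.70/0.30 Bernoulli rewards, then 5-point
ratings.  One task set puts the preference-phase favourite on the 0.70
schedule ("preferred stimulus high probability task"), the other puts the
other set's favourite on 0.30; which comes first is counterbalanced across
participants.

Preference choices come from a logistic rule on latent preference
strengths — a participant-specific random permutation of an evenly spaced
7-level hierarchy, strong enough that the empirically labelled favourite /
least-liked almost always coincide with the latent extremes (the preference
phase itself is not the fitted model); gambling
choices come from :func:`prefbandit.rl_models.simulate_session` under a
configurable generating model.  Ratings are a rounded, clipped linear blend
of latent preference and final learned value plus noise, so both of the
design's qualitative rating effects (favourite rated highest; novel 70% >
novel 30%) are reproducible and can be switched off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .core_data import (
    GambleTrial,
    PairId,
    ParticipantDataset,
    PrefTrial,
    Rating,
    Role,
    Stimulus,
    TaskType,
    chosen_frequency,
    label_preference_extremes,
    write_study,
    STIMULUS_COLUMNS,
)
from .rl_models import ModelSpec, ParamSet, get_model, q_trajectory, simulate_session

__all__ = [
    "PrefSchedule",
    "GambleSchedule",
    "LatentPreference",
    "ParamSampler",
    "StudyConfig",
    "build_pref_schedule",
    "simulate_idm_participant",
    "build_gamble_schedule",
    "generate_study",
    "write_synthetic_study",
]

N_IDM_STIMULI = 7
TRIALS_PER_BLOCK = 21
N_BLOCKS = 5
REPS_PER_PAIR = 50
REWARD_HIGH = 0.70
REWARD_LOW = 0.30


@dataclass(frozen=True)
class PrefSchedule:
    """105 ordered preference pairs: 5 blocks, each a shuffle of all 21 pairs."""

    stimulus_ids: tuple[str, ...]
    #: (block, left, right) per trial, blocks 1..5
    presentations: tuple[tuple[int, str, str], ...]


@dataclass(frozen=True)
class GambleSchedule:
    """A gambling task: its 6 stimuli with roles/reward probabilities and
    the randomized order of 150 pair presentations (50 per pair)."""

    task_type: TaskType
    stimuli: tuple[Stimulus, ...]
    #: (pair_id, left, right) per trial
    presentations: tuple[tuple[PairId, str, str], ...]


@dataclass
class LatentPreference:
    """Latent preference strength per stimulus, with optional choice-induced drift.

    With ``drift`` > 0 the chosen item's strength rises by ``drift`` and the
    rejected one's falls by it after every preference trial (free-choice
    preference change as a generative option only; it is never fitted).
    """

    strengths: dict[str, float]
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.drift < 0:
            raise ValueError("drift must be >= 0")


@dataclass(frozen=True)
class ParamSampler:
    """Per-participant generating parameters for the gambling phase.

    Defaults: alpha uniform on [0.1, 0.6]; beta fixed at 0.8 x the default
    inverse-temperature cap (4.0 = 0.8 x 5; calibrated so an initial-value
    gap of 0.3 yields first-encounter choice proportions near the reported
    ~0.8); eta slots fixed at (0.7, 0.4, ...) so the preferred-stimulus
    slot clearly exceeds the others.  Any entry may instead be a (lo, hi)
    range to sample per participant.
    """

    alpha: tuple[float, float] = (0.1, 0.6)
    beta: float | tuple[float, float] = 4.0
    etas: tuple[float | tuple[float, float], ...] = (0.7, 0.4, 0.4)

    def draw(self, model: ModelSpec, rng: np.random.Generator) -> ParamSet:
        def _draw(spec):
            if isinstance(spec, tuple):
                lo, hi = spec
                return float(rng.uniform(lo, hi))
            return float(spec)

        if len(self.etas) < model.n_etas:
            raise ValueError(f"need {model.n_etas} eta specs for {model.name}")
        return ParamSet(
            alpha=_draw(self.alpha),
            beta=_draw(self.beta),
            etas=tuple(_draw(e) for e in self.etas[: model.n_etas]),
        )


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the synthetic study; defaults are the study's design constants."""

    n_participants: int = 42
    choice_sensitivity: float = 2.0
    #: spacing of the 7 evenly spaced latent preference levels; at the
    #: default logistic sensitivity this makes the labelled extremes match
    #: the latent extremes for >= 95% of simulated participants
    latent_step: float = 1.1
    drift: float = 0.0
    #: rating = round(clip(a*latent + b*q_final + intercept + noise, 1, 5))
    rating_latent_weight: float = 0.8
    rating_value_weight: float = 2.0
    rating_intercept: float = 2.0
    rating_noise_sd: float = 0.5
    label_tie_break: str = "lexicographic"


# ---------------------------------------------------------------------------
# Schedules

def build_pref_schedule(
    rng: np.random.Generator, stimulus_ids: Sequence[str] | None = None
) -> PrefSchedule:
    """All 21 unordered pairs of 7 stimuli, shuffled independently per block,
    left/right randomized per trial."""
    if stimulus_ids is None:
        stimulus_ids = tuple(f"S{chr(ord('A') + i)}" for i in range(N_IDM_STIMULI))
    ids = tuple(stimulus_ids)
    if len(ids) != N_IDM_STIMULI:
        raise ValueError(f"expected {N_IDM_STIMULI} stimulus ids, got {len(ids)}")
    pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    presentations: list[tuple[int, str, str]] = []
    for block in range(1, N_BLOCKS + 1):
        order = rng.permutation(len(pairs))
        for k in order:
            a, b = pairs[k]
            if rng.random() < 0.5:
                a, b = b, a
            presentations.append((block, a, b))
    return PrefSchedule(stimulus_ids=ids, presentations=tuple(presentations))


def simulate_idm_participant(
    latent: LatentPreference,
    schedule: PrefSchedule,
    choice_sensitivity: float,
    rng: np.random.Generator,
    participant_id: str = "sim",
    task_set: int = 1,
) -> list[PrefTrial]:
    """Preference choices from a logistic rule on latent strengths.

    P(left) = logistic(sensitivity * (z_left - z_right)); with drift enabled
    the chosen/rejected strengths move up/down after each trial.
    """
    if choice_sensitivity < 0:
        raise ValueError("choice_sensitivity must be >= 0")
    z = dict(latent.strengths)
    trials: list[PrefTrial] = []
    for i, (block, left, right) in enumerate(schedule.presentations, start=1):
        x = choice_sensitivity * (z[left] - z[right])
        p_left = float(expit(x))
        chosen, rejected = (left, right) if rng.random() < p_left else (right, left)
        if latent.drift:
            z[chosen] += latent.drift
            z[rejected] -= latent.drift
        trials.append(
            PrefTrial(
                participant_id=participant_id,
                task_set=task_set,
                block=block,
                trial_index=i,
                left_stim=left,
                right_stim=right,
                chosen_stim=chosen,
            )
        )
    latent.strengths.update(z)
    return trials


def build_gamble_schedule(
    task_type: TaskType,
    pref_high: str,
    pref_low: str,
    rng: np.random.Generator,
    novel_ids: Sequence[str] | None = None,
    reps_per_pair: int = REPS_PER_PAIR,
) -> GambleSchedule:
    """Assemble the three pairs and their randomized 150-trial order.

    The preference-phase favourite and least-liked are each paired with a
    previously unseen partner at the complementary reward probability; the
    third pair is two unseen stimuli at 0.70 vs 0.30.  In the
    ``pref_high_prob`` task the favourite is on 0.70; in ``pref_low_prob``
    it is on 0.30 (and the least-liked on 0.70).
    """
    if pref_high == pref_low:
        raise ValueError("pref_high and pref_low must differ")
    if novel_ids is None:
        novel_ids = tuple(f"N{i}" for i in range(1, 5))
    partner_high, partner_low, novel_a, novel_b = novel_ids

    if task_type is TaskType.PREF_HIGH_PROB:
        p_pref_high, p_pref_low = REWARD_HIGH, REWARD_LOW
    elif task_type is TaskType.PREF_LOW_PROB:
        p_pref_high, p_pref_low = REWARD_LOW, REWARD_HIGH
    else:
        raise ValueError(f"unknown task_type {task_type!r}")

    def _complement(p: float) -> float:
        return REWARD_LOW if p == REWARD_HIGH else REWARD_HIGH

    def _novel_role(p: float) -> Role:
        return Role.NOVEL_HIGH if p == REWARD_HIGH else Role.NOVEL_LOW

    stimuli = (
        Stimulus(pref_high, Role.PREF_HIGH, p_pref_high),
        Stimulus(partner_high, _novel_role(_complement(p_pref_high)),
                 _complement(p_pref_high)),
        Stimulus(pref_low, Role.PREF_LOW, p_pref_low),
        Stimulus(partner_low, _novel_role(_complement(p_pref_low)),
                 _complement(p_pref_low)),
        Stimulus(novel_a, Role.NOVEL_HIGH, REWARD_HIGH),
        Stimulus(novel_b, Role.NOVEL_LOW, REWARD_LOW),
    )
    pair_members = {
        PairId.HIGH_PREF_PAIR: (pref_high, partner_high),
        PairId.LOW_PREF_PAIR: (pref_low, partner_low),
        PairId.NOVEL_PAIR: (novel_a, novel_b),
    }
    order = [pid for pid in PairId for _ in range(reps_per_pair)]
    order = [order[k] for k in rng.permutation(len(order))]
    presentations: list[tuple[PairId, str, str]] = []
    for pid in order:
        a, b = pair_members[pid]
        if rng.random() < 0.5:
            a, b = b, a
        presentations.append((pid, a, b))
    return GambleSchedule(task_type=task_type, stimuli=stimuli,
                          presentations=tuple(presentations))


# ---------------------------------------------------------------------------
# Whole-study generation

def _set_stimulus_ids(task_set: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Disjoint id namespaces for the two task sets: 7 IDM + 4 gambling-only each."""
    idm = tuple(f"T{task_set}{chr(ord('A') + i)}" for i in range(N_IDM_STIMULI))
    novel = tuple(f"T{task_set}N{i}" for i in range(1, 5))
    return idm, novel


@dataclass
class SyntheticStudy:
    """A generated study plus its ground truth (the key for recovery tests)."""

    datasets: dict[str, ParticipantDataset]
    #: per participant: generating ParamSet
    true_params: dict[str, ParamSet]
    #: per participant: {task_type: [Stimulus, ...]} with roles and reward probs
    stimulus_tables: dict[str, dict[TaskType, tuple[Stimulus, ...]]]
    #: per participant per task set: latent strengths and intended extremes
    latents: dict[str, dict[int, dict]]
    generating_model: str
    seed: int
    config: StudyConfig

    def stimuli_for(self, participant_id: str, task: TaskType) -> tuple[Stimulus, ...]:
        return self.stimulus_tables[participant_id][task]


def generate_study(
    n_participants: int,
    generating_model: ModelSpec | str,
    param_sampler: ParamSampler,
    rng: np.random.Generator | int,
    config: StudyConfig | None = None,
) -> SyntheticStudy:
    """Simulate a complete study: per participant two task sets, each
    preference phase -> gambling phase -> ratings, task order counterbalanced.

    The favourite/least-liked labels that define the gambling pairs are the
    ones *recovered from the simulated preference choices* (exactly as an
    experimenter would assign them), not the latent truth; the latent
    intended extremes are kept alongside for validation.
    """
    if n_participants < 2:
        raise ValueError("need n_participants >= 2 for counterbalancing")
    model = get_model(generating_model) if isinstance(generating_model, str) else generating_model
    cfg = config or StudyConfig(n_participants=n_participants)
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    datasets: dict[str, ParticipantDataset] = {}
    true_params: dict[str, ParamSet] = {}
    stim_tables: dict[str, dict[TaskType, tuple[Stimulus, ...]]] = {}
    latents: dict[str, dict[int, dict]] = {}

    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        params = param_sampler.draw(model, rng)
        true_params[pid] = params
        ds = ParticipantDataset(participant_id=pid)
        stim_tables[pid] = {}
        latents[pid] = {}
        # counterbalance which condition the first task set carries
        first_type = TaskType.PREF_HIGH_PROB if p % 2 == 0 else TaskType.PREF_LOW_PROB
        ds.first_task = first_type
        for task_set in (1, 2):
            task_type = first_type if task_set == 1 else (
                TaskType.PREF_LOW_PROB if first_type is TaskType.PREF_HIGH_PROB
                else TaskType.PREF_HIGH_PROB
            )
            idm_ids, novel_ids = _set_stimulus_ids(task_set)
            levels = np.linspace(-3.0, 3.0, len(idm_ids)) * cfg.latent_step
            z = {s: float(v)
                 for s, v in zip(idm_ids, rng.permutation(levels))}
            latent = LatentPreference(strengths=dict(z), drift=cfg.drift)
            schedule = build_pref_schedule(rng, idm_ids)
            pref_trials = simulate_idm_participant(
                latent, schedule, cfg.choice_sensitivity, rng,
                participant_id=pid, task_set=task_set,
            )
            ds.pref_trials.extend(pref_trials)
            freqs = chosen_frequency(pref_trials)
            high, low = label_preference_extremes(freqs, tie_break=cfg.label_tie_break)
            z_sorted = sorted(z, key=z.get)
            latents[pid][task_set] = {
                "strengths": z,
                "intended_high": z_sorted[-1],
                "intended_low": z_sorted[0],
                "labelled_high": high,
                "labelled_low": low,
                "task_type": task_type.value,
            }
            gamble_schedule = build_gamble_schedule(task_type, high, low, rng, novel_ids)
            stim_tables[pid][task_type] = gamble_schedule.stimuli
            gamble_trials = simulate_session(model, params, gamble_schedule, rng,
                                             participant_id=pid)
            ds.gamble_trials.extend(gamble_trials)
            ds.ratings.extend(
                _simulate_ratings(pid, task_set, model, params, gamble_schedule,
                                  gamble_trials, latent, cfg, rng)
            )
        datasets[pid] = ds.validate()

    return SyntheticStudy(
        datasets=datasets,
        true_params=true_params,
        stimulus_tables=stim_tables,
        latents=latents,
        generating_model=model.name,
        seed=seed if seed is not None else -1,
        config=cfg,
    )


def _simulate_ratings(
    pid: str,
    task_set: int,
    model: ModelSpec,
    params: ParamSet,
    schedule: GambleSchedule,
    gamble_trials: list[GambleTrial],
    latent: LatentPreference,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> list[Rating]:
    """Ratings for the task set's gambling stimuli: monotone noisy blend of
    latent preference and final learned value."""
    traj = q_trajectory(model, params, gamble_trials, schedule.stimuli)
    ratings = []
    for s in schedule.stimuli:
        z = latent.strengths.get(s.stimulus_id, 0.0)
        q_final = traj.final(s.stimulus_id)
        raw = (
            cfg.rating_latent_weight * z
            + cfg.rating_value_weight * q_final
            + cfg.rating_intercept
            + rng.normal(0.0, cfg.rating_noise_sd)
        )
        ratings.append(
            Rating(
                participant_id=pid,
                task_set=task_set,
                stimulus_id=s.stimulus_id,
                rating=int(np.clip(round(raw), 1, 5)),
            )
        )
    return ratings


# ---------------------------------------------------------------------------
# Serialisation

def write_synthetic_study(directory: str | Path, study: SyntheticStudy) -> None:
    """Write pref_trials/gamble_trials/ratings/stimuli CSVs plus truth.json.

    stimuli.csv records each gambling stimulus's role and reward probability
    (the design key an experimenter would hold); truth.json additionally
    records generating parameters and latents for recovery checks.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_study(directory, study.datasets)

    rows = ["\t".join(STIMULUS_COLUMNS).replace("\t", ",")]
    for pid in sorted(study.stimulus_tables):
        for task in TaskType:
            if task not in study.stimulus_tables[pid]:
                continue
            for s in study.stimulus_tables[pid][task]:
                rows.append(f"{pid},{task.value},{s.stimulus_id},{s.role.value},{s.reward_prob}")
    (directory / "stimuli.csv").write_text("\n".join(rows) + "\n")

    truth = {
        "generating_model": study.generating_model,
        "seed": study.seed,
        "config": {k: getattr(study.config, k) for k in (
            "n_participants", "choice_sensitivity", "latent_step", "drift",
            "rating_latent_weight", "rating_value_weight", "rating_intercept",
            "rating_noise_sd", "label_tie_break")},
        "participants": {
            pid: {
                "params": {
                    "alpha": study.true_params[pid].alpha,
                    "beta": study.true_params[pid].beta,
                    "etas": list(study.true_params[pid].etas),
                },
                "first_task": study.datasets[pid].first_task.value,
                "task_sets": {
                    str(ts): study.latents[pid][ts] for ts in study.latents[pid]
                },
            }
            for pid in sorted(study.datasets)
        },
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_stimulus_table(path: str | Path) -> dict[str, dict[TaskType, tuple[Stimulus, ...]]]:
    """Read stimuli.csv back into per-participant, per-task stimulus tuples."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    out: dict[str, dict[TaskType, list[Stimulus]]] = {}
    for row in df.itertuples(index=False):
        task = TaskType(row.task_type)
        out.setdefault(row.participant_id, {}).setdefault(task, []).append(
            Stimulus(row.stimulus_id, Role(row.role), float(row.reward_prob))
        )
    return {
        pid: {task: tuple(stims) for task, stims in tasks.items()}
        for pid, tasks in out.items()
    }
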