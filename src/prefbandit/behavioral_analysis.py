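"""Behavioral statistics for the preference/gambling study.

Covers the study's non-model analyses: the paired contrast of chosen
frequencies for the most- vs least-preferred shapes, correct-response-rate
tables and their 2x2 repeated-measures ANOVA (gambling-task condition x
stimulus type), one-sample above-chance tests, all pairwise rating
contrasts with Holm's step-down correction, first-trial choice proportions,
and the three-way ANOVA on model-derived initial/final values.

"Correct" is choosing a pair's 0.70-probability member: with asymmetric
Bernoulli payoffs that option maximises expected reward, so it is the
normative answer the instruction "pick the correct shape" refers to.

Effect sizes follow the field's reporting conventions: Cohen's d for paired
t (mean difference over the SD of the differences) and partial eta squared
for ANOVA effects.  No sphericity correction is applied — every factor here
has two levels, where the correction is vacuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .core_data import (
    GambleTrial,
    PairId,
    ParticipantDataset,
    Rating,
    Role,
    Stimulus,
    TaskType,
    chosen_frequency,
)
from .rl_models import QTrajectory

__all__ = [
    "StatResult",
    "pref_frequency_contrast",
    "correct_rate_table",
    "rm_anova_2x2",
    "above_chance_tests",
    "rating_comparisons",
    "first_trial_choice",
    "value_stage_table",
    "value_stage_anova",
    "holm_adjust",
    "paired_t",
    "results_frame",
]

StimulusTable = Mapping[str, Mapping[TaskType, Sequence[Stimulus]]]


@dataclass(frozen=True)
class StatResult:
    """One reported test: statistic, df, p, effect size, optional adjusted p."""

    effect: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float
    effect_size_name: str
    p_adjusted: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def results_frame(results: Iterable[StatResult]) -> pd.DataFrame:
    """Tidy one-row-per-test export."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "statistic": r.statistic,
                "df": "/".join(f"{d:g}" for d in r.df),
                "p_value": r.p_value,
                "effect_size": r.effect_size,
                "effect_size_name": r.effect_size_name,
                "p_adjusted": r.p_adjusted,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Elementary tests

def paired_t(x: np.ndarray, y: np.ndarray, effect: str) -> StatResult:
    """Paired t-test with Cohen's d = mean(x - y) / sd(x - y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    flags: tuple[str, ...] = ()
    if sd == 0:
        if np.all(diff == 0):
            t, p, d = 0.0, 1.0, 0.0
        else:
            t = math.inf if diff.mean() > 0 else -math.inf
            p, d = 0.0, math.inf
        flags = ("zero_variance",)
    else:
        t, p = stats.ttest_rel(x, y)
        d = diff.mean() / sd
    return StatResult(effect=effect, statistic=float(t), df=(len(x) - 1,),
                      p_value=float(p), effect_size=float(d),
                      effect_size_name="cohen_d", flags=flags)


def one_sample_t(x: np.ndarray, popmean: float, effect: str) -> StatResult:
    x = np.asarray(x, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a vector with n >= 2")
    sd = x.std(ddof=1)
    flags: tuple[str, ...] = ()
    if sd == 0:
        if x[0] == popmean:
            t, p, d = 0.0, 1.0, 0.0
        else:
            t = math.inf if x[0] > popmean else -math.inf
            p, d = 0.0, math.inf
        flags = ("zero_variance",)
    else:
        t, p = stats.ttest_1samp(x, popmean)
        d = (x.mean() - popmean) / sd
    return StatResult(effect=effect, statistic=float(t), df=(len(x) - 1,),
                      p_value=float(p), effect_size=float(d),
                      effect_size_name="cohen_d", flags=flags)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, never below the raw p)."""
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="holm")
    return [float(p) for p in adjusted]


def _partial_eta_sq(f: float, df1: float, df2: float) -> float:
    if math.isinf(f):
        return 1.0
    return f * df1 / (f * df1 + df2)


def _rm_anova(frame: pd.DataFrame, depvar: str, subject: str,
              within: list[str]) -> list[StatResult]:
    """Repeated-measures ANOVA via statsmodels, effects as StatResults.

    All-equal cells (zero error variance) yield F = 0, p = 1 rather than an
    exception from the underlying solver.
    """
    if frame.groupby([subject, *within]).size().max() != 1:
        raise ValueError("design must have exactly one observation per cell")
    n_cells = int(np.prod([frame[w].nunique() for w in within]))
    per_subject = frame.groupby(subject).size()
    if (per_subject != n_cells).any() or \
            frame.groupby(within).size().nunique() != 1:
        raise ValueError("incomplete within-subject design (missing cells)")
    if np.allclose(frame[depvar].var(ddof=0), 0.0):
        # all cells identical: every effect is exactly zero (two-level factors)
        from itertools import combinations

        n_sub = frame[subject].nunique()
        return [
            StatResult(effect=":".join(combo), statistic=0.0,
                       df=(1.0, float(n_sub - 1)), p_value=1.0,
                       effect_size=0.0, effect_size_name="partial_eta_sq",
                       flags=("zero_variance",))
            for k in range(1, len(within) + 1)
            for combo in combinations(within, k)
        ]
    res = AnovaRM(frame, depvar=depvar, subject=subject, within=within).fit()
    table = res.anova_table
    out = []
    for effect, row in table.iterrows():
        f = float(row["F Value"])
        df1, df2 = float(row["Num DF"]), float(row["Den DF"])
        out.append(StatResult(effect=effect.replace(" * ", ":"), statistic=f,
                              df=(df1, df2), p_value=float(row["Pr > F"]),
                              effect_size=_partial_eta_sq(f, df1, df2),
                              effect_size_name="partial_eta_sq"))
    return out


# ---------------------------------------------------------------------------
# Study analyses

def pref_frequency_contrast(datasets: Mapping[str, ParticipantDataset]) -> StatResult:
    """Paired t of chosen frequency, most- vs least-preferred stimulus.

    Per participant, each task set's extremes are taken from that set's own
    chosen frequencies, then the high (and low) frequencies are averaged
    across the two sets before the test.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two participants")
    highs, lows = [], []
    for pid in sorted(datasets):
        ds = datasets[pid]
        h_vals, l_vals = [], []
        for task_set in (1, 2):
            trials = [t for t in ds.pref_trials if t.task_set == task_set]
            if not trials:
                continue
            freqs = chosen_frequency(trials)
            h_vals.append(max(freqs.values()))
            l_vals.append(min(freqs.values()))
        if not h_vals:
            raise ValueError(f"{pid}: no preference trials")
        highs.append(np.mean(h_vals))
        lows.append(np.mean(l_vals))
    return paired_t(np.array(highs), np.array(lows),
                    effect="chosen_frequency_high_vs_low")


def correct_rate_table(
    datasets: Mapping[str, ParticipantDataset],
    stimulus_table: StimulusTable,
) -> pd.DataFrame:
    """Per participant x task_type x pair_id proportion of choices of the
    0.70-probability stimulus.  Pairs with no trials are dropped with a warning."""
    import logging

    logger = logging.getLogger(__name__)
    rows = []
    for pid in sorted(datasets):
        ds = datasets[pid]
        for task in TaskType:
            trials = ds.gamble_trials_for(task)
            if not trials:
                continue
            prob = {s.stimulus_id: s.reward_prob
                    for s in stimulus_table[pid][task]}
            for pair in PairId:
                pair_trials = [t for t in trials if t.pair_id is pair]
                if not pair_trials:
                    logger.warning("%s/%s/%s: no trials, excluded",
                                   pid, task.value, pair.value)
                    continue
                correct = sum(prob[t.chosen_stim] > prob[t.rejected_stim]
                              for t in pair_trials)
                rows.append({"participant_id": pid, "task_type": task.value,
                             "pair_id": pair.value,
                             "correct_rate": correct / len(pair_trials),
                             "n_trials": len(pair_trials)})
    return pd.DataFrame(rows)


def rm_anova_2x2(rates: pd.DataFrame) -> list[StatResult]:
    """2 (task condition) x 2 (IDM vs novel pair) repeated-measures ANOVA on
    correct rates, plus simple effects of task condition within each
    stimulus type when the interaction is significant.

    The two preference pairs (favourite's and least-liked's) are averaged
    into one "idm" level per participant and condition.
    """
    df = rates.copy()
    df["stimulus_type"] = np.where(df.pair_id == PairId.NOVEL_PAIR.value,
                                   "novel", "idm")
    cell = (df.groupby(["participant_id", "task_type", "stimulus_type"],
                       as_index=False)["correct_rate"].mean())
    results = _rm_anova(cell, "correct_rate", "participant_id",
                        ["task_type", "stimulus_type"])
    interaction = next(r for r in results if set(r.effect.split(":")) ==
                       {"task_type", "stimulus_type"})
    if interaction.p_value < 0.05:
        wide = cell.pivot_table(index="participant_id",
                                columns=["stimulus_type", "task_type"],
                                values="correct_rate")
        for stim_type in ("idm", "novel"):
            res = paired_t(
                wide[(stim_type, TaskType.PREF_HIGH_PROB.value)].to_numpy(),
                wide[(stim_type, TaskType.PREF_LOW_PROB.value)].to_numpy(),
                effect=f"simple:task_type@{stim_type}",
            )
            # report the two-condition simple effect on the F scale too
            f = res.statistic ** 2
            results.append(StatResult(
                effect=res.effect, statistic=f, df=(1.0, res.df[0]),
                p_value=res.p_value,
                effect_size=_partial_eta_sq(f, 1.0, res.df[0]),
                effect_size_name="partial_eta_sq", flags=res.flags))
    return results


def above_chance_tests(rates: pd.DataFrame) -> list[StatResult]:
    """One-sample t vs 0.5 for every task condition x pair cell."""
    out = []
    for (task, pair), grp in rates.groupby(["task_type", "pair_id"], sort=True):
        out.append(one_sample_t(grp["correct_rate"].to_numpy(), 0.5,
                                effect=f"above_chance:{task}:{pair}"))
    return out


_RATED_ROLES = (Role.PREF_HIGH, Role.PREF_LOW, Role.NOVEL_HIGH, Role.NOVEL_LOW)


def key_stimuli(
    dataset: ParticipantDataset,
    task: TaskType,
    stimuli: Sequence[Stimulus],
) -> dict[str, str]:
    """The four stimuli the rating and value contrasts are about.

    The favourite and least-liked carry their preference roles; the novel
    0.70/0.30 members are the *novel pair's* two stimuli, identified from
    the trials — the unseen partners completing the preference pairs also
    have novel roles but are not part of this contrast set.
    """
    by_id = {s.stimulus_id: s for s in stimuli}
    out: dict[str, str] = {}
    for s in stimuli:
        if s.role is Role.PREF_HIGH:
            out["pref_high"] = s.stimulus_id
        elif s.role is Role.PREF_LOW:
            out["pref_low"] = s.stimulus_id
    novel_members = {x for t in dataset.gamble_trials_for(task)
                     if t.pair_id is PairId.NOVEL_PAIR
                     for x in (t.left_stim, t.right_stim)}
    for sid in novel_members:
        label = "novel_high" if by_id[sid].reward_prob > 0.5 else "novel_low"
        out[label] = sid
    return out


def rating_comparisons(
    datasets: Mapping[str, ParticipantDataset],
    stimulus_table: StimulusTable,
) -> list[StatResult]:
    """All pairwise paired t-tests among the four key stimuli's ratings,
    Holm-corrected within each gambling-task condition.

    The four stimuli are the favourite, the least-liked, and the novel
    pair's 0.70 and 0.30 members (the partners completing the preference
    pairs are not part of this contrast set).
    """
    rows = []
    for pid in sorted(datasets):
        ds = datasets[pid]
        ratings = {(r.task_set, r.stimulus_id): r.rating for r in ds.ratings}
        for task in TaskType:
            if task not in stimulus_table[pid]:
                continue
            keys = key_stimuli(ds, task, stimulus_table[pid][task])
            task_sets = {r.task_set for r in ds.ratings
                         if r.stimulus_id in keys.values()}
            for ts in task_sets:
                for label, sid in keys.items():
                    if (ts, sid) in ratings:
                        rows.append({"participant_id": pid,
                                     "task_type": task.value,
                                     "role": label,
                                     "rating": ratings[(ts, sid)]})
    frame = pd.DataFrame(rows)
    results = []
    for task in TaskType:
        sub = frame[frame.task_type == task.value]
        wide = sub.pivot_table(index="participant_id", columns="role",
                               values="rating")
        tests = []
        roles = [r.value for r in _RATED_ROLES if r.value in wide.columns]
        for i in range(len(roles)):
            for j in range(i + 1, len(roles)):
                tests.append(paired_t(wide[roles[i]].to_numpy(),
                                      wide[roles[j]].to_numpy(),
                                      effect=f"rating:{task.value}:"
                                             f"{roles[i]}_vs_{roles[j]}"))
        adjusted = holm_adjust([t.p_value for t in tests])
        results.extend(
            StatResult(effect=t.effect, statistic=t.statistic, df=t.df,
                       p_value=t.p_value, effect_size=t.effect_size,
                       effect_size_name=t.effect_size_name,
                       p_adjusted=adj, flags=t.flags)
            for t, adj in zip(tests, adjusted)
        )
    return results


_DEFAULT_DESIGNATED = {
    PairId.HIGH_PREF_PAIR: Role.PREF_HIGH,
    PairId.LOW_PREF_PAIR: Role.PREF_LOW,
    PairId.NOVEL_PAIR: Role.NOVEL_HIGH,
}


def first_trial_choice(
    datasets: Mapping[str, ParticipantDataset],
    stimulus_table: StimulusTable,
    designated: Mapping[PairId, Role] = _DEFAULT_DESIGNATED,
) -> pd.DataFrame:
    """Proportion of participants choosing each pair's designated stimulus on
    that pair's first presentation, per task condition.

    Defaults: the preference-labelled member for the two preference pairs
    and the 0.70 member for the novel pair — the quantities behind the
    "chose it on the very first encounter" descriptive statistics.
    """
    rows = []
    for pid in sorted(datasets):
        ds = datasets[pid]
        for task in TaskType:
            trials = ds.gamble_trials_for(task)
            if not trials:
                continue
            role_of = {s.stimulus_id: s.role for s in stimulus_table[pid][task]}
            for pair in PairId:
                first = next((t for t in trials if t.pair_id is pair), None)
                if first is None:
                    continue
                rows.append({"participant_id": pid, "task_type": task.value,
                             "pair_id": pair.value,
                             "chose_designated":
                                 role_of[first.chosen_stim] is designated[pair]})
    df = pd.DataFrame(rows)
    return (df.groupby(["task_type", "pair_id"], as_index=False)
            .agg(proportion=("chose_designated", "mean"),
                 n=("chose_designated", "size")))


def value_stage_table(
    trajectories: Mapping[str, Mapping[TaskType, QTrajectory]],
    stimulus_table: StimulusTable,
    datasets: Mapping[str, ParticipantDataset],
) -> pd.DataFrame:
    """Initial and final model values of the four key stimuli, tidy per
    participant x task condition x stimulus type x reward probability x stage."""
    rows = []
    for pid, by_task in trajectories.items():
        for task, traj in by_task.items():
            keys = key_stimuli(datasets[pid], task, stimulus_table[pid][task])
            prob_of = {s.stimulus_id: s.reward_prob
                       for s in stimulus_table[pid][task]}
            for label, sid in keys.items():
                stim_type = "idm" if label.startswith("pref") else "novel"
                prob = "high" if prob_of[sid] > 0.5 else "low"
                for stage, value in (("initial", traj.initial(sid)),
                                     ("final", traj.final(sid))):
                    rows.append({"participant_id": pid, "task_type": task.value,
                                 "stimulus_type": stim_type,
                                 "reward_prob": prob, "stage": stage,
                                 "q_value": value})
    return pd.DataFrame(rows)


def value_stage_anova(values: pd.DataFrame, task_type: TaskType) -> list[StatResult]:
    """Three-way within-subject ANOVA (stimulus type x reward probability x
    stage) on one task condition's values, plus the stimulus-type simple
    effect within each stage.

    The stage-wise simple effects carry the study's substantive question:
    a stimulus-type effect on *initial* values means preferences seeded the
    gambling values; its absence on *final* values means reward learning
    washed the seeding out.
    """
    sub = values[values.task_type == task_type.value]
    if sub.empty:
        raise ValueError(f"no values for {task_type.value}")
    results = _rm_anova(sub, "q_value", "participant_id",
                        ["stimulus_type", "reward_prob", "stage"])
    wide = sub.pivot_table(index="participant_id",
                           columns=["stage", "stimulus_type"],
                           values="q_value")  # mean over reward_prob
    for stage in ("initial", "final"):
        res = paired_t(wide[(stage, "idm")].to_numpy(),
                       wide[(stage, "novel")].to_numpy(),
                       effect=f"simple:stimulus_type@{stage}")
        f = res.statistic ** 2
        results.append(StatResult(
            effect=res.effect, statistic=f, df=(1.0, res.df[0]),
            p_value=res.p_value, effect_size=_partial_eta_sq(f, 1.0, res.df[0]),
            effect_size_name="partial_eta_sq", flags=res.flags))
    return results
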