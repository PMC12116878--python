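"""Seeded end-to-end orchestration: configuration, stages, and manifests.

A run is a sequence of stages over one output directory:

``simulate``  write a synthetic study (trial CSVs + stimuli.csv + truth.json)
``fit``       per-participant posterior-mean parameters and value trajectories
``compare``   WBIC table over the four models with Bayes factors vs. the best
``analyze``   behavioral statistics and first-trial proportions
``recover``   parameter- and model-recovery simulations

Every stage derives its randomness from the master seed and records what it
read and wrote (with SHA-256 hashes) in ``manifest.json``, so any table is
traceable to a seed and identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import TaskType, read_study
from .inference import (
    DEFAULT_BETA_MAX,
    PriorSpec,
    SamplerConfig,
    compare_models,
    fit_point_estimates,
    model_recovery,
    parameter_recovery,
    prepare_participant,
)
from .rl_models import ParamSet, get_model, q_trajectory, trajectory_frame
from .synthetic_data import (
    ParamSampler,
    StudyConfig,
    generate_study,
    read_stimulus_table,
    write_synthetic_study,
)
from .behavioral_analysis import (
    above_chance_tests,
    correct_rate_table,
    first_trial_choice,
    pref_frequency_contrast,
    rating_comparisons,
    results_frame,
    rm_anova_2x2,
    value_stage_anova,
    value_stage_table,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "compare", "analyze", "recover")


class PipelineError(RuntimeError):
    """A stage cannot run (bad config or missing upstream artifact)."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; defaults mirror the study's design constants
    (42 participants, 105 preference trials, 50 presentations per pair,
    0.70/0.30 rewards) with the package's calibrated inverse-temperature
    cap (see :data:`prefbandit.inference.DEFAULT_BETA_MAX`)."""

    seed: int
    out_dir: str = "run"
    n_participants: int = 42
    generating_model: str = "RL2"
    fit_model: str = "RL2"
    models: tuple[str, ...] = ("RL1", "RL2", "RL3", "RL4")
    beta_max: float = DEFAULT_BETA_MAX
    alpha_range: tuple[float, float] = (0.1, 0.6)
    beta_value: float | None = None  # default: 0.8 * beta_max
    eta_values: tuple[float, ...] = (0.7, 0.4, 0.4)
    choice_sensitivity: float = 2.0
    drift: float = 0.0
    n_chains: int = 4
    n_draws: int = 2500
    n_warmup: int = 1000
    recover_n_datasets: int = 10
    recover_n_per_model: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PipelineError("a master seed is mandatory")
        if not 0.0 < self.beta_max:
            raise PipelineError("beta_max must be positive")
        for e in self.eta_values:
            if not 0.0 <= e <= 1.0:
                raise PipelineError("eta values must lie in [0, 1]")
        for name in (self.generating_model, self.fit_model, *self.models):
            get_model(name)  # raises on unknown names

    @property
    def sampler(self) -> SamplerConfig:
        return SamplerConfig(n_chains=self.n_chains, n_draws=self.n_draws,
                             n_warmup=self.n_warmup)

    @property
    def param_sampler(self) -> ParamSampler:
        beta = self.beta_value if self.beta_value is not None else 0.8 * self.beta_max
        return ParamSampler(alpha=self.alpha_range, beta=beta, etas=self.eta_values)

    @property
    def study_config(self) -> StudyConfig:
        return StudyConfig(n_participants=self.n_participants,
                           choice_sensitivity=self.choice_sensitivity,
                           drift=self.drift)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        for key in ("models", "eta_values", "alpha_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError(f"invalid config: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_rng(config: RunConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per stage of one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(STAGES.index(stage) + 1)[-1]
    )


class Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.path = out_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "seed": config.seed,
                         "config": dataclasses.asdict(config), "stages": {}}

    def record(self, stage: str, outputs: list[Path], params: dict) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}: run the '{produced_by}' stage first"
        )
    return path


def _load_data_and_stimuli(data_dir: Path):
    _require(data_dir / "gamble_trials.csv", "simulate")
    datasets = read_study(data_dir)
    table = read_stimulus_table(_require(data_dir / "stimuli.csv", "simulate"))
    return datasets, table


def _load_fitted_params(path: Path) -> dict[str, ParamSet]:
    df = pd.read_csv(_require(path, "fit"))
    eta_cols = [c for c in df.columns if c.startswith("eta")]
    return {
        row.participant_id: ParamSet(
            alpha=row.alpha, beta=row.beta,
            etas=tuple(getattr(row, c) for c in eta_cols),
        )
        for row in df.itertuples(index=False)
    }


def run_pipeline(config: RunConfig, stages: list[str] | tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in canonical order; returns the manifest dict."""
    bad = set(stages) - set(STAGES)
    if bad:
        raise PipelineError(f"unknown stages: {sorted(bad)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = out_dir / "data"
    manifest = Manifest(out_dir, config)

    for stage in [s for s in STAGES if s in stages]:
        logger.info("stage %s", stage)
        rng = _stage_rng(config, stage)

        if stage == "simulate":
            study = generate_study(config.n_participants, config.generating_model,
                                   config.param_sampler, rng, config.study_config)
            write_synthetic_study(data_dir, study)
            outputs = sorted(data_dir.glob("*.csv")) + [data_dir / "truth.json"]
            manifest.record(stage, outputs,
                            {"n_participants": config.n_participants,
                             "generating_model": config.generating_model})

        elif stage == "fit":
            datasets, table = _load_data_and_stimuli(data_dir)
            model = get_model(config.fit_model)
            prior = PriorSpec.default(model, beta_max=config.beta_max)
            participants = [prepare_participant(model, datasets[pid], table[pid])
                            for pid in sorted(datasets)]
            fits = fit_point_estimates(model, participants, prior,
                                       config.sampler, rng)
            rows = [{"participant_id": pid, "alpha": p.alpha, "beta": p.beta,
                     **{name: e for name, e in
                        zip(model.param_names[2:], p.etas)}}
                    for pid, p in sorted(fits.items())]
            fit_path = out_dir / "fitted_params.csv"
            pd.DataFrame(rows).to_csv(fit_path, index=False, lineterminator="\n")
            traj_frames = []
            for pid in sorted(datasets):
                for task in TaskType:
                    trials = datasets[pid].gamble_trials_for(task)
                    if not trials:
                        continue
                    traj = q_trajectory(model, fits[pid], trials, table[pid][task])
                    traj_frames.append(trajectory_frame(pid, task, traj,
                                                        table[pid][task]))
            traj_path = out_dir / "trajectories.csv"
            pd.concat(traj_frames, ignore_index=True).to_csv(
                traj_path, index=False, lineterminator="\n")
            manifest.record(stage, [fit_path, traj_path],
                            {"fit_model": config.fit_model})

        elif stage == "compare":
            datasets, table = _load_data_and_stimuli(data_dir)
            by_model = {}
            for name in config.models:
                model = get_model(name)
                by_model[name] = [prepare_participant(model, datasets[pid],
                                                      table[pid])
                                  for pid in sorted(datasets)]
            result = compare_models(by_model, list(config.models),
                                    config=config.sampler, rng=rng,
                                    beta_max=config.beta_max)
            cmp_path = out_dir / "comparison.csv"
            result.table.to_csv(cmp_path, index=False, lineterminator="\n")
            manifest.record(stage, [cmp_path],
                            {"models": list(config.models), "best": result.best})

        elif stage == "analyze":
            datasets, table = _load_data_and_stimuli(data_dir)
            results = [pref_frequency_contrast(datasets)]
            rates = correct_rate_table(datasets, table)
            results.extend(rm_anova_2x2(rates))
            results.extend(above_chance_tests(rates))
            results.extend(rating_comparisons(datasets, table))
            fitted = _load_fitted_params(out_dir / "fitted_params.csv")
            model = get_model(config.fit_model)
            trajectories = {
                pid: {task: q_trajectory(model, fitted[pid],
                                         datasets[pid].gamble_trials_for(task),
                                         table[pid][task])
                      for task in TaskType
                      if datasets[pid].gamble_trials_for(task)}
                for pid in sorted(datasets)
            }
            values = value_stage_table(trajectories, table, datasets)
            for task in TaskType:
                for r in value_stage_anova(values, task):
                    results.append(dataclasses.replace(
                        r, effect=f"{task.value}:{r.effect}"))
            res_path = out_dir / "behavioral_results.csv"
            results_frame(results).to_csv(res_path, index=False,
                                          lineterminator="\n")
            ft_path = out_dir / "first_trial.csv"
            first_trial_choice(datasets, table).to_csv(ft_path, index=False,
                                                       lineterminator="\n")
            rates_path = out_dir / "correct_rates.csv"
            rates.to_csv(rates_path, index=False, lineterminator="\n")
            manifest.record(stage, [res_path, ft_path, rates_path], {})

        elif stage == "recover":
            model = get_model(config.fit_model)
            sampler = config.param_sampler
            outputs = []
            if config.recover_n_datasets > 0:
                truths = [sampler.draw(model, rng)
                          for _ in range(config.recover_n_datasets)]
                # spread eta slots too so their recovery is measurable
                truths = [
                    ParamSet(p.alpha, p.beta,
                             tuple(float(np.clip(e + rng.uniform(-0.2, 0.2), 0, 1))
                                   for e in p.etas))
                    for p in truths
                ]
                prep = parameter_recovery(model, truths, config.sampler, rng,
                                          beta_max=config.beta_max)
                pr_path = out_dir / "parameter_recovery.csv"
                prep.summary.to_csv(pr_path, index=False, lineterminator="\n")
                outputs.append(pr_path)
            if config.recover_n_per_model > 0:
                gen_params = {name: sampler.draw(get_model(name), rng)
                              for name in config.models}
                mrep = model_recovery(list(config.models), gen_params,
                                      config.recover_n_per_model, config.sampler,
                                      rng, beta_max=config.beta_max)
                mr_path = out_dir / "model_recovery.csv"
                mrep.confusion.to_csv(mr_path, lineterminator="\n")
                outputs.append(mr_path)
            manifest.record(stage, outputs,
                            {"n_datasets": config.recover_n_datasets,
                             "n_per_model": config.recover_n_per_model})

    return manifest.data
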