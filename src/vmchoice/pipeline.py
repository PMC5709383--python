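"""End-to-end reproducible runs: configuration, seeding, and stage commands.

A :class:`RunConfig` describes one experiment (task, agents, sizes,
output directory) and round-trips through YAML.  A single top-level
seed is expanded into per-stage seeds with ``numpy``'s SeedSequence
spawn mechanism, keyed by stage name in a fixed order, so every
stochastic stage is independently reproducible.  Stage commands write a
deterministic artifact tree (event TSVs, value CSVs, fit CSVs, JSON
reports) plus a manifest recording the package version and all seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agents_rl, bold_sim, glm_engine, tasks_agents, timecourse, valuation

_pkg_version = "0.1.0"

STAGES = ("simulate", "fit_rl", "bold", "glm", "timecourse", "report")


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    experiment: str = "lessismore"  # or "reversal"
    n_subjects: int = 4
    n_sessions: int = 4
    seed: int = 0
    out_dir: str = "runs/demo"
    agent: dict = field(default_factory=dict)  # SubjectiveAgent or RLParams kwargs
    task: dict = field(default_factory=dict)  # LessIsMoreConfig / ReversalConfig kwargs
    rt_model: dict = field(default_factory=dict)
    betas: dict = field(default_factory=dict)  # LinearBetas kwargs for BOLD generation
    noise: dict = field(default_factory=dict)  # NoiseModel kwargs
    tr: float = 2.28

    def __post_init__(self) -> None:
        if self.experiment not in ("lessismore", "reversal"):
            raise ValueError(f"unknown experiment {self.experiment!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds: SeedSequence(seed).spawn in STAGES order."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2 ** 31))
            for stage, child in zip(STAGES, children)}


def _session_rngs(stage_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(stage_seed).spawn(n)]


def _manifest(config: RunConfig, extra: dict | None = None) -> dict:
    man = {"version": _pkg_version, "seed": config.seed,
           "stage_seeds": stage_seeds(config.seed),
           "config": dataclasses.asdict(config)}
    if extra:
        man.update(extra)
    return man


def run_simulate(config: RunConfig) -> dict:
    """Generate and write all sessions; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    rngs = _session_rngs(seeds["simulate"], config.n_subjects * config.n_sessions)
    rt_model = tasks_agents.RTModel(**config.rt_model)

    k = 0
    paths = []
    for subj in range(config.n_subjects):
        for sess in range(config.n_sessions):
            if config.experiment == "lessismore":
                cfg = tasks_agents.LessIsMoreConfig(**config.task)
                agent = tasks_agents.SubjectiveAgent(**config.agent)
                trials = tasks_agents.generate_lessismore_session(
                    cfg, agent, rt_model, rng=rngs[k])
            else:
                cfg = tasks_agents.ReversalConfig(**config.task)
                params = agents_rl.RLParams(**(config.agent or
                                               {"alpha": 0.3, "temp": 0.2}))
                agent = agents_rl.RWAgent(params, n_stimuli=cfg.n_stimuli)
                trials = tasks_agents.generate_reversal_session(
                    cfg, agent, rng=rngs[k], rt_model=rt_model)
            path = out / f"sub-{subj:02d}_ses-{sess:02d}"
            tasks_agents.write_session(trials, path, config=cfg, seed=config.seed)
            paths.append(str(path))
            k += 1
    manifest = _manifest(config, {"sessions": paths})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _load_sessions(config: RunConfig) -> dict[tuple[int, int], list]:
    out = Path(config.out_dir)
    sessions = {}
    for subj in range(config.n_subjects):
        for sess in range(config.n_sessions):
            path = out / f"sub-{subj:02d}_ses-{sess:02d}"
            if not path.with_suffix(".tsv").exists():
                raise FileNotFoundError(
                    f"missing session artifact {path}.tsv: run the simulate stage first")
            sessions[(subj, sess)] = tasks_agents.read_session(path)
    return sessions


def run_fit_rl(config: RunConfig) -> pd.DataFrame:
    """Fit the learning model to every reversal session; write fits.csv."""
    if config.experiment != "reversal":
        raise ValueError("RL fitting applies to the reversal experiment")
    sessions = _load_sessions(config)
    seeds = stage_seeds(config.seed)
    rows = []
    for (subj, sess), trials in sessions.items():
        seq = agents_rl.ChoiceSequence.from_trials(trials)
        fit = agents_rl.fit_session(seq, seed=seeds["fit_rl"] + subj * 100 + sess)
        rows.append(dict(subject=subj, session=sess, alpha_hat=fit.alpha_hat,
                         temp_hat=fit.temp_hat, nll=fit.nll,
                         n_trials=len(seq), seed=config.seed))
    fits = pd.DataFrame(rows)
    fits.to_csv(Path(config.out_dir) / "fits.csv", index=False)
    return fits


def _session_bold_and_regressors(trials, config: RunConfig, rng):
    """Shared forward model: empirical values -> regressors -> linear BOLD."""
    if config.experiment == "lessismore":
        table = valuation.value_table(trials)
    else:
        # reversal: learned values are not observable; refit and replay
        seq = agents_rl.ChoiceSequence.from_trials(trials)
        fit = agents_rl.fit_session(seq, seed=int(rng.integers(2 ** 31)))
        table = None
        vals = _replay_values(seq, fit.alpha_hat)
        regs = valuation.normalize(vals[:, 0], vals[:, 1])
        values = pd.DataFrame(vals, columns=["chosen", "unchosen"])
        values.index.name = "trial"
    if table is not None:
        values, regs = valuation.regressors_from_trials(trials, table)
    betas = bold_sim.LinearBetas(**config.betas)
    noise = bold_sim.NoiseModel(**config.noise) if config.noise else bold_sim.NoiseModel()
    cues = np.array([t.t_cue for t in trials])
    outs = np.array([t.t_outcome for t in trials])
    n_vol = glm_engine.n_volumes_for(trials, config.tr)
    bold = bold_sim.generate_linear_roi(
        cues, regs.diff_z, regs.sum_z, betas=betas, tr=config.tr, n_volumes=n_vol,
        noise_model=noise, rng=rng, outcome_onsets=outs, chosen_z=regs.chosen_z)
    return values, regs, bold


def _replay_values(seq: agents_rl.ChoiceSequence, alpha: float) -> np.ndarray:
    """Per-trial (chosen, unchosen) learned values from a forward RW pass."""
    v = np.full(seq.n_stimuli, 0.5)
    out = np.empty((len(seq), 2))
    for t in range(len(seq)):
        c = seq.choices[t]
        others = [s for s in seq.offered[t] if s != c]
        out[t] = (v[c], v[others[0]] if others else v[c])
        v = agents_rl.rw_update(v, c, seq.outcomes[t], alpha)
    return out


def run_glm(config: RunConfig) -> dict:
    """Per-session GLM-2, fixed effects per subject, group test on the value-difference beta."""
    sessions = _load_sessions(config)
    seeds = stage_seeds(config.seed)
    rngs = _session_rngs(seeds["bold"], len(sessions))
    subj_effects = []
    session_rows = []
    value_rows = []
    for k, ((subj, sess), trials) in enumerate(sessions.items()):
        values, regs, bold = _session_bold_and_regressors(trials, config, rngs[k])
        v = values.reset_index()
        v.insert(0, "session", sess)
        v.insert(0, "subject", subj)
        value_rows.append(v)
        if config.experiment == "lessismore":
            design = glm_engine.build_glm2(trials, regs, tr=config.tr,
                                           n_volumes=bold.n_volumes)
            col = "cs_cue_x_diff"
        else:
            cues = np.array([t.t_cue for t in trials])
            design = glm_engine.DesignMatrix(
                names=["decision", "diff"],
                X=np.column_stack([
                    bold_sim.convolve_events(cues, 1.0, tr=config.tr,
                                             n_volumes=bold.n_volumes).values,
                    bold_sim.convolve_events(cues, regs.diff_z, tr=config.tr,
                                             n_volumes=bold.n_volumes).values]),
                tr=config.tr, convolved=[True, True])
            col = "diff"
        fit = glm_engine.fit_session(bold, design)
        res = glm_engine.contrast_for(fit, col)
        session_rows.append(dict(subject=subj, session=sess, effect=res.effect,
                                 var=res.se ** 2, t=res.t))
    df = pd.DataFrame(session_rows)
    df.to_csv(Path(config.out_dir) / "glm_sessions.csv", index=False)
    pd.concat(value_rows, ignore_index=True).to_csv(
        Path(config.out_dir) / "trial_values.csv", index=False)
    for subj, grp in df.groupby("subject"):
        eff, _ = glm_engine.fixed_effects(grp["effect"].to_numpy(), grp["var"].to_numpy())
        subj_effects.append(eff)
    t, p = glm_engine.group_test(np.array(subj_effects))
    report = {"subject_effects": subj_effects, "group_t": t, "group_p": p,
              "contrast": "chosen-unchosen value difference at decision"}
    (Path(config.out_dir) / "glm_group.json").write_text(json.dumps(report, indent=2))
    return report


def run_timecourse(config: RunConfig) -> dict:
    """Decision-locked epochs, per-timepoint value regression, LOO peak test."""
    sessions = _load_sessions(config)
    seeds = stage_seeds(config.seed)
    rngs = _session_rngs(seeds["timecourse"], len(sessions))
    courses = []
    for k, ((subj, sess), trials) in enumerate(sessions.items()):
        values, regs, bold = _session_bold_and_regressors(trials, config, rngs[k])
        epochs = timecourse.epoch_upsample(
            bold, np.array([t.t_cue for t in trials]))
        kept = epochs.trial_index
        X = pd.DataFrame({"diff_z": regs.diff_z[kept], "sum_z": regs.sum_z[kept]})
        tb = timecourse.timepoint_regression(epochs, X)
        courses.append(tb.series("diff_z"))
        epochs.to_frame().to_csv(
            Path(config.out_dir) / f"epochs_sub-{subj:02d}_ses-{sess:02d}.csv",
            index=False)
    loo = timecourse.loo_peak_stat(np.array(courses), mode="abs")
    report = {"loo": loo.to_json_dict(),
              "regressor": "chosen-unchosen value difference"}
    (Path(config.out_dir) / "timecourse_loo.json").write_text(
        json.dumps(report, indent=2))
    return report


def run_report(config: RunConfig) -> dict:
    """Summary across stages; includes the re-offer-rate check for reversal runs."""
    sessions = _load_sessions(config)
    report: dict = {"experiment": config.experiment,
                    "n_sessions": len(sessions), "seed": config.seed}
    if config.experiment == "reversal":
        all_trials = [tr for trials in sessions.values() for tr in trials]
        rates = [tasks_agents.reoffer_rate(trials) for trials in sessions.values()]
        report["reoffer_rate_pct"] = 100.0 * float(np.mean(rates))
        fits_path = Path(config.out_dir) / "fits.csv"
        if fits_path.exists():
            fits = pd.read_csv(fits_path)
            report["median_alpha_hat"] = float(fits["alpha_hat"].median())
            report["median_temp_hat"] = float(fits["temp_hat"].median())
        report["n_trials_total"] = len(all_trials)
    else:
        tables = [valuation.value_table(trials) for trials in sessions.values()]
        mean_vals = {stim: float(np.mean([t[stim] for t in tables if stim in t]))
                     for stim in ("HV", "CV", "LV")}
        report["mean_empirical_values"] = mean_vals
        report["less_is_more_ordering"] = bool(
            mean_vals["HV"] > mean_vals["CV"] > mean_vals["LV"])
    glm_path = Path(config.out_dir) / "glm_group.json"
    if glm_path.exists():
        report["glm_group"] = json.loads(glm_path.read_text())
    (Path(config.out_dir) / "report.json").write_text(json.dumps(report, indent=2))
    return report


def sign_flip_betas(
    n_trials: int = 500,
    seed: int = 0,
    decay: bold_sim.NetworkParams | None = None,
    sustain: bold_sim.NetworkParams | None = None,
    tr: float = 2.28,
    iti: float = 6.0,
) -> dict:
    """Fitted value-difference betas under matched decay vs sustain networks.

    Per-trial option values are drawn uniformly, the same value stream
    drives both regimes, each trial's aggregate network activity is
    integrated into an event amplitude, convolved with the macaque HRF,
    and regressed on the z-scored chosen-minus-unchosen value at the
    decision events.  The decay regime yields a negative (difficulty-
    positive) beta; sustaining the winner's attractor raises it.
    """
    if decay is None:
        decay = bold_sim.NetworkParams(regime="decay")
    if sustain is None:
        sustain = dataclasses.replace(decay, regime="sustain")
    root = np.random.SeedSequence(seed)
    value_rng, *regime_rngs = [np.random.default_rng(s) for s in root.spawn(3)]
    v_a = value_rng.uniform(0.1, 0.9, n_trials)
    v_b = value_rng.uniform(0.1, 0.9, n_trials)

    out: dict = {}
    for params, rng in zip((decay, sustain), regime_rngs):
        res = bold_sim.simulate_attractor_trials(params, v_a, v_b, rng)
        ok = ~res.undecided
        amps = bold_sim.attractor_trial_amplitudes(res)[ok]
        v_chosen = np.where(res.choices == 0, v_a, v_b)[ok]
        v_unchosen = np.where(res.choices == 0, v_b, v_a)[ok]
        diff = v_chosen - v_unchosen
        diff_z = (diff - diff.mean()) / diff.std()
        onsets = np.arange(ok.sum()) * (params.trial_duration + iti)
        n_vol = int(np.ceil((onsets[-1] + 30.0) / tr))
        bold = bold_sim.convolve_events(onsets, amps, tr=tr, n_volumes=n_vol)
        design = glm_engine.DesignMatrix(
            names=["decision", "diff"],
            X=np.column_stack([
                bold_sim.convolve_events(onsets, 1.0, tr=tr, n_volumes=n_vol).values,
                bold_sim.convolve_events(onsets, diff_z, tr=tr, n_volumes=n_vol).values,
            ]),
            tr=tr, convolved=[True, True])
        fit = glm_engine.fit_session(bold, design)
        out[params.regime] = {
            "beta_diff": fit.beta("diff"),
            "n_decided": int(ok.sum()),
            "mean_decision_time": float(np.nanmean(res.decision_times)),
        }
    return out
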