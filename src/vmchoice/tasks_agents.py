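"""Synthetic session generators for the two decision tasks.

Two tasks are simulated:

* a cued-choice task in which three rewarded stimuli (HV = high value,
  LV = low value, CV = a compound of both) and unrewarded stimuli are
  offered either alone (one-option trials, skippable) or in pairs
  (two-option trials).  A ``SubjectiveAgent`` chooses by softmax over its
  subjective values; its valuation of the compound can be biased towards
  the mean of the component values, producing the "less-is-more"
  preference HV > CV > LV.
* a three-option probabilistic reversal task in which two of three
  stimuli are drawn uniformly at random each trial and each stimulus
  pays reward with a slowly drifting probability.  Choices come from a
  Rescorla-Wagner learner (:mod:`vmchoice.agents_rl`).

Sessions are lists of :class:`TrialRecord` and can be serialized as
tab-separated event tables (one row per cue / response / outcome event)
with a JSON sidecar recording the generating configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents_rl import RWAgent, softmax_probs

HV = "HV"
LV = "LV"
CV = "CV"
CSM = "CSM"  # unrewarded CS- stimulus
SKIP = "skip"  # touching the blank side of the screen

#: two-option pairings among the rewarded stimuli
CS_PLUS_PAIRS = ((HV, LV), (HV, CV), (CV, LV))


class ConfigError(ValueError):
    """Raised when a task configuration violates its invariants."""


@dataclass(frozen=True)
class LessIsMoreConfig:
    """Schedule parameters for the cued one-/two-option task.

    A 120-trial session contains 75% one-option trials (a single CS+
    that can be taken or skipped) and 25% two-option trials.  Two-option
    trials are split between CS+ vs CS- pairs and CS+ vs CS+ pairs;
    ``p_choice_csminus`` is the fraction of two-option trials that pair
    a CS+ with a CS- (the published schedule is ambiguous between a
    split of all trials and of choice trials, so the split is a knob).
    The inter-trial interval is uniform on ``iti_range`` and the
    response-to-outcome delay is jittered around ``outcome_delay_mean``.
    """

    n_trials: int = 120
    p_single: float = 0.75
    iti_range: tuple[float, float] = (5.0, 7.0)
    outcome_delay_mean: float = 4.0
    outcome_delay_jitter: float = 1.0
    outcome_duration: float = 3.0
    p_choice_csminus: float = 0.5
    option_set: tuple[str, ...] = (HV, LV, CV, CSM)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError(f"n_trials must be positive, got {self.n_trials}")
        if not 0.0 <= self.p_single <= 1.0:
            raise ConfigError(f"p_single must lie in [0, 1], got {self.p_single}")
        if not 0.0 <= self.p_choice_csminus <= 1.0:
            raise ConfigError("p_choice_csminus must lie in [0, 1]")
        if self.iti_range[0] > self.iti_range[1] or self.iti_range[0] < 0:
            raise ConfigError(f"invalid iti_range {self.iti_range}")
        if not self.option_set:
            raise ConfigError("option_set must not be empty")


@dataclass(frozen=True)
class ReversalConfig:
    """Schedule parameters for the three-option probabilistic task.

    Reward probabilities follow independent reflected Gaussian random
    walks: start uniform on ``walk_start_range``, per-trial step s.d.
    ``walk_step_sd``, reflected into ``walk_bounds``.
    """

    n_trials: int = 200
    n_stimuli: int = 3
    n_offered: int = 2
    walk_start_range: tuple[float, float] = (0.2, 0.8)
    walk_step_sd: float = 0.03
    walk_bounds: tuple[float, float] = (0.1, 0.9)
    iti_range: tuple[float, float] = (5.0, 7.0)
    outcome_duration: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if not 0 < self.n_offered <= self.n_stimuli:
            raise ConfigError("need 0 < n_offered <= n_stimuli")
        lo, hi = self.walk_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigError(f"walk_bounds must be within [0, 1], got {self.walk_bounds}")
        if not lo <= self.walk_start_range[0] <= self.walk_start_range[1] <= hi:
            raise ConfigError("walk_start_range must lie within walk_bounds")


@dataclass(frozen=True)
class SubjectiveAgent:
    """Softmax chooser with a biased valuation of the compound option.

    The compound value interpolates between the sum (``cv_bias = 0``)
    and the mean (``cv_bias = 1``) of the HV and LV values:
    ``v_CV = cv_bias * mean(v_HV, v_LV) + (1 - cv_bias) * (v_HV + v_LV)``.
    With the default full bias towards the mean the agent shows the
    control animals' ordering v_HV > v_CV > v_LV.  One-option trials are
    a softmax choice between the offered value and ``v_skip``.
    """

    v_hv: float = 0.95
    v_lv: float = 0.6
    v_unrew: float = 0.1
    cv_bias: float = 1.0
    temperature: float = 0.25
    v_skip: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_bias <= 1.0:
            raise ConfigError("cv_bias must lie in [0, 1]")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        for v in (self.v_hv, self.v_lv, self.v_unrew):
            if not np.isfinite(v):
                raise ConfigError("agent values must be finite")

    @property
    def v_cv(self) -> float:
        mean = 0.5 * (self.v_hv + self.v_lv)
        total = self.v_hv + self.v_lv
        return self.cv_bias * mean + (1.0 - self.cv_bias) * total

    def value(self, option: str) -> float:
        table = {HV: self.v_hv, LV: self.v_lv, CV: self.v_cv,
                 CSM: self.v_unrew, SKIP: self.v_skip}
        try:
            return table[option]
        except KeyError:
            raise KeyError(f"unknown option label {option!r}") from None


@dataclass(frozen=True)
class RTModel:
    """Linear reaction-time model.

    RT = intercept + b_sum * (v_chosen + v_unchosen)
       + b_diff * (v_chosen - v_unchosen) + Gaussian noise, truncated at
    ``floor_ms``.  Negative slopes reproduce faster responses when the
    available options are valuable and when they are easy to tell apart.
    """

    intercept_ms: float = 1000.0
    b_sum: float = -100.0
    b_diff: float = -50.0
    noise_sd: float = 100.0
    floor_ms: float = 250.0


@dataclass
class TrialRecord:
    """One trial: offers, choice, timing and outcome."""

    index: int
    trial_type: str  # "single" or "choice"
    offered: tuple[str, ...]
    sides: tuple[str, ...]
    choice: str
    rt_ms: float
    outcome: float
    t_cue: float
    t_response: float
    t_outcome: float

    def __post_init__(self) -> None:
        if not self.t_cue < self.t_response < self.t_outcome:
            raise ValueError(
                f"trial {self.index}: event times must increase "
                f"(cue {self.t_cue}, response {self.t_response}, outcome {self.t_outcome})"
            )
        allowed = set(self.offered) | ({SKIP} if len(self.offered) == 1 else set())
        if self.choice not in allowed:
            raise ValueError(f"trial {self.index}: choice {self.choice!r} not in {allowed}")


def simulate_rt(rt_model: RTModel, v_chosen: float, v_unchosen: float,
                rng: np.random.Generator | None = None) -> float:
    """Draw one reaction time (ms) from the linear RT model."""
    rt = (rt_model.intercept_ms
          + rt_model.b_sum * (v_chosen + v_unchosen)
          + rt_model.b_diff * (v_chosen - v_unchosen))
    if rt_model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        rt += rng.normal(0.0, rt_model.noise_sd)
    return max(rt, rt_model.floor_ms)


def allocate_trial_types(config: LessIsMoreConfig) -> tuple[int, int]:
    """Exact deterministic split into (n_single, n_choice).

    The single-option count is rounded to the nearest integer when
    ``n_trials * p_single`` is not integral; the remainder goes to
    choice trials.
    """
    n_single = int(round(config.n_trials * config.p_single))
    return n_single, config.n_trials - n_single


def _softmax_choice(options: tuple[str, ...], values: np.ndarray, temperature: float,
                    rng: np.random.Generator) -> int:
    probs = softmax_probs(values, temperature)
    return int(rng.choice(len(options), p=probs))


def generate_lessismore_session(
    config: LessIsMoreConfig,
    agent: SubjectiveAgent,
    rt_model: RTModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate one session of the cued one-/two-option task.

    Trial-type counts are allocated deterministically and then the
    trial order is shuffled; choices are drawn by softmax over the
    offered subjective values (one-option trials include the skip
    option).  Event times accumulate ITIs, reaction times and jittered
    response-to-outcome delays, so they strictly increase.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if rt_model is None:
        rt_model = RTModel()

    n_single, n_choice = allocate_trial_types(config)
    cs_plus = [o for o in config.option_set if o in (HV, LV, CV)]
    if not cs_plus:
        raise ConfigError("option_set contains no rewarded stimulus")

    offers: list[tuple[str, ...]] = []
    for i in range(n_single):
        offers.append((cs_plus[i % len(cs_plus)],))
    n_csm = int(round(n_choice * config.p_choice_csminus))
    for i in range(n_csm):
        offers.append((cs_plus[i % len(cs_plus)], CSM))
    pairs = [p for p in CS_PLUS_PAIRS if p[0] in cs_plus and p[1] in cs_plus]
    if not pairs:
        pairs = [(cs_plus[0], cs_plus[0])]
    for i in range(n_choice - n_csm):
        offers.append(pairs[i % len(pairs)])
    rng.shuffle(offers)

    trials: list[TrialRecord] = []
    t = 0.0
    for index, offered in enumerate(offers):
        t += rng.uniform(*config.iti_range)
        t_cue = t
        if len(offered) == 1:
            options = (offered[0], SKIP)
            sides = (rng.choice(["left", "right"]), "blank")
        else:
            options = tuple(offered)
            sides = ("left", "right") if rng.random() < 0.5 else ("right", "left")
        values = np.array([agent.value(o) for o in options])
        k = _softmax_choice(options, values, agent.temperature, rng)
        choice = options[k]
        v_chosen = values[k]
        v_unchosen = values[1 - k]
        rt = simulate_rt(rt_model, v_chosen, v_unchosen, rng)
        t_response = t_cue + rt / 1000.0
        delay = max(0.25, rng.uniform(config.outcome_delay_mean - config.outcome_delay_jitter,
                                      config.outcome_delay_mean + config.outcome_delay_jitter))
        t_outcome = t_response + delay
        outcome = agent.value(choice) if choice in (HV, LV, CV) else 0.0
        trials.append(TrialRecord(
            index=index,
            trial_type="single" if len(offered) == 1 else "choice",
            offered=tuple(offered),
            sides=sides,
            choice=choice,
            rt_ms=rt,
            outcome=outcome,
            t_cue=t_cue,
            t_response=t_response,
            t_outcome=t_outcome,
        ))
        t = t_outcome + config.outcome_duration
    return trials


def probability_walks(config: ReversalConfig, rng: np.random.Generator) -> np.ndarray:
    """Reflected Gaussian random walks, one column per stimulus.

    Returns an ``(n_trials, n_stimuli)`` array of reward probabilities,
    every entry inside ``walk_bounds``.
    """
    lo, hi = config.walk_bounds
    p = rng.uniform(*config.walk_start_range, size=config.n_stimuli)
    out = np.empty((config.n_trials, config.n_stimuli))
    for t in range(config.n_trials):
        out[t] = p
        p = p + rng.normal(0.0, config.walk_step_sd, size=config.n_stimuli)
        # reflect into [lo, hi]
        p = np.where(p > hi, 2 * hi - p, p)
        p = np.where(p < lo, 2 * lo - p, p)
        p = np.clip(p, lo, hi)  # guard pathological step sizes
    if np.any(out < 0) or np.any(out > 1):
        raise RuntimeError("reflection failed to keep probabilities in [0, 1]")
    return out


def generate_reversal_session(
    config: ReversalConfig,
    rl_agent: RWAgent,
    rng: np.random.Generator | None = None,
    rt_model: RTModel | None = None,
) -> list[TrialRecord]:
    """Simulate one session of the three-option probabilistic task.

    Per trial, ``n_offered`` of the ``n_stimuli`` stimuli are drawn
    uniformly without replacement, the agent chooses by softmax over its
    current learned values, reward is Bernoulli in the stimulus's
    current walk probability, and the agent's values are updated by the
    Rescorla-Wagner rule.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if rt_model is None:
        rt_model = RTModel(noise_sd=0.0)
    labels = [chr(ord("A") + i) for i in range(config.n_stimuli)]
    probs = probability_walks(config, rng)

    trials: list[TrialRecord] = []
    t = 0.0
    for index in range(config.n_trials):
        offered_idx = rng.choice(config.n_stimuli, size=config.n_offered, replace=False)
        k = rl_agent.choose(offered_idx, rng)
        reward = float(rng.random() < probs[index, k])
        v_chosen = rl_agent.values[k]
        v_unchosen = float(np.mean([rl_agent.values[j] for j in offered_idx if j != k])) \
            if config.n_offered > 1 else rl_agent.values[k]
        rl_agent.update(k, reward)

        t += rng.uniform(*config.iti_range)
        t_cue = t
        rt = simulate_rt(rt_model, v_chosen, v_unchosen, rng)
        t_response = t_cue + rt / 1000.0
        t_outcome = t_response + 1e-3  # outcome follows the response immediately
        trials.append(TrialRecord(
            index=index,
            trial_type="choice",
            offered=tuple(labels[j] for j in offered_idx),
            sides=("left", "right"),
            choice=labels[k],
            rt_ms=rt,
            outcome=reward,
            t_cue=t_cue,
            t_response=t_response,
            t_outcome=t_outcome,
        ))
        t = t_outcome + config.outcome_duration
    return trials


def reoffer_rate(trials: list[TrialRecord]) -> float:
    """Fraction of trials whose chosen stimulus is offered again next trial."""
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    hits = sum(trials[t].choice in trials[t + 1].offered for t in range(len(trials) - 1))
    return hits / (len(trials) - 1)


# ---------------------------------------------------------------------------
# serialization: event tables + JSON sidecar


def session_to_events(trials: list[TrialRecord]) -> pd.DataFrame:
    """Long event table: one row per cue, response and outcome event."""
    rows = []
    for tr in trials:
        common = dict(trial=tr.index, trial_type=tr.trial_type,
                      offered="+".join(tr.offered), choice=tr.choice,
                      rt_ms=round(tr.rt_ms, 3), outcome=tr.outcome)
        rows.append(dict(onset=round(tr.t_cue, 4), duration=0.0, event="cue", **common))
        rows.append(dict(onset=round(tr.t_response, 4), duration=0.0, event="response", **common))
        rows.append(dict(onset=round(tr.t_outcome, 4), duration=0.0, event="outcome", **common))
    return pd.DataFrame(rows)


def write_session(trials: list[TrialRecord], path: str | Path,
                  config=None, seed: int | None = None) -> None:
    """Write ``<path>.tsv`` (events) and ``<path>.json`` (config sidecar)."""
    path = Path(path)
    session_to_events(trials).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    sidecar: dict = {"n_trials": len(trials), "seed": seed}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_session(path: str | Path) -> list[TrialRecord]:
    """Rebuild TrialRecords from an event table written by :func:`write_session`."""
    df = pd.read_csv(Path(path).with_suffix(".tsv"), sep="\t")
    trials = []
    for trial, grp in df.groupby("trial", sort=True):
        by_event = grp.set_index("event")
        first = grp.iloc[0]
        offered = tuple(str(first["offered"]).split("+"))
        trials.append(TrialRecord(
            index=int(trial),
            trial_type=str(first["trial_type"]),
            offered=offered,
            sides=("left", "right") if len(offered) > 1 else ("left", "blank"),
            choice=str(first["choice"]),
            rt_ms=float(first["rt_ms"]),
            outcome=float(first["outcome"]),
            t_cue=float(by_event.loc["cue", "onset"]),
            t_response=float(by_event.loc["response", "onset"]),
            t_outcome=float(by_event.loc["outcome", "onset"]),
        ))
    return trials
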