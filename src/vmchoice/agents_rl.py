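"""Rescorla-Wagner learning, softmax choice, and session likelihood fitting.

Value learning follows the delta rule

    V[t+1, s] = V[t, s] + alpha * (r_t - V[t, s])   if s was chosen,
    V[t+1, s] = V[t, s]                             otherwise,

and choices are modelled by a softmax over values with stochasticity
(temperature) T, P(s) proportional to exp(V_s / T).  The per-session
negative log-likelihood L = -sum_t log P(t, c_t) is minimized over
(alpha, T) with a bounded quasi-Newton optimizer and Latin-hypercube
multi-start.

By default the softmax normalizes over the two options offered on each
trial, since only those are available; normalization over all stimuli is
available via ``denominator="all"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import qmc

ALPHA_BOUNDS = (0.01, 0.99)
TEMP_BOUNDS = (0.01, 10.0)


class ParameterError(ValueError):
    """Raised for out-of-range learning parameters."""


class FitError(RuntimeError):
    """Raised when no optimizer start converges."""


@dataclass(frozen=True)
class RLParams:
    """Learning rate alpha in [0, 1] and softmax stochasticity T > 0."""

    alpha: float
    temp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.temp <= 0.0:
            raise ParameterError(f"temp must be positive, got {self.temp}")


@dataclass
class ChoiceSequence:
    """Offered pairs, choices and outcomes for one session (integer stimulus ids)."""

    offered: np.ndarray  # (N, n_offered) int
    choices: np.ndarray  # (N,) int
    outcomes: np.ndarray  # (N,) float
    n_stimuli: int = 3

    def __post_init__(self) -> None:
        self.offered = np.asarray(self.offered, dtype=int)
        self.choices = np.asarray(self.choices, dtype=int)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if not all((self.choices[t] == self.offered[t]).any() for t in range(len(self.choices))):
            raise ValueError("every choice must be among the offered options")

    def __len__(self) -> int:
        return len(self.choices)

    @classmethod
    def from_trials(cls, trials) -> "ChoiceSequence":
        """Build from reversal-task TrialRecords (labels 'A', 'B', ...)."""
        labels = sorted({o for tr in trials for o in tr.offered})
        idx = {lab: i for i, lab in enumerate(labels)}
        offered = np.array([[idx[o] for o in tr.offered] for tr in trials])
        choices = np.array([idx[tr.choice] for tr in trials])
        outcomes = np.array([tr.outcome for tr in trials])
        return cls(offered=offered, choices=choices, outcomes=outcomes, n_stimuli=len(labels))


@dataclass
class RLFit:
    """Fitted parameters with the attained negative log-likelihood."""

    alpha_hat: float
    temp_hat: float
    nll: float
    n_restarts: int
    converged: bool


def rw_update(values: np.ndarray, choice: int, reward: float, alpha: float) -> np.ndarray:
    """One Rescorla-Wagner step; only the chosen entry moves toward the reward."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    out = np.array(values, dtype=float, copy=True)
    out[choice] += alpha * (reward - out[choice])
    return out


def softmax_probs(values: np.ndarray, temp: float,
                  offered: np.ndarray | None = None) -> np.ndarray:
    """Softmax choice probabilities P(s) ~ exp(V_s / T) over the offered set.

    If ``offered`` is given, returns probabilities for those entries in
    order; otherwise over all of ``values``.  Uses a max-shift for
    numerical stability.
    """
    if temp <= 0:
        raise ParameterError(f"temp must be positive, got {temp}")
    v = np.asarray(values, dtype=float)
    if offered is not None:
        offered = np.asarray(offered, dtype=int)
        if offered.size == 0:
            raise ParameterError("offered set must be nonempty")
        v = v[offered]
    z = v / temp
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def session_nll(params: RLParams, sequence: ChoiceSequence, v0: float = 0.5,
                denominator: str = "offered") -> float:
    """Negative log-likelihood of observed choices under RW + softmax.

    Forward pass: on each trial, choice probabilities are computed from
    the current values over the offered pair (or over all stimuli with
    ``denominator="all"``), then the chosen value is updated with the
    observed outcome.
    """
    return _nll(params.alpha, params.temp,
                sequence.offered, sequence.choices, sequence.outcomes,
                sequence.n_stimuli, v0, denominator)


def _nll(alpha: float, temp: float, offered, choices, outcomes,
         n_stimuli: int, v0: float, denominator: str) -> float:
    # plain-float inner loop: called thousands of times by the optimizer
    if denominator not in ("offered", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    over_all = denominator == "all"
    v = [float(v0)] * n_stimuli
    inv_t = 1.0 / temp
    off_list = offered.tolist()
    ch_list = choices.tolist()
    out_list = outcomes.tolist()
    nll = 0.0
    for off, c, r in zip(off_list, ch_list, out_list):
        idx = range(n_stimuli) if over_all else off
        zs = [v[s] * inv_t for s in idx]
        zmax = max(zs)
        denom = sum(math.exp(z - zmax) for z in zs)
        nll -= (v[c] * inv_t - zmax) - math.log(denom)
        v[c] += alpha * (r - v[c])
    return nll


def fit_session(sequence: ChoiceSequence, v0: float = 0.5, n_restarts: int = 10,
                denominator: str = "offered", seed: int | None = None,
                tol: float = 1e-8) -> RLFit:
    """Fit (alpha, T) by bounded L-BFGS-B with Latin-hypercube restarts."""
    n = len(sequence)
    if n < 20:
        warnings.warn(f"fitting only {n} trials; estimates will be unstable", stacklevel=2)

    def objective(x):
        return _nll(x[0], x[1], sequence.offered, sequence.choices,
                    sequence.outcomes, sequence.n_stimuli, v0, denominator)

    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n_restarts)
    starts = qmc.scale(unit, [ALPHA_BOUNDS[0], TEMP_BOUNDS[0]],
                       [ALPHA_BOUNDS[1], 1.0])  # temps above 1 fit noise; start low
    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=[ALPHA_BOUNDS, TEMP_BOUNDS],
                                options={"ftol": tol})
        any_converged = any_converged or bool(res.success)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"no optimizer start converged over {n_restarts} restarts")
    # never report an NLL worse than the best evaluated start
    start_nlls = [objective(x0) for x0 in starts]
    if best.fun > min(start_nlls):
        k = int(np.argmin(start_nlls))
        return RLFit(alpha_hat=float(starts[k][0]), temp_hat=float(starts[k][1]),
                     nll=float(start_nlls[k]), n_restarts=n_restarts, converged=False)
    return RLFit(alpha_hat=float(best.x[0]), temp_hat=float(best.x[1]),
                 nll=float(best.fun), n_restarts=n_restarts, converged=any_converged)


class RWAgent:
    """Stateful Rescorla-Wagner learner used by the reversal-task simulator."""

    def __init__(self, params: RLParams, n_stimuli: int = 3, v0: float = 0.5):
        self.params = params
        self.values = np.full(n_stimuli, float(v0))

    def choose(self, offered: np.ndarray, rng: np.random.Generator) -> int:
        """Softmax choice among the offered stimulus indices."""
        probs = softmax_probs(self.values, self.params.temp, offered)
        return int(offered[rng.choice(len(offered), p=probs)])

    def update(self, choice: int, reward: float) -> None:
        self.values = rw_update(self.values, choice, reward, self.params.alpha)
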