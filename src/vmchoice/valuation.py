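"""Empirical subjective values from choice frequencies, and GLM regressor values.

Each stimulus's subjective value is estimated from how often it was
taken when offered, pooled over the contexts in which it appeared
(against the blank side of the screen, against an unrewarded CS-, and
against each other rewarded stimulus):

    value = sum_contexts p_chosen(context) * n_offered(context)
            / sum_contexts n_offered(context)

which is algebraically the total number of times the stimulus was
chosen divided by the total number of times it was offered.  Values
live on the [0, 1] proportion scale.

Per-trial chosen/unchosen values are then looked up (never re-sorted by
magnitude: the chosen value may be the lower one) and z-scored to build
the parametric fMRI regressors.  The chosen value, unchosen value,
their sum and their difference are each normalized independently — the
difference regressor is z(chosen - unchosen), not z(chosen) -
z(unchosen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tasks_agents import CSM, SKIP, TrialRecord


class UndefinedValueError(ValueError):
    """Raised when a stimulus was never offered."""


class DegenerateRegressorError(ValueError):
    """Raised when a regressor has zero variance and cannot be z-scored."""


@dataclass
class ChoiceCounts:
    """Offer/choice counts per stimulus and context.

    ``counts[stimulus][context] = (n_offered, n_chosen)`` where contexts
    are ``"vs_blank"``, ``"vs_csminus"`` and ``"vs_<other CS+>"``.
    """

    counts: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def add(self, stimulus: str, context: str, offered: int, chosen: int) -> None:
        if not 0 <= chosen <= offered:
            raise ValueError(f"need 0 <= chosen <= offered, got {chosen}/{offered}")
        ctx = self.counts.setdefault(stimulus, {})
        n_off, n_ch = ctx.get(context, (0, 0))
        ctx[context] = (n_off + offered, n_ch + chosen)

    def stimuli(self) -> list[str]:
        return sorted(self.counts)


def counts_from_trials(trials: list[TrialRecord]) -> ChoiceCounts:
    """Tally per-stimulus offer/choice counts over a session's contexts."""
    counts = ChoiceCounts()
    for tr in trials:
        if tr.trial_type == "single":
            stim = tr.offered[0]
            counts.add(stim, "vs_blank", 1, int(tr.choice == stim))
        elif CSM in tr.offered:
            stim = next(o for o in tr.offered if o != CSM)
            counts.add(stim, "vs_csminus", 1, int(tr.choice == stim))
            counts.add(CSM, f"vs_{stim}", 1, int(tr.choice == CSM))
        else:
            a, b = tr.offered
            counts.add(a, f"vs_{b}", 1, int(tr.choice == a))
            counts.add(b, f"vs_{a}", 1, int(tr.choice == b))
    return counts


def empirical_value(counts: ChoiceCounts, stimulus: str) -> float:
    """Offer-weighted mean choice proportion across contexts.

    Equals total-chosen / total-offered; both forms are computed and the
    weighted-proportion form is returned (they agree to rounding).
    """
    ctx = counts.counts.get(stimulus, {})
    total_offered = sum(n_off for n_off, _ in ctx.values())
    if total_offered == 0:
        raise UndefinedValueError(f"stimulus {stimulus!r} was never offered")
    weighted = sum((n_ch / n_off) * n_off for n_off, n_ch in ctx.values() if n_off > 0)
    return weighted / total_offered


def value_table(trials: list[TrialRecord], skip_value: float = 0.0) -> dict[str, float]:
    """Empirical value for every stimulus offered in a session.

    The skip option (blank side) is assigned ``skip_value``; an
    unrewarded CS- that never drew a choice gets its empirical value
    like any other stimulus when it was offered.
    """
    counts = counts_from_trials(trials)
    table = {stim: empirical_value(counts, stim) for stim in counts.stimuli()}
    table[SKIP] = skip_value
    return table


def build_trial_values(
    trials: list[TrialRecord],
    table: dict[str, float],
    include_single: bool = True,
) -> pd.DataFrame:
    """Per-trial chosen/unchosen values from a value table.

    Two-option trials look up both offered stimuli; one-option trials
    (if included) use the skip value as the unchosen value when the
    stimulus was taken, and vice versa.  No reordering by magnitude.
    Returns a DataFrame indexed by trial with columns ``chosen`` and
    ``unchosen``.
    """
    rows = []
    for tr in trials:
        if tr.trial_type == "single" and not include_single:
            continue
        if len(tr.offered) == 1:
            alternatives = [SKIP if tr.choice == tr.offered[0] else tr.offered[0]]
        else:
            alternatives = [o for o in tr.offered if o != tr.choice]
        try:
            chosen = table[tr.choice]
            unchosen = table[alternatives[0]]
        except KeyError as err:
            raise KeyError(f"trial {tr.index}: no value for stimulus {err.args[0]!r}") from None
        rows.append(dict(trial=tr.index, chosen=chosen, unchosen=unchosen))
    return pd.DataFrame(rows).set_index("trial")


@dataclass
class NormalizedRegressors:
    """Independently z-scored parametric regressor values (one entry per trial)."""

    chosen_z: np.ndarray
    unchosen_z: np.ndarray
    diff_z: np.ndarray
    sum_z: np.ndarray


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score with a population (ddof=0) standard deviation."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateRegressorError("need at least 2 values to z-score")
    sd = x.std()
    if sd == 0:
        raise DegenerateRegressorError("zero-variance regressor cannot be z-scored")
    return (x - x.mean()) / sd


def normalize(chosen: np.ndarray, unchosen: np.ndarray) -> NormalizedRegressors:
    """Z-score chosen, unchosen, difference and sum, each independently.

    The difference (chosen - unchosen) and sum are formed on the raw
    values first and then z-scored, so ``diff_z`` is generally not
    ``chosen_z - unchosen_z``.  Because the chosen and unchosen value
    distributions differ, normalized unchosen values can exceed
    normalized chosen values even when every raw chosen value is the
    larger one.
    """
    chosen = np.asarray(chosen, dtype=float)
    unchosen = np.asarray(unchosen, dtype=float)
    if chosen.shape != unchosen.shape:
        raise ValueError("chosen and unchosen must have equal length")
    total = chosen + unchosen
    if total.std() == 0:
        # a constant value sum carries no information; keep a null column
        # rather than failing the three contracted regressors
        warnings.warn("value sum has zero variance; sum_z set to zeros", stacklevel=2)
        sum_z = np.zeros_like(total)
    else:
        sum_z = zscore(total)
    return NormalizedRegressors(
        chosen_z=zscore(chosen),
        unchosen_z=zscore(unchosen),
        diff_z=zscore(chosen - unchosen),
        sum_z=sum_z,
    )


def regressors_from_trials(trials: list[TrialRecord], table: dict[str, float] | None = None,
                           include_single: bool = True) -> tuple[pd.DataFrame, NormalizedRegressors]:
    """Convenience: value table -> per-trial values -> normalized regressors."""
    if table is None:
        table = value_table(trials)
    vals = build_trial_values(trials, table, include_single=include_single)
    regs = normalize(vals["chosen"].to_numpy(), vals["unchosen"].to_numpy())
    return vals, regs
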