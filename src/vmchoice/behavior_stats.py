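"""Behavioral statistics: tests against chance, RT regressions, mixed ANOVA.

Choice performance is tested per decision type with a two-tailed
one-sample t test of subject percentages against 50%.  Reaction times
are regressed per session on the (chosen + unchosen) value sum and the
(chosen - unchosen) difference, the per-subject mean coefficients are
then tested against zero across subjects.  Factorial designs (e.g.
group x testing day x decision) are analysed with a classical balanced
repeated-measures ANOVA: subject is a random factor nested in the
optional between-subject factor, within-subject effects are tested
against their interaction with subjects, and the response can be
square-root transformed first.  No sphericity correction is applied;
the uncorrected degrees of freedom are reported with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TTestResult:
    t: float
    p: float
    dof: int
    mean: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    """One effect of a repeated-measures ANOVA."""

    factor: str
    F: float
    df1: int
    df2: int
    p: float
    ss: float
    transformation: str = "identity"


class UnbalancedError(ValueError):
    """Raised when a repeated-measures table has unequal or missing cells."""


def test_vs_chance(percents: np.ndarray, chance: float = 50.0) -> TTestResult:
    """Two-tailed one-sample t of per-subject percentages against chance.

    With zero between-subject variance the t statistic is undefined
    (infinite for any nonzero mean offset); the result is flagged
    ``degenerate`` instead of raising.
    """
    x = np.asarray(percents, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    mean = float(x.mean())
    if x.std(ddof=1) == 0.0:
        t = 0.0 if mean == chance else float(np.sign(mean - chance) * np.inf)
        return TTestResult(t=t, p=0.0 if mean != chance else 1.0,
                           dof=x.size - 1, mean=mean, degenerate=True)
    res = stats.ttest_1samp(x, chance)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       dof=x.size - 1, mean=mean)


def rt_regression(table: pd.DataFrame, rt_col: str = "rt_ms",
                  sum_col: str = "v_sum", diff_col: str = "v_diff",
                  subject_col: str = "subject", session_col: str = "session",
                  ) -> dict:
    """Per-session RT ~ value-sum + value-difference OLS, pooled per subject.

    Returns per-subject mean coefficients and a two-tailed one-sample t
    across subjects for each slope.  Negative group effects of both
    terms are the expected signature: responses speed up when the
    options are valuable and when they are far apart.
    """
    required = {rt_col, sum_col, diff_col, subject_col, session_col}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    rows = []
    for (subj, sess), grp in table.groupby([subject_col, session_col]):
        s = grp[sum_col].to_numpy(dtype=float)
        d = grp[diff_col].to_numpy(dtype=float)
        if s.std() == 0 or d.std() == 0:
            raise ValueError(f"constant value regressor in session {subj}/{sess}")
        X = np.column_stack([np.ones(len(grp)), s, d])
        beta, *_ = np.linalg.lstsq(X, grp[rt_col].to_numpy(dtype=float), rcond=None)
        rows.append(dict(subject=subj, session=sess,
                         intercept=beta[0], b_sum=beta[1], b_diff=beta[2]))
    per_session = pd.DataFrame(rows)
    per_subject = per_session.groupby("subject")[["intercept", "b_sum", "b_diff"]].mean()
    out = {"per_session": per_session, "per_subject": per_subject}
    for coef in ("b_sum", "b_diff"):
        res = stats.ttest_1samp(per_subject[coef].to_numpy(), 0.0)
        out[coef] = {"mean": float(per_subject[coef].mean()),
                     "t": float(res.statistic), "p": float(res.pvalue),
                     "dof": len(per_subject) - 1}
    return out


# ---------------------------------------------------------------------------
# balanced repeated-measures ANOVA (classical sums of squares)


def _raw_ss(df: pd.DataFrame, factors: list[str], dv: str) -> float:
    """R(factors) = sum over cells of (cell total)^2 / (cell size)."""
    if not factors:
        return df[dv].sum() ** 2 / len(df)
    grp = df.groupby(factors, observed=True)[dv]
    totals = grp.sum()
    counts = grp.size()
    return float((totals ** 2 / counts).sum())


def _check_balance(df: pd.DataFrame, dv: str, within: list[str], subject: str,
                   between: str | None) -> None:
    counts = df.groupby([subject] + within, observed=True)[dv].size()
    expected = df[subject].nunique() * int(np.prod([df[f].nunique() for f in within]))
    if counts.nunique() != 1 or len(counts) != expected:
        bad = counts[counts != counts.max()].index.tolist()
        raise UnbalancedError(f"unbalanced or missing subject x within cells: {bad[:10]}")
    if between is not None:
        per_subj = df.groupby(subject, observed=True)[between].nunique()
        if (per_subj != 1).any():
            raise UnbalancedError("each subject must belong to exactly one group")
        group_sizes = df.drop_duplicates(subject).groupby(between, observed=True).size()
        if group_sizes.nunique() != 1:
            raise UnbalancedError(f"unequal group sizes: {group_sizes.to_dict()}")


def ss_decomposition(df: pd.DataFrame, dv: str, within: list[str],
                     subject: str = "subject", between: str | None = None,
                     ) -> tuple[dict[str, tuple[float, int]], dict[tuple, float]]:
    """Classical SS strata for a balanced mixed design.

    Returns ``(strata, effect_ss)`` where ``strata`` maps stratum name to
    (SS, df) for every effect and error term, and ``effect_ss`` keeps the
    within-effect SS keyed by factor tuple for F construction.  Strata:
    the between factor, subjects within groups, each within effect, each
    within x between interaction, each within x subjects error term, and
    within-cell replication.
    """
    n_subj = df[subject].nunique()
    levels = {f: df[f].nunique() for f in within}
    g = df[between].nunique() if between else 1
    ct = _raw_ss(df, [], dv)

    def subsets(ws):
        for r in range(1, len(ws) + 1):
            yield from itertools.combinations(ws, r)

    strata: dict[str, tuple[float, int]] = {}
    ss: dict[tuple, float] = {}
    if between:
        ss[("G",)] = _raw_ss(df, [between], dv) - ct
        strata["between"] = (ss[("G",)], g - 1)
    ss_subj = _raw_ss(df, [subject], dv) - (ct + ss.get(("G",), 0.0))
    df_subj = n_subj - g
    strata["subjects"] = (ss_subj, df_subj)

    err: dict[tuple, float] = {}
    for w in sorted(subsets(tuple(within)), key=len):
        name = " x ".join(w)
        ss_w = _raw_ss(df, list(w), dv) - ct - sum(
            ss[v] for v in subsets(w) if v != w and v in ss)
        ss[w] = ss_w
        df_w = int(np.prod([levels[f] - 1 for f in w]))
        strata[name] = (ss_w, df_w)
        if between:
            ss_wg = (_raw_ss(df, list(w) + [between], dv) - ct - ss[("G",)]
                     - sum(ss[v] for v in subsets(w) if v in ss)
                     - sum(ss[v + ("G",)] for v in subsets(w)
                           if v != w and v + ("G",) in ss))
            ss[w + ("G",)] = ss_wg
            strata[f"between x {name}"] = (ss_wg, (g - 1) * df_w)
        ss_err = (_raw_ss(df, list(w) + [subject], dv) - ct
                  - ss.get(("G",), 0.0) - ss_subj
                  - sum(ss[v] + ss.get(v + ("G",), 0.0) for v in subsets(w))
                  - sum(err[v] for v in subsets(w) if v != w))
        err[w] = ss_err
        strata[f"error({name})"] = (ss_err, df_subj * df_w)

    y = df[dv].to_numpy(dtype=float)
    cell_means = df.groupby([subject] + within, observed=True)[dv].transform("mean")
    ss_rep = float(((y - cell_means) ** 2).sum())
    n_cells = n_subj * int(np.prod(list(levels.values())))
    strata["replication"] = (ss_rep, len(df) - n_cells)
    return strata, ss


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
    between: str | None = None,
    transformation: str = "identity",
) -> list[AnovaResult]:
    """Classical balanced mixed ANOVA with subject as a random factor.

    ``within`` factors are fully crossed within subjects; ``between``
    (optional) nests subjects in groups.  Effects reported: the between
    factor (tested against subjects-within-groups), every within effect
    and its interactions with other within factors and with the between
    factor (each tested against its interaction with subjects).
    Unbalanced or incomplete tables raise :class:`UnbalancedError`
    listing the offending cells.  ``transformation="sqrt"`` square-root
    transforms the response before decomposition.
    """
    df = table.copy()
    if transformation == "sqrt":
        if (df[dv] < 0).any():
            raise ValueError("square-root transform requires non-negative responses")
        df[dv] = np.sqrt(df[dv])
    elif transformation != "identity":
        raise ValueError(f"unknown transformation {transformation!r}")
    _check_balance(df, dv, within, subject, between)

    strata, _ = ss_decomposition(df, dv, within, subject=subject, between=between)
    results: list[AnovaResult] = []

    def f_test(name_eff: str, name_err: str, label: str) -> AnovaResult:
        ss_e, df_e = strata[name_eff]
        ss_r, df_r = strata[name_err]
        ms_e, ms_r = ss_e / df_e, ss_r / df_r
        if ms_e <= 1e-300:  # no effect variance at all (e.g. identical columns)
            f, p = 0.0, 1.0
        elif ms_r <= 1e-300:
            f, p = np.inf, 0.0
        else:
            f = ms_e / ms_r
            p = float(stats.f.sf(f, df_e, df_r))
        return AnovaResult(factor=label, F=f, df1=df_e, df2=df_r, p=p, ss=ss_e,
                           transformation=transformation)

    if between:
        results.append(f_test("between", "subjects", between))

    def subsets(ws):
        for r in range(1, len(ws) + 1):
            yield from itertools.combinations(ws, r)

    for w in sorted(subsets(tuple(within)), key=len):
        name = " x ".join(w)
        results.append(f_test(name, f"error({name})", name))
        if between:
            results.append(f_test(f"between x {name}", f"error({name})",
                                  f"{between} x {name}"))

    warnings.warn("sphericity is assumed; no Huynh-Feldt correction applied",
                  stacklevel=2)
    return results


def anova_total_check(table: pd.DataFrame, dv: str, within: list[str],
                      subject: str = "subject", between: str | None = None,
                      ) -> tuple[float, float]:
    """(total SS, sum of all decomposed strata) — equal for a valid decomposition."""
    y = table[dv].to_numpy(dtype=float)
    total = float(((y - y.mean()) ** 2).sum())
    strata, _ = ss_decomposition(table, dv, within, subject=subject, between=between)
    return total, float(sum(s for s, _ in strata.values()))
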