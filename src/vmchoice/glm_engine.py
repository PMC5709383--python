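"""Event-related GLM construction, per-session OLS, and session/group pooling.

Two designs are provided for the cued-choice task:

* GLM-1: categorical — nine decision-condition regressors plus one for
  discarded trials, each entered at cue onset and at outcome delivery
  (20 columns), plus four response regressors (left/right, convolved
  and unconvolved) for 24 columns;
* GLM-2: parametric — cue and outcome events split by whether a
  rewarded stimulus (CS+) was chosen (4 columns), two parametric
  modulators on the CS+-chosen cue events (z-scored value sum and
  chosen-minus-unchosen value difference), and the same four response
  regressors, 10 columns.

Parametric modulators are mean-centered per session before convolution
so they are orthogonal to their parent event regressor.  Data and design
are high-pass filtered identically (cubic B-spline drift basis, 100 s
cutoff) before OLS.  Session effects are pooled within subject by
inverse-variance (fixed-effects) weighting and tested across subjects
with a two-tailed one-sample t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bold_sim import BoldSeries, HRFParams, convolve_events
from .tasks_agents import CSM, SKIP, TrialRecord
from .valuation import NormalizedRegressors


class DesignError(ValueError):
    pass


class CollinearityError(ValueError):
    """Raised when jointly entered regressors are too correlated to separate."""


@dataclass
class DesignMatrix:
    """Named design with convolution flags and a record of dropped columns."""

    names: list[str]
    X: np.ndarray
    tr: float
    convolved: list[bool]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise DesignError("X must be (n_volumes, n_columns) matching names")

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)

    def to_tsv(self, path) -> None:
        """Write the design as TSV plus a JSON column manifest alongside."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        manifest = {"columns": self.names, "convolved": self.convolved,
                    "dropped": self.dropped, "tr": self.tr}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


@dataclass
class SessionFit:
    """OLS estimates for one session."""

    names: list[str]
    betas: np.ndarray
    beta_vars: np.ndarray
    sigma2: float
    dof: int
    xtx_inv: np.ndarray

    def beta(self, name: str) -> float:
        return float(self.betas[self.names.index(name)])

    def beta_var(self, name: str) -> float:
        return float(self.beta_vars[self.names.index(name)])


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    weights: tuple[float, ...]


@dataclass
class ContrastResult:
    name: str
    effect: float
    se: float
    t: float
    p: float
    dof: int


def _assemble(columns: dict[str, np.ndarray], convolved: dict[str, bool],
              tr: float) -> DesignMatrix:
    names, cols, flags, dropped = [], [], [], []
    for name, col in columns.items():
        if np.allclose(col, 0.0):
            warnings.warn(f"design column {name!r} is empty and was dropped", stacklevel=3)
            dropped.append(name)
            continue
        names.append(name)
        cols.append(col)
        flags.append(convolved[name])
    return DesignMatrix(names=names, X=np.column_stack(cols), tr=tr,
                        convolved=flags, dropped=dropped)


def _response_columns(trials: list[TrialRecord], hrf: HRFParams, tr: float,
                      n_volumes: int) -> tuple[dict[str, np.ndarray], dict[str, bool]]:
    cols: dict[str, np.ndarray] = {}
    flags: dict[str, bool] = {}
    for side in ("left", "right"):
        onsets = _response_onsets(trials, side)
        conv = convolve_events(onsets, 1.0, hrf=hrf, tr=tr, n_volumes=n_volumes).values \
            if onsets.size else np.zeros(n_volumes)
        cols[f"resp_{side}"] = conv
        flags[f"resp_{side}"] = True
        unconv = np.zeros(n_volumes)
        for onset in onsets:
            k = int(round(onset / tr))
            if 0 <= k < n_volumes:
                unconv[k] += 1.0
        cols[f"resp_{side}_raw"] = unconv
        flags[f"resp_{side}_raw"] = False
    return cols, flags


def _response_onsets(trials: list[TrialRecord], side: str) -> np.ndarray:
    onsets = []
    for tr_ in trials:
        if tr_.choice == SKIP:
            chosen_side = "blank"
        else:
            chosen_side = tr_.sides[tr_.offered.index(tr_.choice)]
        if chosen_side == side:
            onsets.append(tr_.t_response)
    return np.asarray(onsets, dtype=float)


def n_volumes_for(trials: list[TrialRecord], tr: float, padding: float = 20.0) -> int:
    return int(np.ceil((trials[-1].t_outcome + padding) / tr))


def build_glm2(
    trials: list[TrialRecord],
    regressors: NormalizedRegressors,
    hrf: HRFParams = HRFParams(),
    tr: float = 2.28,
    n_volumes: int | None = None,
) -> DesignMatrix:
    """Parametric design: 4 event + 2 modulator + 4 response columns.

    ``regressors`` must align with the trials in order (one entry per
    trial, as produced by :func:`vmchoice.valuation.regressors_from_trials`
    with ``include_single=True``).  Modulators are mean-centered (they
    come in z-scored) and apply to CS+-chosen cue events only.
    """
    if n_volumes is None:
        n_volumes = n_volumes_for(trials, tr)
    if len(regressors.diff_z) != len(trials):
        raise DesignError("regressor values must align one-per-trial")

    cs_mask = np.array([tr_.choice not in (SKIP, CSM) for tr_ in trials])
    if not cs_mask.any():
        raise DesignError("no CS+-chosen trials: parametric design undefined")
    cues = np.array([tr_.t_cue for tr_ in trials])
    outs = np.array([tr_.t_outcome for tr_ in trials])

    def conv(onsets, amps=1.0):
        if np.size(onsets) == 0:
            return np.zeros(n_volumes)
        return convolve_events(onsets, amps, hrf=hrf, tr=tr, n_volumes=n_volumes).values

    diff_c = regressors.diff_z[cs_mask] - regressors.diff_z[cs_mask].mean()
    sum_c = regressors.sum_z[cs_mask] - regressors.sum_z[cs_mask].mean()

    columns = {
        "cs_cue": conv(cues[cs_mask]),
        "cs_outcome": conv(outs[cs_mask]),
        "nocs_cue": conv(cues[~cs_mask]),
        "nocs_outcome": conv(outs[~cs_mask]),
        "cs_cue_x_sum": conv(cues[cs_mask], sum_c),
        "cs_cue_x_diff": conv(cues[cs_mask], diff_c),
    }
    flags = {name: True for name in columns}
    resp_cols, resp_flags = _response_columns(trials, hrf, tr, n_volumes)
    columns.update(resp_cols)
    flags.update(resp_flags)
    return _assemble(columns, flags, tr)


def glm1_condition(trial: TrialRecord) -> str:
    """Provisional decision-type x choice condition labels (9 cells)."""
    if trial.trial_type == "single":
        return "single_skip" if trial.choice == SKIP else f"single_{trial.offered[0]}"
    if CSM in trial.offered:
        return "csm_pair_csplus" if trial.choice != CSM else "csm_pair_csm"
    pair = "_".join(sorted(trial.offered))
    return f"pair_{pair}"


GLM1_CONDITIONS = (
    "single_HV", "single_LV", "single_CV", "single_skip",
    "csm_pair_csplus", "csm_pair_csm",
    "pair_HV_LV", "pair_CV_HV", "pair_CV_LV",
)


def build_glm1(
    trials: list[TrialRecord],
    hrf: HRFParams = HRFParams(),
    tr: float = 2.28,
    n_volumes: int | None = None,
    discarded: list[int] | None = None,
) -> DesignMatrix:
    """Categorical design: (9 conditions + discard) x (cue, outcome) + 4 response.

    Conditions absent from the session produce empty columns that are
    dropped with a warning; a full session covering every condition
    yields 24 columns.
    """
    if n_volumes is None:
        n_volumes = n_volumes_for(trials, tr)
    discarded = set(discarded or [])

    cond_cues: dict[str, list[float]] = {c: [] for c in GLM1_CONDITIONS}
    cond_outs: dict[str, list[float]] = {c: [] for c in GLM1_CONDITIONS}
    disc_cues, disc_outs = [], []
    for tr_ in trials:
        if tr_.index in discarded:
            disc_cues.append(tr_.t_cue)
            disc_outs.append(tr_.t_outcome)
            continue
        cond = glm1_condition(tr_)
        if cond not in cond_cues:
            raise DesignError(f"unknown condition label {cond!r}")
        cond_cues[cond].append(tr_.t_cue)
        cond_outs[cond].append(tr_.t_outcome)

    def conv(onsets):
        if not len(onsets):
            return np.zeros(n_volumes)
        return convolve_events(np.asarray(onsets), 1.0, hrf=hrf, tr=tr,
                               n_volumes=n_volumes).values

    columns: dict[str, np.ndarray] = {}
    for cond in GLM1_CONDITIONS:
        columns[f"{cond}_cue"] = conv(cond_cues[cond])
    columns["discard_cue"] = conv(disc_cues)
    for cond in GLM1_CONDITIONS:
        columns[f"{cond}_outcome"] = conv(cond_outs[cond])
    columns["discard_outcome"] = conv(disc_outs)
    flags = {name: True for name in columns}
    resp_cols, resp_flags = _response_columns(trials, hrf, tr, n_volumes)
    columns.update(resp_cols)
    flags.update(resp_flags)
    return _assemble(columns, flags, tr)


# ---------------------------------------------------------------------------
# filtering and estimation


def highpass_basis(n_volumes: int, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Cubic B-spline drift basis tracking fluctuations slower than ``cutoff``.

    Knots are spaced ``cutoff / 3`` seconds apart: dense enough that a
    drift with period twice the cutoff is absorbed to well under 1% of
    its amplitude, while event-speed signal passes nearly untouched.
    """
    from scipy.interpolate import BSpline

    t = np.arange(n_volumes) * tr
    spacing = cutoff / 3.0
    nseg = max(1, int(np.ceil((t[-1] - t[0]) / spacing)))
    interior = np.linspace(t[0], t[-1], nseg + 1)
    knots = np.concatenate([[t[0]] * 3, interior, [t[-1]] * 3])
    return BSpline.design_matrix(t, knots, 3).toarray()


def highpass(data: np.ndarray, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Residualize columns (or a vector) against the drift basis."""
    arr = np.asarray(data, dtype=float)
    vec = arr.ndim == 1
    if vec:
        arr = arr[:, None]
    basis = highpass_basis(arr.shape[0], tr, cutoff)
    coef, *_ = np.linalg.lstsq(basis, arr, rcond=None)
    out = arr - basis @ coef
    return out[:, 0] if vec else out


def fit_session(bold: BoldSeries, design: DesignMatrix,
                highpass_cutoff: float | None = 100.0) -> SessionFit:
    """OLS after identical high-pass filtering of data and design.

    Filtering removes the constant, so no intercept column is added.
    Rank-deficient designs raise after an attempt to prune duplicate
    columns.
    """
    y = bold.values
    X = design.X
    names = list(design.names)
    if highpass_cutoff is not None:
        y = highpass(y, bold.tr, highpass_cutoff)
        X = highpass(X, bold.tr, highpass_cutoff)
    else:
        X = np.column_stack([X, np.ones(len(y))])
        names = names + ["intercept"]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep, seen = [], []
        for j in range(X.shape[1]):
            cand = X[:, seen + [j]]
            if np.linalg.matrix_rank(cand) == len(seen) + 1:
                seen.append(j)
                keep.append(j)
            else:
                warnings.warn(f"pruning rank-deficient column {names[j]!r}", stacklevel=2)
        X = X[:, keep]
        names = [names[j] for j in keep]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("design remains rank deficient after pruning")

    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ y
    resid = y - X @ betas
    dof = len(y) - X.shape[1]
    if highpass_cutoff is not None:
        dof -= highpass_basis(len(y), bold.tr, highpass_cutoff).shape[1]
    if dof <= 0:
        raise DesignError("non-positive residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    return SessionFit(names=names, betas=betas, beta_vars=sigma2 * np.diag(xtx_inv),
                      sigma2=sigma2, dof=dof, xtx_inv=xtx_inv)


def contrast(fit: SessionFit, spec: ContrastSpec) -> ContrastResult:
    """t = c'beta / sqrt(c' (X'X)^-1 c sigma2), two-tailed p."""
    c = np.asarray(spec.weights, dtype=float)
    if c.size != len(fit.names):
        raise DesignError(f"contrast length {c.size} != {len(fit.names)} columns")
    effect = float(c @ fit.betas)
    var = float(c @ fit.xtx_inv @ c) * fit.sigma2
    se = np.sqrt(var)
    t = effect / se
    p = 2.0 * stats.t.sf(abs(t), fit.dof)
    return ContrastResult(name=spec.name, effect=effect, se=se, t=t, p=p, dof=fit.dof)


def contrast_for(fit: SessionFit, column: str) -> ContrastResult:
    """Single-column contrast by name."""
    w = tuple(1.0 if n == column else 0.0 for n in fit.names)
    return contrast(fit, ContrastSpec(name=column, weights=w))


def fixed_effects(effects: np.ndarray, variances: np.ndarray) -> tuple[float, float]:
    """Inverse-variance weighted combination across sessions.

    Returns (pooled effect, pooled variance).  A single session passes
    through unchanged; equal variances reduce to the plain mean.
    """
    effects = np.atleast_1d(np.asarray(effects, dtype=float))
    variances = np.atleast_1d(np.asarray(variances, dtype=float))
    if effects.size == 0:
        raise ValueError("no session effects to combine")
    if np.any(variances <= 0):
        raise ValueError("session variances must be positive")
    w = 1.0 / variances
    return float(np.sum(w * effects) / np.sum(w)), float(1.0 / np.sum(w))


def group_test(subject_effects: np.ndarray, popmean: float = 0.0) -> tuple[float, float]:
    """Two-tailed one-sample t across subjects (stand-in for mixed effects)."""
    x = np.asarray(subject_effects, dtype=float)
    if x.size < 2:
        raise ValueError("group test needs at least 2 subjects")
    res = stats.ttest_1samp(x, popmean)
    return float(res.statistic), float(res.pvalue)


def signed_vs_absolute(
    cue_onsets: np.ndarray,
    diff_z: np.ndarray,
    bold: BoldSeries,
    hrf: HRFParams = HRFParams(),
    max_correlation: float = 0.9,
    highpass_cutoff: float | None = 100.0,
    orthogonalize: bool = False,
) -> dict:
    """Joint GLM with signed and absolute value-difference modulators.

    The signed regressor is the z-scored chosen-minus-unchosen
    difference; the absolute regressor is the z-scored |difference|.
    Both are entered together on the decision events (plus the decision
    main effect).  Refuses to fit when their correlation exceeds
    ``max_correlation``.  With ``orthogonalize=True`` the absolute
    modulator is residualized against the signed one before entry; when
    the two are exactly uncorrelated this changes nothing.
    """
    diff_z = np.asarray(diff_z, dtype=float)
    signed = diff_z - diff_z.mean()
    abs_raw = np.abs(diff_z)
    absolute = abs_raw - abs_raw.mean()
    sd_s, sd_a = signed.std(), absolute.std()
    if sd_s == 0 or sd_a == 0:
        raise CollinearityError("a value-difference modulator is constant")
    signed, absolute = signed / sd_s, absolute / sd_a
    r = float(np.corrcoef(signed, absolute)[0, 1])
    if abs(r) > max_correlation:
        raise CollinearityError(
            f"signed/absolute modulators correlate at r={r:.3f} > {max_correlation}")
    if orthogonalize:
        absolute = absolute - (absolute @ signed) / (signed @ signed) * signed

    n_volumes = bold.n_volumes
    cols = {
        "decision": convolve_events(cue_onsets, 1.0, hrf=hrf, tr=bold.tr,
                                    n_volumes=n_volumes).values,
        "signed_diff": convolve_events(cue_onsets, signed, hrf=hrf, tr=bold.tr,
                                       n_volumes=n_volumes).values,
        "abs_diff": convolve_events(cue_onsets, absolute, hrf=hrf, tr=bold.tr,
                                    n_volumes=n_volumes).values,
    }
    design = _assemble(cols, {k: True for k in cols}, bold.tr)
    fit = fit_session(bold, design, highpass_cutoff=highpass_cutoff)
    out = {"correlation": r, "dof": fit.dof}
    for name in ("signed_diff", "abs_diff"):
        res = contrast_for(fit, name)
        out[name] = {"beta": res.effect, "se": res.se, "t": res.t, "p": res.p}
    return out
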