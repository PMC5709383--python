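"""Decision-locked ROI time-course analysis.

The analysis chain mirrors standard event-related ROI practice: extract
the mean signal of a small spherical mask, cut epochs around each
decision onset on an upsampled (linearly interpolated) time grid,
regress the signal across trials at every timepoint on per-trial value
regressors, and summarize either with leave-one-out (LOO) peak
selection — pick the peak timepoint (or voxel) from the mean of all
*other* sessions, read out the held-out session there — or with
per-trial peak measures in a fixed post-stimulus window.

LOO selection exists because picking the peak and testing it on the
same data is circular: the suite demonstrates that same-data selection
inflates the false-positive rate while LOO keeps it nominal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bold_sim import BoldSeries


class MaskError(ValueError):
    pass


@dataclass(frozen=True)
class RoiMask:
    """Spherical voxel mask: Euclidean distance <= radius (voxel units)."""

    center: tuple[int, int, int]
    radius: float = 2.0

    def voxels(self, shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        cx, cy, cz = self.center
        r = int(np.floor(self.radius))
        out = []
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dz in range(-r, r + 1):
                    if dx * dx + dy * dy + dz * dz <= self.radius ** 2:
                        v = (cx + dx, cy + dy, cz + dz)
                        if all(0 <= v[i] < shape[i] for i in range(3)):
                            out.append(v)
        return out


def extract_roi(grid: np.ndarray, mask: RoiMask, tr: float = 2.28) -> BoldSeries:
    """Mean over in-sphere voxels of a 4-D (x, y, z, time) array."""
    voxels = mask.voxels(grid.shape[:3])
    if not voxels:
        raise MaskError(f"mask at {mask.center} covers no voxels of grid {grid.shape[:3]}")
    stack = np.stack([grid[v] for v in voxels])
    return BoldSeries(values=stack.mean(axis=0), tr=tr)


@dataclass
class EpochedTimecourse:
    """Trial-aligned, upsampled signal matrix (trials x timepoints)."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to the locked event
    trial_index: np.ndarray  # indices of retained trials
    dropped: list[int]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long format: (trial, time_s, value)."""
        rows = pd.DataFrame(self.data, index=self.trial_index, columns=self.times)
        rows.index.name = "trial"
        out = rows.reset_index().melt(id_vars="trial", var_name="time_s", value_name="value")
        return out.sort_values(["trial", "time_s"]).reset_index(drop=True)


def epoch_upsample(
    series: BoldSeries,
    event_times: np.ndarray,
    window: tuple[float, float] = (-2.0, 14.0),
    step: float = 0.25,
    baseline: tuple[float, float] | None = None,
) -> EpochedTimecourse:
    """Cut upsampled epochs around each event by linear interpolation.

    Events whose window extends past the recording are dropped (logged
    in ``dropped``).  ``baseline=(a, b)`` subtracts each trial's mean
    signal over [a, b] seconds relative to the event; default is no
    baseline correction.
    """
    event_times = np.asarray(event_times, dtype=float)
    rel = np.arange(window[0], window[1] + step / 2, step)
    scan_times = series.times
    rows, kept, dropped = [], [], []
    for i, ev in enumerate(event_times):
        t = ev + rel
        if t[0] < scan_times[0] or t[-1] > scan_times[-1]:
            dropped.append(i)
            continue
        row = np.interp(t, scan_times, series.values)
        if baseline is not None:
            sel = (rel >= baseline[0]) & (rel <= baseline[1])
            row = row - row[sel].mean()
        rows.append(row)
        kept.append(i)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} epoch(s) at the recording edge", stacklevel=2)
    if not rows:
        raise ValueError("no epochs survived; window exceeds the recording everywhere")
    return EpochedTimecourse(data=np.array(rows), times=rel,
                             trial_index=np.array(kept), dropped=dropped)


@dataclass
class TimepointBetas:
    """Per-timepoint regression coefficients ('effect size') with SEs."""

    times: np.ndarray
    names: list[str]
    betas: np.ndarray  # (timepoints, regressors)
    ses: np.ndarray

    def series(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


def timepoint_regression(epochs: EpochedTimecourse,
                         regressors: pd.DataFrame) -> TimepointBetas:
    """Across-trial OLS of the signal at every timepoint.

    ``regressors`` has one row per retained trial; an intercept is added
    automatically.
    """
    if len(regressors) != epochs.n_trials:
        raise ValueError(
            f"{len(regressors)} regressor rows for {epochs.n_trials} trials")
    X = np.column_stack([np.ones(epochs.n_trials), regressors.to_numpy(dtype=float)])
    names = ["intercept", *map(str, regressors.columns)]
    if epochs.n_trials <= X.shape[1]:
        raise ValueError("fewer trials than regression parameters")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = (xtx_inv @ X.T @ epochs.data).T  # (timepoints, k)
    resid = epochs.data - X @ betas.T  # (trials, timepoints)
    dof = epochs.n_trials - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    ses = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    return TimepointBetas(times=epochs.times, names=names, betas=betas, ses=ses)


@dataclass
class LooResult:
    """Held-out values at peaks selected from the remaining sessions."""

    values: np.ndarray
    indices: np.ndarray  # selected timepoint/voxel index per fold
    t: float
    p: float  # naive one-sample t p-value
    perm_p: float | None = None  # exact sign-flip permutation p-value

    def to_json_dict(self) -> dict:
        return {"values": self.values.tolist(), "indices": self.indices.tolist(),
                "t": self.t, "p": self.p, "perm_p": self.perm_p}


def _peak_index(mean_course: np.ndarray, mode: str) -> int:
    if mode == "max":
        return int(np.argmax(mean_course))
    if mode == "abs":
        return int(np.argmax(np.abs(mean_course)))
    raise ValueError(f"unknown peak mode {mode!r}")


def _loo_values(courses: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    n = courses.shape[0]
    others = (courses.sum(axis=0)[None, :] - courses) / (n - 1)
    stat = np.abs(others) if mode == "abs" else others
    if mode not in ("abs", "max"):
        raise ValueError(f"unknown peak mode {mode!r}")
    indices = np.argmax(stat, axis=1)
    values = courses[np.arange(n), indices]
    return values, indices


def _one_sample_t(values: np.ndarray) -> float:
    sd = values.std(ddof=1)
    if sd == 0:
        return np.inf if values.mean() != 0 else 0.0
    return float(values.mean() / (sd / np.sqrt(values.size)))


def loo_peak_stat(session_courses: np.ndarray, mode: str = "abs",
                  permutation: bool = True) -> LooResult:
    """Leave-one-out peak selection over sessions.

    ``session_courses`` is (n_sessions, n_points): per-session beta time
    courses, or flattened per-session voxel statistic maps (the spatial
    variant uses identical fold logic).  For each fold the peak of the
    mean of the other sessions is found (``mode="abs"``: extremum of
    |mean|, suitable for negative effects; ``mode="max"``: literal
    maximum) and the held-out session's value there is collected.

    Two p-values accompany the fold values.  ``p`` is the two-tailed
    one-sample t test; it removes selection *bias* (each fold's value is
    selected without seeing that session) but is still anticonservative
    when selection is noise-driven, because the folds share their
    selection and are therefore correlated.  ``perm_p`` re-runs the
    entire selection under every session sign-flip pattern and is exact
    under the null hypothesis of sign-symmetric session courses; it is
    the recommended inference.  Because flipping *all* sessions leaves
    |t| unchanged, the flip distribution has 2^(n-1) distinct values:
    at alpha = 0.05 the test is conservative (level 1/32) with 6
    sessions and close to nominal (level 6/128) with 8.
    """
    courses = np.asarray(session_courses, dtype=float)
    if courses.ndim != 2 or courses.shape[0] < 3:
        raise ValueError("need a (n_sessions >= 3, n_points) array")
    n = courses.shape[0]
    values, indices = _loo_values(courses, mode)
    t = _one_sample_t(values)
    p = 2.0 * stats.t.sf(abs(t), n - 1) if np.isfinite(t) else 0.0

    perm_p = None
    if permutation:
        t_obs = abs(t)
        count = total = 0
        for bits in range(2 ** n):
            signs = np.array([1.0 if bits >> j & 1 else -1.0 for j in range(n)])
            t_perm = abs(_one_sample_t(_loo_values(courses * signs[:, None], mode)[0]))
            count += t_perm >= t_obs - 1e-12
            total += 1
        perm_p = count / total
    return LooResult(values=values, indices=indices, t=t, p=float(p), perm_p=perm_p)


def insample_peak_stat(session_courses: np.ndarray, mode: str = "abs") -> LooResult:
    """Circular (biased) variant: peak selected from the mean of all sessions.

    Provided to quantify selection bias; inference from it is
    anticonservative.
    """
    courses = np.asarray(session_courses, dtype=float)
    k = _peak_index(courses.mean(axis=0), mode)
    values = courses[:, k]
    res = stats.ttest_1samp(values, 0.0)
    return LooResult(values=values, indices=np.full(courses.shape[0], k),
                     t=float(res.statistic), p=float(res.pvalue))


def trial_peaks(epochs: EpochedTimecourse,
                window: tuple[float, float] = (1.5, 6.5)) -> np.ndarray:
    """Per-trial maximum of the epoch within a post-stimulus window."""
    sel = (epochs.times >= window[0]) & (epochs.times <= window[1])
    if not sel.any():
        raise ValueError(f"window {window} lies outside the epoch times")
    return epochs.data[:, sel].max(axis=1)


def trial_peak_analysis(
    epochs: EpochedTimecourse,
    labels: pd.DataFrame,
    window: tuple[float, float] = (1.5, 6.5),
    factors: tuple[str, str] = ("chosen", "unchosen"),
) -> pd.DataFrame:
    """Per-condition means of trial peaks in the 1.5-6.5 s window.

    ``labels`` carries one row per retained trial with the two factor
    columns (e.g. chosen-option and unchosen-option identity).  Returns
    the cell table (factor levels, mean peak, n); empty cells simply do
    not appear.  Feed per-subject cell tables to
    :func:`vmchoice.behavior_stats.rm_anova` for the factorial test.
    """
    if len(labels) != epochs.n_trials:
        raise ValueError("labels must have one row per retained trial")
    peaks = trial_peaks(epochs, window)
    df = labels.loc[:, list(factors)].copy()
    df["peak"] = peaks
    cells = (df.groupby(list(factors), observed=True)["peak"]
               .agg(mean="mean", n="size").reset_index())
    return cells
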