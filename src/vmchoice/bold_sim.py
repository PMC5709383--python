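"""Synthetic BOLD generation: gamma HRF, event convolution, and two generators.

The hemodynamic response is a gamma-density kernel with 3 s mean and
1.5 s standard deviation (shape k = mean^2/sd^2 = 4, scale
theta = sd^2/mean = 0.75 s), the conventional fast macaque HRF, sampled
at ``dt`` and normalized to unit sum.

Two forward models produce ROI time series from trial events:

* a *linear* generator in which each decision event has amplitude
  ``b0 + b_diff * diff_z + b_sum * sum_z`` (mirroring the parametric GLM
  it is meant to validate), plus AR(1)+white noise and optional slow
  cosine drift;
* a *two-pool attractor* generator: two rectified leaky accumulators
  with self-excitation and mutual inhibition race to a threshold, their
  summed (aggregate) activity is integrated per trial and convolved with
  the HRF.  When the winning pool's activity *decays* after the decision
  the aggregate signal is dominated by decision time, which is longer
  for harder decisions — yielding a negative chosen-minus-unchosen value
  beta.  When the winner is *sustained* in its attractor until trial
  end, the post-decision activity scales with time remaining, shifting
  the fitted value-difference beta upward.  This single post-decision
  regime switch is the sign-flip mechanism the generator demonstrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class HRFConfigError(ValueError):
    pass


@dataclass(frozen=True)
class HRFParams:
    """Gamma HRF with given mean and spread (seconds).

    ``sd_is_fwhm=False`` (default) reads the spread as the standard
    deviation of the gamma density; set True to interpret it as FWHM.
    """

    mean: float = 3.0
    sd: float = 1.5
    dt: float = 0.1
    length: float = 20.0
    sd_is_fwhm: bool = False

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise HRFConfigError("mean and sd must be positive")
        if self.dt >= self.length:
            raise HRFConfigError(f"dt ({self.dt}) must be smaller than length ({self.length})")

    @property
    def sd_effective(self) -> float:
        # FWHM of a gamma is not closed-form; use the Gaussian conversion
        return self.sd / (2.0 * np.sqrt(2.0 * np.log(2.0))) if self.sd_is_fwhm else self.sd

    @property
    def shape(self) -> float:
        return self.mean ** 2 / self.sd_effective ** 2

    @property
    def scale(self) -> float:
        return self.sd_effective ** 2 / self.mean


def gamma_hrf(params: HRFParams = HRFParams()) -> np.ndarray:
    """Discretized gamma-density kernel, normalized to unit sum.

    Evaluated at bin centers so the discrete moments track the
    continuous mean and sd to within one grid step.
    """
    t = (np.arange(int(round(params.length / params.dt))) + 0.5) * params.dt
    kernel = stats.gamma.pdf(t, a=params.shape, scale=params.scale)
    total = kernel.sum()
    if total <= 0:
        raise HRFConfigError("degenerate kernel: no mass on the grid")
    return kernel / total


def kernel_moments(kernel: np.ndarray, dt: float) -> tuple[float, float]:
    """Empirical (mean, sd) of a discretized kernel on its bin-center grid."""
    t = (np.arange(kernel.size) + 0.5) * dt
    w = kernel / kernel.sum()
    mean = float(np.sum(w * t))
    var = float(np.sum(w * (t - mean) ** 2))
    return mean, float(np.sqrt(var))


@dataclass
class BoldSeries:
    """A single ROI (or voxel) time series sampled at the scanner TR."""

    values: np.ndarray
    tr: float = 2.28

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "signal": self.values})


def convolve_events(
    onsets: np.ndarray,
    amplitudes: np.ndarray | float,
    hrf: HRFParams | np.ndarray = HRFParams(),
    tr: float = 2.28,
    n_volumes: int | None = None,
    durations: np.ndarray | float = 0.0,
    dt: float | None = None,
) -> BoldSeries:
    """HRF-convolve an event train and sample it on the TR grid.

    Events are placed as deltas (or boxcars when ``durations`` > 0) on a
    fine ``dt`` grid, convolved with the kernel, and linearly
    interpolated onto scan times.  The operation is exactly linear in
    the amplitudes.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets.shape)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    if isinstance(hrf, HRFParams):
        params = hrf
        kernel = gamma_hrf(params)
        dt = params.dt if dt is None else dt
    else:
        kernel = np.asarray(hrf, dtype=float)
        if dt is None:
            raise ValueError("dt is required when passing a raw kernel")
    if n_volumes is None:
        t_end = float(onsets.max() + durations.max()) + kernel.size * dt
        n_volumes = int(np.ceil(t_end / tr)) + 1

    n_fine = int(np.ceil(n_volumes * tr / dt)) + 1
    train = np.zeros(n_fine)
    for onset, amp, dur in zip(onsets, amplitudes, durations):
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            continue
        i1 = min(max(i0 + 1, i0 + int(round(dur / dt))), n_fine)
        train[i0:i1] += amp
    signal = np.convolve(train, kernel)[:n_fine]
    scan_times = np.arange(n_volumes) * tr
    fine_times = np.arange(n_fine) * dt
    return BoldSeries(values=np.interp(scan_times, fine_times, signal), tr=tr)


@dataclass(frozen=True)
class NoiseModel:
    """AR(1)-plus-white scanner noise with optional slow cosine drift.

    Default sds are on the scale of single-event responses under the
    unit-sum HRF kernel (peak ~0.03 per unit event amplitude), giving a
    realistically detectable but noisy per-session effect.  The drift
    (period ``drift_period`` seconds) lies below the GLM high-pass
    cutoff and should be removed by filtering.
    """

    white_sd: float = 0.015
    ar1: float = 0.3
    ar_sd: float = 0.01
    drift_amp: float = 0.03
    drift_period: float = 300.0

    def sample(self, n_volumes: int, tr: float, rng: np.random.Generator) -> np.ndarray:
        noise = np.zeros(n_volumes)
        if self.white_sd > 0:
            noise += rng.normal(0.0, self.white_sd, n_volumes)
        if self.ar_sd > 0:
            innov = rng.normal(0.0, self.ar_sd * np.sqrt(1 - self.ar1 ** 2), n_volumes)
            ar = np.empty(n_volumes)
            ar[0] = innov[0]
            for i in range(1, n_volumes):
                ar[i] = self.ar1 * ar[i - 1] + innov[i]
            noise += ar
        if self.drift_amp > 0:
            t = np.arange(n_volumes) * tr
            phase = rng.uniform(0, 2 * np.pi)
            noise += self.drift_amp * np.cos(2 * np.pi * t / self.drift_period + phase)
        return noise


@dataclass(frozen=True)
class LinearBetas:
    """Planted amplitudes of the linear ROI generator."""

    decision: float = 1.0
    diff: float = -0.5  # negative: difficulty-positive, macaque-like
    sum: float = 0.0
    outcome: float = 0.5
    outcome_chosen: float = 0.0  # optional outcome-locked chosen-value amplitude


def generate_linear_roi(
    cue_onsets: np.ndarray,
    diff_z: np.ndarray,
    sum_z: np.ndarray,
    betas: LinearBetas = LinearBetas(),
    hrf: HRFParams = HRFParams(),
    tr: float = 2.28,
    n_volumes: int | None = None,
    noise_model: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    outcome_onsets: np.ndarray | None = None,
    chosen_z: np.ndarray | None = None,
) -> BoldSeries:
    """Linear forward model: per-decision amplitude then HRF convolution.

    Decision-event amplitude is ``decision + diff * diff_z + sum *
    sum_z``; outcome events (if given) add ``outcome`` plus optionally
    ``outcome_chosen * chosen_z``.  Seeded noise from ``noise_model``.
    """
    cue_onsets = np.asarray(cue_onsets, dtype=float)
    amps = betas.decision + betas.diff * np.asarray(diff_z) + betas.sum * np.asarray(sum_z)
    onsets, amplitudes = [cue_onsets], [amps]
    if outcome_onsets is not None:
        out_amp = np.full(len(outcome_onsets), betas.outcome, dtype=float)
        if betas.outcome_chosen != 0.0 and chosen_z is not None:
            out_amp = out_amp + betas.outcome_chosen * np.asarray(chosen_z)
        onsets.append(np.asarray(outcome_onsets, dtype=float))
        amplitudes.append(out_amp)
    series = convolve_events(np.concatenate(onsets), np.concatenate(amplitudes),
                             hrf=hrf, tr=tr, n_volumes=n_volumes)
    if noise_model is not None:
        if rng is None:
            rng = np.random.default_rng()
        series.values = series.values + noise_model.sample(series.n_volumes, tr, rng)
    return series


def generate_linear_grid(
    cue_onsets: np.ndarray,
    diff_z: np.ndarray,
    sum_z: np.ndarray,
    shape: tuple[int, int, int] = (9, 9, 9),
    center: tuple[int, int, int] | None = None,
    blob_sigma: float = 1.5,
    betas: LinearBetas = LinearBetas(),
    hrf: HRFParams = HRFParams(),
    tr: float = 2.28,
    n_volumes: int | None = None,
    noise_model: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Voxel-grid version: the effect sits in a Gaussian blob (~3-voxel radius).

    Returns a 4-D array (x, y, z, time) and the TR.  Noise is drawn
    independently per voxel; the signal is the linear ROI series scaled
    by the blob profile.
    """
    if rng is None:
        rng = np.random.default_rng()
    if center is None:
        center = tuple(s // 2 for s in shape)
    clean = generate_linear_roi(cue_onsets, diff_z, sum_z, betas=betas, hrf=hrf,
                                tr=tr, n_volumes=n_volumes, noise_model=None)
    nv = clean.n_volumes
    xs, ys, zs = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = ((xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2).astype(float)
    profile = np.exp(-d2 / (2.0 * blob_sigma ** 2))
    grid = profile[..., None] * clean.values[None, None, None, :]
    if noise_model is not None:
        for idx in np.ndindex(shape):
            grid[idx] += noise_model.sample(nv, tr, rng)
    return grid, tr


# ---------------------------------------------------------------------------
# two-pool attractor generator


@dataclass(frozen=True)
class NetworkParams:
    """Reduced two-variable rate model of a winner-take-all decision circuit.

    Each pool obeys (Euler step ``dt``, rectified at zero)

        x' = -leak * (x - baseline) + w_excite * (x - baseline)
             - w_inhib * (y - baseline) + input_gain * v_x + noise

    until one pool crosses ``threshold``.  Afterwards, in the ``decay``
    regime both pools relax back to baseline; in ``sustain`` the winner
    holds its attractor level until trial end while the loser relaxes.
    Defaults are tuned so the mean decision time is near 1 s when the
    option values are far apart, growing as they approach each other.
    """

    w_excite: float = 3.0
    w_inhib: float = 2.5
    input_gain: float = 4.0
    leak: float = 3.0
    noise_sd: float = 0.8
    threshold: float = 6.0
    baseline: float = 1.0
    regime: str = "decay"
    dt: float = 0.005
    max_decision_time: float = 4.0
    trial_duration: float = 8.0

    def __post_init__(self) -> None:
        if self.threshold <= self.baseline:
            raise ValueError("threshold must exceed baseline")
        if self.regime not in ("decay", "sustain"):
            raise ValueError(f"regime must be 'decay' or 'sustain', got {self.regime!r}")
        if min(self.w_excite, self.w_inhib, self.input_gain, self.leak) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class AttractorResult:
    """Batch of simulated attractor trials."""

    choices: np.ndarray  # 0 = first option, 1 = second
    decision_times: np.ndarray  # seconds; nan when undecided
    traces: np.ndarray  # (n_trials, n_steps) aggregate activity above baseline
    dt: float
    undecided: np.ndarray  # bool mask


def simulate_attractor_trials(
    network: NetworkParams,
    v_a: np.ndarray,
    v_b: np.ndarray,
    rng: np.random.Generator | None = None,
) -> AttractorResult:
    """Vectorized simulation of many independent attractor trials.

    Returns per-trial choices, threshold-crossing times and the summed
    (both-pool) activity traces relative to baseline.  Exact ties at the
    threshold are broken by a seeded coin flip.
    """
    if rng is None:
        rng = np.random.default_rng()
    v_a = np.atleast_1d(np.asarray(v_a, dtype=float))
    v_b = np.atleast_1d(np.asarray(v_b, dtype=float))
    if v_a.shape != v_b.shape or not (np.isfinite(v_a).all() and np.isfinite(v_b).all()):
        raise ValueError("option values must be finite arrays of equal shape")
    n = v_a.size
    p = network
    n_steps = int(round(p.trial_duration / p.dt))
    max_dec_step = int(round(p.max_decision_time / p.dt))

    x = np.full(n, p.baseline)
    y = np.full(n, p.baseline)
    choices = np.full(n, -1, dtype=int)
    dec_step = np.full(n, -1, dtype=int)
    traces = np.zeros((n, n_steps))
    sqrt_dt = np.sqrt(p.dt)

    for step in range(n_steps):
        racing = dec_step < 0
        if racing.any() and step < max_dec_step:
            xb, yb = x - p.baseline, y - p.baseline
            dx = (-p.leak * xb + p.w_excite * xb - p.w_inhib * yb + p.input_gain * v_a) * p.dt
            dy = (-p.leak * yb + p.w_excite * yb - p.w_inhib * xb + p.input_gain * v_b) * p.dt
            if p.noise_sd > 0:
                dx = dx + p.noise_sd * sqrt_dt * rng.standard_normal(n)
                dy = dy + p.noise_sd * sqrt_dt * rng.standard_normal(n)
            x = np.where(racing, np.maximum(x + dx, 0.0), x)
            y = np.where(racing, np.maximum(y + dy, 0.0), y)

            crossed_x = racing & (x >= p.threshold)
            crossed_y = racing & (y >= p.threshold)
            tie = crossed_x & crossed_y
            if tie.any():
                flip = rng.integers(0, 2, size=n).astype(bool)
                crossed_x = crossed_x & ~(tie & flip)
                crossed_y = crossed_y & ~(tie & ~flip)
            newly = crossed_x | crossed_y
            choices[newly] = np.where(crossed_x[newly], 0, 1)
            dec_step[newly] = step
        # post-decision dynamics
        decided = dec_step >= 0
        if decided.any():
            just = dec_step == step
            relax = decided & ~just
            if relax.any():
                winner_x = choices == 0
                if p.regime == "decay":
                    x = np.where(relax, x + (-p.leak * (x - p.baseline)) * p.dt, x)
                    y = np.where(relax, y + (-p.leak * (y - p.baseline)) * p.dt, y)
                else:  # sustain: winner holds its attractor, loser relaxes
                    x = np.where(relax & winner_x, p.threshold,
                                 np.where(relax, x + (-p.leak * (x - p.baseline)) * p.dt, x))
                    y = np.where(relax & ~winner_x, p.threshold,
                                 np.where(relax, y + (-p.leak * (y - p.baseline)) * p.dt, y))
        traces[:, step] = (x - p.baseline) + (y - p.baseline)

    undecided = dec_step < 0
    times = np.where(undecided, np.nan, dec_step * p.dt)
    return AttractorResult(choices=choices, decision_times=times, traces=traces,
                           dt=p.dt, undecided=undecided)


def simulate_attractor_trial(network: NetworkParams, v_left: float, v_right: float,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[int, float, np.ndarray]:
    """Single trial: returns (choice, decision time, aggregate trace)."""
    res = simulate_attractor_trials(network, np.array([v_left]), np.array([v_right]), rng)
    return int(res.choices[0]), float(res.decision_times[0]), res.traces[0]


def write_bold_tsv(series: BoldSeries, path) -> None:
    """Write a single time series as a (time, signal) TSV."""
    series.to_frame().to_csv(path, sep="\t", index=False)


def write_hrf_csv(params: HRFParams, path) -> None:
    """Export the discretized kernel as a (time_s, weight) CSV."""
    kernel = gamma_hrf(params)
    t = (np.arange(kernel.size) + 0.5) * params.dt
    pd.DataFrame({"time_s": t, "weight": kernel}).to_csv(path, index=False)


def write_grid_nifti(grid: np.ndarray, tr: float, path,
                     voxel_size_mm: float = 1.5) -> None:
    """Write a 4-D voxel grid as NIfTI with the TR in the header."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + (tr,))
    nib.save(img, str(path))


def attractor_trial_amplitudes(result: AttractorResult,
                               window: float | None = None) -> np.ndarray:
    """Integrated aggregate activity per trial (signal units x seconds).

    ``window`` limits the integral to the first ``window`` seconds of
    each trial (e.g. the pre-outcome period); default integrates the
    whole trial.
    """
    traces = result.traces
    if window is not None:
        traces = traces[:, : int(round(window / result.dt))]
    return traces.sum(axis=1) * result.dt
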