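"""Traveling-wave analysis of digit-cycling functional runs.

A run cycles through the digits in fixed-length blocks. Each voxel's response
lag across the cycle is recovered by correlating its time series against a
bank of circularly lag-shifted reference regressors (a gamma-convolved
boxcar), yielding a tuning profile in r-values; a sinusoid fitted to that
profile gives per-voxel amplitude and period maps, from which an
FDR-thresholded ROI and the scalar tuning metric (inverse mean period) are
derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TaskDesign",
    "TuningProfile",
    "SinusoidFit",
    "TuningMaps",
    "ROIMask",
    "gamma_hrf",
    "build_reference_model",
    "default_lag_grid",
    "compute_tuning_profile",
    "fit_sinusoid",
    "fit_sinusoid_map",
    "combine_runs",
    "define_roi",
    "tuning_metric",
    "press_metrics",
]

#: internal fine time grid (s) on which boxcars are built before HRF
#: convolution and TR sampling, so cycle_s need not divide by TR
FINE_DT = 0.1


@dataclass(frozen=True)
class TaskDesign:
    """Timing of the digit-movement cycle and scanner sampling."""

    tr: float
    block_s: float
    n_cycles: int
    digits: tuple[int, ...] = (2, 3, 4, 5)
    direction: Literal["forward", "backward"] = "forward"

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.block_s <= 0 or self.n_cycles < 1:
            raise ValueError("tr, block_s must be > 0 and n_cycles >= 1")
        if len(self.digits) < 2:
            raise ValueError("need at least two digits")

    @property
    def cycle_s(self) -> float:
        return self.block_s * len(self.digits)

    @property
    def run_s(self) -> float:
        return self.cycle_s * self.n_cycles

    @property
    def n_volumes(self) -> int:
        """Volumes acquired within the run.

        cycle_s need not be a multiple of TR (regressors are built on a
        fine grid and sampled at TR); a trailing partial TR is simply not
        acquired. The 32 s cycle x 8 at TR 1.5 s gives 170 volumes.
        """
        if self.tr / FINE_DT != round(self.tr / FINE_DT):
            raise ValueError(
                f"TR {self.tr} s is not a multiple of the {FINE_DT} s fine "
                "grid; no finer resampling policy is defined"
            )
        return int(np.floor(self.run_s / self.tr + 1e-9))

    @property
    def ordered_digits(self) -> tuple[int, ...]:
        """Digit order as presented, honoring run direction."""
        if self.direction == "backward":
            return tuple(reversed(self.digits))
        return self.digits

    def cue_schedule(self) -> list[dict]:
        """Block onsets: one entry per digit block over the whole run."""
        sched = []
        t = 0.0
        for _ in range(self.n_cycles):
            for d in self.ordered_digits:
                sched.append({"onset_s": round(t, 6), "digit": int(d),
                              "duration_s": self.block_s})
                t += self.block_s
        return sched


@dataclass
class TuningProfile:
    """Lag-correlation curve of one voxel across the movement cycle."""

    lags: np.ndarray
    r: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.lags.shape != self.r.shape:
            raise ValueError("lags and r must have the same shape")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class SinusoidFit:
    """y = a*sin(omega*x - phi) + B fitted to a tuning profile."""

    a: float
    omega: float
    phi: float
    offset: float
    rss: float
    converged: bool

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.sin(self.omega * np.asarray(x) - self.phi) + self.offset


@dataclass
class TuningMaps:
    """Per-voxel amplitude / period / phase maps plus a converged mask."""

    amplitude: np.ndarray
    period: np.ndarray
    phase: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        shp = self.amplitude.shape
        for arr in (self.period, self.phase, self.converged):
            if arr.shape != shp:
                raise ValueError("all maps must share one spatial shape")


@dataclass
class ROIMask:
    mask: np.ndarray
    alpha: float

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def gamma_hrf(t: np.ndarray, shape: float = 6.0, scale: float = 0.9) -> np.ndarray:
    """Gamma-density hemodynamic response kernel (no undershoot)."""
    t = np.asarray(t, dtype=float)
    return stats.gamma.pdf(t, a=shape, scale=scale)


def _cycle_boxcar_fine(design: TaskDesign, lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Full-run boxcar on the fine grid, circularly shifted by ``lag``.

    'On' covers one block per cycle starting at ``lag`` (wrapping at the
    cycle boundary).
    """
    n_fine = int(round(design.run_s / FINE_DT))
    t = np.arange(n_fine) * FINE_DT
    phase = (t - lag) % design.cycle_s
    return t, (phase < design.block_s).astype(float)


def build_reference_model(
    design: TaskDesign,
    lag: float,
    hrf_shape: float = 6.0,
    hrf_scale: float = 0.9,
) -> np.ndarray:
    """Lag-shifted gamma-convolved boxcar sampled at TR, unit-variance.

    The boxcar is block_s 'on' and cycle_s - block_s 'off', repeated
    n_cycles times, circularly shifted by ``lag`` seconds within the cycle.
    """
    if not (0.0 <= lag < design.cycle_s):
        raise ValueError(f"lag must lie in [0, {design.cycle_s}), got {lag}")
    _, box = _cycle_boxcar_fine(design, lag)
    # circular convolution: the run is periodic in the cycle, so wrap the
    # HRF tail instead of truncating the first cycle
    hrf_t = np.arange(0.0, 32.0, FINE_DT)
    kernel = gamma_hrf(hrf_t, hrf_shape, hrf_scale)
    kernel = kernel / kernel.sum()
    n = box.size
    padded = np.concatenate([box[-kernel.size + 1:] if kernel.size > 1 else box[:0], box])
    conv = np.convolve(padded, kernel, mode="valid")[:n]
    tr_idx = np.round(np.arange(design.n_volumes) * design.tr / FINE_DT).astype(int)
    sampled = conv[tr_idx]
    sd = sampled.std()
    if sd == 0:
        raise ValueError("degenerate reference model (zero variance)")
    return (sampled - sampled.mean()) / sd


def default_lag_grid(design: TaskDesign, step: float | None = None) -> np.ndarray:
    """Lag grid covering [0, cycle_s); default step = TR."""
    step = design.tr if step is None else step
    return np.arange(0.0, design.cycle_s - 1e-9, step)


def compute_tuning_profile(
    ts: np.ndarray,
    design: TaskDesign,
    lag_grid: Sequence[float] | None = None,
    models: np.ndarray | None = None,
) -> TuningProfile:
    """Pearson-correlate a voxel time series against each lagged model.

    ``models`` may pass a precomputed (n_lags, n_volumes) regressor bank to
    amortize model construction across voxels.
    """
    ts = np.asarray(ts, dtype=float)
    lags = default_lag_grid(design) if lag_grid is None else np.asarray(lag_grid, float)
    if ts.size != design.n_volumes:
        raise ValueError(
            f"time series has {ts.size} volumes, design implies {design.n_volumes}"
        )
    if models is None:
        models = np.stack([build_reference_model(design, lag) for lag in lags])
    sd = ts.std()
    if sd == 0 or not np.isfinite(sd):
        return TuningProfile(lags=lags, r=np.full(lags.shape, np.nan), valid=False)
    z = (ts - ts.mean()) / sd
    # models are already zero-mean unit-variance
    r = models @ z / ts.size
    return TuningProfile(lags=lags, r=np.clip(r, -1.0, 1.0))


def _sine_linear_lsq(x: np.ndarray, y: np.ndarray, omega: float) -> tuple[float, float, float, float]:
    """Best (a, phi, B) for fixed omega via the linear parameterization
    a*sin(wx - phi) + B = p*sin(wx) + q*cos(wx) + B."""
    design_mat = np.column_stack([np.sin(omega * x), np.cos(omega * x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design_mat, y, rcond=None)
    p, q, b = coef
    a = float(np.hypot(p, q))
    phi = float(np.arctan2(-q, p))
    resid = y - design_mat @ coef
    return a, phi, b, float(resid @ resid)


def fit_sinusoid(
    profile: TuningProfile,
    n_period_starts: int = 48,
    cycle_s: float | None = None,
) -> SinusoidFit:
    """Least-squares sinusoid fit to a tuning profile.

    Searches a dense period grid (each candidate solved exactly for
    amplitude/phase/offset, which are linear given the frequency), then
    refines all four parameters with bounded nonlinear least squares.
    Period is constrained to [2*lag_step, 2*lag_span].

    A tuning profile is periodic on the movement cycle, so when ``cycle_s``
    is given the lag axis is re-centered modulo the cycle to put the
    profile peak mid-axis before fitting; profiles peaking near the cycle
    boundary would otherwise present a split bump that biases the period
    long. The fitted phase is mapped back to the original axis (exact when
    the fitted period divides the cycle, approximate otherwise).
    """
    x, y = profile.lags, profile.r
    if x.size < 8:
        raise ValueError("need at least 8 lag points")
    if not profile.valid or not np.all(np.isfinite(y)):
        return SinusoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
    shift_s = 0.0
    if cycle_s is not None:
        shift_s = float(x[np.argmax(y)]) - 0.5 * cycle_s
        x_new = np.mod(x - shift_s, cycle_s)
        order = np.argsort(x_new, kind="stable")
        x, y = x_new[order], y[order]
        dup = np.diff(x) <= 1e-12
        if np.any(dup):  # merge coincident wrapped samples
            keep = np.concatenate([[True], ~dup])
            x, y = x[keep], y[keep]
    step = float(np.min(np.diff(x)))
    span = float(x[-1] - x[0] + step)
    p_min, p_max = 2.0 * step, 2.0 * span
    if np.ptp(y) < 1e-12:  # degenerate flat profile
        return SinusoidFit(0.0, 2 * np.pi / span, 0.0, float(y.mean()), 0.0,
                           converged=False)
    periods = np.geomspace(p_min, p_max, n_period_starts)
    best = None
    for period in periods:
        w = 2 * np.pi / period
        a, phi, b, rss = _sine_linear_lsq(x, y, w)
        if best is None or rss < best[0]:
            best = (rss, a, w, phi, b)
    _, a0, w0, phi0, b0 = best

    def resid(theta):
        a, w, phi, b = theta
        return a * np.sin(w * x - phi) + b - y

    w_lo, w_hi = 2 * np.pi / p_max, 2 * np.pi / p_min
    try:
        sol = optimize.least_squares(
            resid,
            x0=[a0, np.clip(w0, w_lo, w_hi), phi0, b0],
            bounds=([0.0, w_lo, -2 * np.pi, -np.inf], [np.inf, w_hi, 2 * np.pi, np.inf]),
        )
        ok = sol.success
        a, w, phi, b = sol.x
        rss = float(2 * sol.cost)
    except Exception:
        ok = False
        a, w, phi, b, rss = a0, w0, phi0, b0, best[0]
    if not ok or best[0] < rss:  # keep grid candidate if refinement regressed
        a, w, phi, b, rss = a0, w0, phi0, b0, best[0]
        ok = True
    # recentred axis x' = (x - shift) mod cycle, so on the original axis
    # y(x) = a*sin(w*(x - shift) - phi') and phi_original = phi' + w*shift
    phi = float(np.mod(phi + w * shift_s + np.pi, 2 * np.pi) - np.pi)
    return SinusoidFit(float(a), float(w), phi, float(b), float(rss), converged=bool(ok))


def fit_sinusoid_map(
    profiles_r: np.ndarray,
    lags: np.ndarray,
    valid: np.ndarray | None = None,
    cycle_s: float | None = None,
) -> TuningMaps:
    """Fit every voxel of an (..., n_lags) profile stack."""
    spatial = profiles_r.shape[:-1]
    flat = profiles_r.reshape(-1, profiles_r.shape[-1])
    vflat = (np.ones(flat.shape[0], bool) if valid is None
             else np.asarray(valid, bool).reshape(-1))
    amp = np.full(flat.shape[0], np.nan)
    per = np.full(flat.shape[0], np.nan)
    pha = np.full(flat.shape[0], np.nan)
    conv = np.zeros(flat.shape[0], bool)
    for i in range(flat.shape[0]):
        fit = fit_sinusoid(TuningProfile(lags=lags, r=flat[i], valid=bool(vflat[i])),
                           cycle_s=cycle_s)
        if fit.converged:
            amp[i], per[i], pha[i], conv[i] = fit.a, fit.period, fit.phi, True
    return TuningMaps(
        amplitude=amp.reshape(spatial),
        period=per.reshape(spatial),
        phase=pha.reshape(spatial),
        converged=conv.reshape(spatial),
    )


def combine_runs(forward: TuningMaps, backward: TuningMaps) -> TuningMaps:
    """Voxel-wise mean of amplitude and period across run directions.

    Only voxels with converged fits in both directions survive; phase is
    taken from the forward run (directions disagree on phase by design).
    """
    if forward.amplitude.shape != backward.amplitude.shape:
        raise ValueError("forward/backward maps have different shapes")
    both = forward.converged & backward.converged
    amp = np.where(both, 0.5 * (forward.amplitude + backward.amplitude), np.nan)
    per = np.where(both, 0.5 * (forward.period + backward.period), np.nan)
    pha = np.where(both, forward.phase, np.nan)
    return TuningMaps(amplitude=amp, period=per, phase=pha, converged=both)


def define_roi(
    amplitude_map: np.ndarray,
    n_timepoints: int,
    alpha: float = 0.01,
) -> ROIMask:
    """FDR-threshold an r-scale amplitude map into an ROI.

    Fisher z-transform, standardize by sqrt(n-3), two-sided normal p per
    voxel, Benjamini-Hochberg at ``alpha``.
    """
    if n_timepoints <= 3:
        raise ValueError("need n_timepoints > 3")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    amp = np.asarray(amplitude_map, dtype=float)
    finite = np.isfinite(amp)
    mask = np.zeros(amp.shape, dtype=bool)
    if finite.any():
        r = np.clip(amp[finite], -1 + 1e-15, 1 - 1e-15)
        z = np.arctanh(r) * np.sqrt(n_timepoints - 3)
        p = 2.0 * stats.norm.sf(np.abs(z))
        reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        mask[finite] = reject
    return ROIMask(mask=mask, alpha=alpha)


def tuning_metric(
    period_map: np.ndarray,
    roi: ROIMask,
    aggregation: Literal["inverse_of_mean", "mean_of_inverse"] = "inverse_of_mean",
) -> float:
    """Scalar cortical tuning metric (1/s) over the ROI.

    Default: 1 / mean(period over ROI). ``mean_of_inverse`` averages the
    per-voxel inverse periods instead.
    """
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    periods = np.asarray(period_map, dtype=float)[roi.mask]
    if not np.all(np.isfinite(periods)):
        raise ValueError("ROI contains voxels without a converged period")
    if aggregation == "inverse_of_mean":
        return float(1.0 / periods.mean())
    if aggregation == "mean_of_inverse":
        return float(np.mean(1.0 / periods))
    raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass
class PressMetrics:
    rate_hz: float
    mean_interval_s: float
    accuracy: float
    n_intervals_used: int
    n_intervals_excluded: int
    valid: bool = True


def press_metrics(
    press_times: Sequence[float],
    cue_times: Sequence[float],
    window_s: float = 0.4,
) -> PressMetrics:
    """Button-press rate and accuracy for one run.

    Rate is the inverse of the mean inter-press interval after excluding
    intervals beyond +/- 2 SD of the interval mean. Accuracy is the fraction
    of cues with a press beginning within ``window_s`` (strict) of the cue.
    """
    presses = np.sort(np.asarray(press_times, dtype=float))
    cues = np.asarray(cue_times, dtype=float)
    if cues.size == 0:
        raise ValueError("no cues supplied")
    if presses.size == 0:
        return PressMetrics(np.nan, np.nan, 0.0, 0, 0, valid=False)
    hits = 0
    for c in cues:
        d = presses - c
        d = d[d >= 0]
        if d.size and d.min() <= window_s:
            hits += 1
    accuracy = hits / cues.size
    ivals = np.diff(presses)
    if ivals.size < 2:
        return PressMetrics(np.nan, np.nan, accuracy, 0, 0, valid=False)
    mu, sd = ivals.mean(), ivals.std(ddof=1)
    keep = np.abs(ivals - mu) <= 2 * sd
    used = ivals[keep]
    mean_ival = float(used.mean())
    return PressMetrics(
        rate_hz=1.0 / mean_ival,
        mean_interval_s=mean_ival,
        accuracy=float(accuracy),
        n_intervals_used=int(keep.sum()),
        n_intervals_excluded=int((~keep).sum()),
    )
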