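"""Synthetic ground-truth generators for every raw-data stream.

Three simulators feed the downstream stages: digit-tuned voxel grids
producing 4D functional runs (wrapped-Gaussian tuning, gamma HRF, optional
AR(1) noise), a lapse-capable logistic temporal-order-judgment observer,
and a structural-equation cohort generator (M = a*X + e_M,
Y = c'*X + b*M + e_Y) with an optional raw-data mode that realizes each
subject's latent tuning and acuity as simulator parameters. A metabolite
table generator with controllable QC failures exercises the spectroscopy
exclusion rules. Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .travelwave import FINE_DT, TaskDesign, gamma_hrf

__all__ = [
    "SimGrid",
    "TOJObserver",
    "CohortTruth",
    "PAPER_ISIS_MS",
    "simulate_fmri_run",
    "simulate_toj_trials",
    "simulate_cohort",
    "cohort_implied_covariance",
    "tuning_to_width",
    "jnd_truth_to_slope",
    "simulate_mrs_table",
]

#: signed interstimulus intervals used in the behavioural task (ms)
PAPER_ISIS_MS = (350, -350, 250, -250, 150, -150, 100, -100, 60, -60, 30, -30)

LN3 = float(np.log(3.0))


@dataclass
class SimGrid:
    """Ground-truth voxel grid for functional-run simulation."""

    shape: tuple[int, ...]
    preferred_digit: np.ndarray
    tuning_width: np.ndarray
    amplitude: np.ndarray
    noise_sd: np.ndarray
    noise_ar1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("preferred_digit", "tuning_width", "amplitude", "noise_sd"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} shape {arr.shape} != grid {self.shape}")
            setattr(self, name, arr)
        if not np.all(np.isin(self.preferred_digit, (2, 3, 4, 5))):
            raise ValueError("preferred_digit must lie in {2, 3, 4, 5}")
        if np.any(self.tuning_width <= 0):
            raise ValueError("tuning_width must be > 0")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.noise_ar1 < 1.0):
            raise ValueError("noise_ar1 must be in [0, 1)")

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, ...],
        tuning_width: float = 1.0,
        amplitude: float = 1.0,
        noise_sd: float = 0.5,
        noise_ar1: float = 0.0,
        seed: int = 0,
    ) -> "SimGrid":
        """Grid with homogeneous widths and randomly assigned digits."""
        rng = np.random.default_rng(seed)
        n = int(np.prod(shape))
        return cls(
            shape=tuple(shape),
            preferred_digit=rng.choice((2, 3, 4, 5), size=n).reshape(shape),
            tuning_width=np.full(shape, float(tuning_width)),
            amplitude=np.full(shape, float(amplitude)),
            noise_sd=np.full(shape, float(noise_sd)),
            noise_ar1=noise_ar1,
        )


@dataclass(frozen=True)
class TOJObserver:
    """Logistic temporal-order-judgment observer.

    Lapse-free, the true JND equals slope * ln(3). A symmetric lapse rate
    compresses the response range to [lapse/2, 1 - lapse/2].
    """

    mu: float = 0.0
    slope: float = 50.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must be in [0, 0.1]")

    def p_first(self, isi_ms: np.ndarray) -> np.ndarray:
        z = (np.asarray(isi_ms, float) - self.mu) / self.slope
        return self.lapse / 2.0 + (1.0 - self.lapse) * expit(z)

    @property
    def true_jnd(self) -> float:
        return self.slope * LN3


@dataclass(frozen=True)
class CohortTruth:
    """Structural-equation ground truth for a metric-level cohort:
    M = a*X + e_M, Y = c'*X + b*M + e_Y with X ~ N(0, 1)."""

    n_subjects: int
    path_a: float
    path_b: float
    path_c_prime: float
    noise_sd_m: float = 0.5
    noise_sd_y: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need n_subjects >= 4")


def _wrapped_gaussian_weight(
    digit_idx: np.ndarray, preferred_idx: np.ndarray, width: np.ndarray, n_digits: int
) -> np.ndarray:
    """Tuning weight on the circular digit axis, peak 1 at the preferred digit."""
    d = np.abs(digit_idx - preferred_idx)
    d = np.minimum(d, n_digits - d)  # circular distance
    # sum over wraps is unnecessary at these widths; a single Gaussian on
    # the circular distance matches the downstream sinusoid model
    return np.exp(-0.5 * (d / width) ** 2)


def simulate_fmri_run(
    grid: SimGrid,
    design: TaskDesign,
    direction: str | None = None,
    seed: int = 0,
    hrf_shape: float = 6.0,
    hrf_scale: float = 0.9,
) -> tuple[np.ndarray, list[dict]]:
    """Simulate one 4D functional run from a ground-truth grid.

    Each voxel's noiseless signal is the HRF-convolved block indicator
    weighted by a wrapped-Gaussian tuning function of circular digit
    distance from the voxel's preferred digit, scaled by its amplitude.
    Gaussian AR(1) noise is added per voxel. Returns the (*grid.shape,
    n_volumes) array and the cue schedule. Backward runs reverse the digit
    order within the cycle.
    """
    if direction is not None and direction != design.direction:
        design = TaskDesign(tr=design.tr, block_s=design.block_s,
                            n_cycles=design.n_cycles, digits=design.digits,
                            direction=direction)
    n_vol = design.n_volumes  # raises on non-commensurate TR
    schedule = design.cue_schedule()
    digits = design.digits
    n_digits = len(digits)
    digit_to_idx = {d: i for i, d in enumerate(digits)}

    n_fine = int(round(design.run_s / FINE_DT))
    t_fine = np.arange(n_fine) * FINE_DT
    # per-digit block indicator on the fine grid
    indicators = np.zeros((n_digits, n_fine))
    for blk in schedule:
        on = (t_fine >= blk["onset_s"]) & (t_fine < blk["onset_s"] + blk["duration_s"])
        indicators[digit_to_idx[blk["digit"]], on] = 1.0

    kernel = gamma_hrf(np.arange(0.0, 32.0, FINE_DT), hrf_shape, hrf_scale)
    kernel /= kernel.sum()
    pad = np.concatenate([indicators[:, -kernel.size + 1:], indicators], axis=1)
    conv = np.stack(
        [np.convolve(pad[i], kernel, mode="valid")[:n_fine] for i in range(n_digits)]
    )
    tr_idx = np.round(np.arange(n_vol) * design.tr / FINE_DT).astype(int)
    regressors = conv[:, tr_idx]  # (n_digits, n_vol)

    n_vox = int(np.prod(grid.shape))
    pref_idx = np.vectorize(digit_to_idx.get)(grid.preferred_digit.reshape(-1))
    weights = _wrapped_gaussian_weight(
        np.arange(n_digits)[None, :], pref_idx[:, None],
        grid.tuning_width.reshape(-1, 1), n_digits,
    )  # (n_vox, n_digits)
    signal = grid.amplitude.reshape(-1, 1) * (weights @ regressors)

    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_vox, n_vol))
    rho = grid.noise_ar1
    if rho > 0:
        noise = np.empty_like(eps)
        scale = np.sqrt(1.0 - rho**2)
        noise[:, 0] = eps[:, 0]
        for t in range(1, n_vol):
            noise[:, t] = rho * noise[:, t - 1] + scale * eps[:, t]
    else:
        noise = eps
    data = signal + grid.noise_sd.reshape(-1, 1) * noise
    return data.reshape(*grid.shape, n_vol), schedule


def simulate_toj_trials(
    observer: TOJObserver,
    isis: tuple[float, ...] = PAPER_ISIS_MS,
    trials_per_isi: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli trial table for a logistic observer.

    Columns: ``isi_ms``, ``response`` (1 = 'first'); length
    len(isis) * trials_per_isi.
    """
    isis = tuple(isis)
    if len(isis) == 0:
        raise ValueError("isis must be non-empty")
    if trials_per_isi < 1:
        raise ValueError("trials_per_isi must be >= 1")
    rng = np.random.default_rng(seed)
    isi_col = np.repeat(np.asarray(isis, float), trials_per_isi)
    p = observer.p_first(isi_col)
    resp = (rng.random(isi_col.size) < p).astype(int)
    return pd.DataFrame({"isi_ms": isi_col, "response": resp})


def cohort_implied_covariance(truth: CohortTruth) -> np.ndarray:
    """Closed-form covariance of (X, M, Y) under the structural equations."""
    a, b, cp = truth.path_a, truth.path_b, truth.path_c_prime
    sm2, sy2 = truth.noise_sd_m**2, truth.noise_sd_y**2
    var_x = 1.0
    var_m = a**2 + sm2
    cov_xm = a
    cov_xy = cp + b * a
    cov_my = cp * a + b * var_m
    var_y = cp**2 + b**2 * var_m + 2 * cp * b * a + sy2
    return np.array([
        [var_x, cov_xm, cov_xy],
        [cov_xm, var_m, cov_my],
        [cov_xy, cov_my, var_y],
    ])


def simulate_cohort(truth: CohortTruth) -> pd.DataFrame:
    """Metric-level subject table (gaba_cr, tuning, jnd) from the
    structural equations, standardized-latent scale."""
    rng = np.random.default_rng(truth.seed)
    x = rng.standard_normal(truth.n_subjects)
    m = truth.path_a * x + truth.noise_sd_m * rng.standard_normal(truth.n_subjects)
    y = (truth.path_c_prime * x + truth.path_b * m
         + truth.noise_sd_y * rng.standard_normal(truth.n_subjects))
    return pd.DataFrame({
        "subject": [f"S{i:03d}" for i in range(truth.n_subjects)],
        "gaba_cr": x,
        "tuning": m,
        "jnd": y,
    })


def tuning_to_width(tuning_latent: np.ndarray, width_mid: float = 1.2,
                    spread: float = 0.35) -> np.ndarray:
    """Monotone link from a latent tuning value to a SimGrid tuning width.

    Higher latent tuning -> sharper (smaller) width; log-linear so widths
    stay positive. Calibrated once so latent values in [-2, 2] span roughly
    [0.6, 2.4] digits of width.
    """
    return width_mid * np.exp(-spread * np.asarray(tuning_latent, float))


def jnd_truth_to_slope(jnd_latent: np.ndarray, jnd_mid_ms: float = 70.0,
                       spread: float = 0.5) -> np.ndarray:
    """Monotone link from a latent acuity value to an observer slope (ms).

    Higher latent value -> larger JND (worse acuity); the observer's true
    JND is slope * ln 3 = jnd_mid_ms * exp(spread * latent).
    """
    return jnd_mid_ms * np.exp(spread * np.asarray(jnd_latent, float)) / LN3


def simulate_mrs_table(
    n: int,
    qc_fail_fraction: float = 0.0,
    seed: int = 0,
    gaba_mean: float = 1.4,
    glu_mean: float = 9.0,
    cr_mean: float = 4.5,
    pcr_mean: float = 3.5,
) -> pd.DataFrame:
    """Metabolite table with a controlled fraction of QC failures.

    One voxel per subject index; rows are (subject, metabolite) with
    absolute estimates, QC fields and simplex tissue fractions. Exactly
    round(n * qc_fail_fraction) subjects get at least one QC-violating row.
    """
    if not (0.0 <= qc_fail_fraction <= 1.0):
        raise ValueError("qc_fail_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fail = int(round(n * qc_fail_fraction))
    fail_subjects = set(rng.choice(n, size=n_fail, replace=False).tolist())
    rows = []
    means = {"GABA": gaba_mean, "Glu": glu_mean, "Cr": cr_mean, "PCr": pcr_mean}
    for i in range(n):
        tissue = rng.dirichlet((8.0, 6.0, 1.0))  # gm, wm, csf
        tissue = tissue / tissue.sum()
        fail_mode = rng.integers(3) if i in fail_subjects else -1
        for j, (met, mean) in enumerate(means.items()):
            crlb = float(rng.uniform(3, 20))
            fwhm = float(rng.uniform(8, 12))
            snr = float(rng.uniform(45, 80))
            if i in fail_subjects and j == 0:
                if fail_mode == 0:
                    crlb = float(rng.uniform(51, 120))
                elif fail_mode == 1:
                    fwhm = float(rng.uniform(15.5, 25))
                else:
                    snr = float(rng.uniform(5, 39))
            rows.append({
                "subject": f"S{i:03d}",
                "metabolite": met,
                "absolute": float(mean * rng.lognormal(0.0, 0.08)),
                "crlb": crlb,
                "fwhm_hz": fwhm,
                "snr": snr,
                "gm": float(tissue[0]),
                "wm": float(tissue[1]),
                "csf": float(tissue[2]),
            })
    return pd.DataFrame(rows)
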