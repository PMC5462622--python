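"""Inferential layer: correlations, dependent-correlation comparison,
conjunction/omnibus compound test, bootstrap mediation, and ICC(A,1).

All Pearson and Sobel p-values are two-tailed. The dependent-correlation
comparison reports both tail conventions because published usage mixes
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "DependentCorrComparison",
    "ConjunctionOmnibusResult",
    "MediationResult",
    "ICCResult",
    "pearson_with_p",
    "pearson_p_from_r",
    "hittner_test",
    "partial_correlation",
    "conjunction_omnibus",
    "mediate",
    "kappa_squared",
    "icc_a1",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float

    @property
    def fisher_z(self) -> float:
        return float(np.arctanh(self.r))


@dataclass(frozen=True)
class DependentCorrComparison:
    """Comparison of two overlapping correlations sharing one variable."""

    r_xy: float
    r_xz: float
    r_yz: float
    n: int
    z_stat: float
    p_one_tailed: float
    p_two_tailed: float


@dataclass(frozen=True)
class ConjunctionOmnibusResult:
    conjunction_statistic: float  # max of the predicted p-values
    omnibus_statistic: float      # min of the unpredicted p-values
    alpha: float
    reject_compound_null: bool


@dataclass(frozen=True)
class MediationResult:
    """Path decomposition X -> M -> Y with bootstrap inference."""

    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    boot_ci: tuple[float, float]
    p_m: float
    sobel_z: float
    sobel_p: float
    kappa2: float
    n: int
    n_boot: int
    seed: int
    warnings: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_sessions: int


# ---------------------------------------------------------------------------
# correlations


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n (t on n-2 df)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 < r < 1.0:
        return 0.0 if abs(r) == 1.0 else float("nan")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with its two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, n=n, p_two_tailed=pearson_p_from_r(r, n))


def _check_psd_triple(r_xy: float, r_xz: float, r_yz: float) -> None:
    m = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")


def hittner_test(
    r_xy: float, r_xz: float, r_yz: float, n: int
) -> DependentCorrComparison:
    """Compare two dependent overlapping correlations r(X,Y) vs r(X,Z).

    Back-transformed-average-z modification (Hittner, May & Silver) of the
    Dunn & Clark statistic: the covariance term uses the back-transform of
    the mean Fisher z of the two compared correlations; the statistic is
    (z_xy - z_xz) * sqrt(n-3) / sqrt(2 - 2*c), referred to a standard
    normal. ``r_yz`` is the correlation of the two non-shared variables.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    _check_psd_triple(r_xy, r_xz, r_yz)
    z_xy, z_xz = np.arctanh(r_xy), np.arctanh(r_xz)
    r_bt = np.tanh(0.5 * (z_xy + z_xz))
    num = r_yz * (1 - 2 * r_bt**2) - 0.5 * r_bt**2 * (1 - 2 * r_bt**2 - r_yz**2)
    c = num / (1 - r_bt**2) ** 2
    z = (z_xy - z_xz) * np.sqrt(n - 3) / np.sqrt(2.0 - 2.0 * c)
    return DependentCorrComparison(
        r_xy=float(r_xy), r_xz=float(r_xz), r_yz=float(r_yz), n=n,
        z_stat=float(z),
        p_one_tailed=float(stats.norm.sf(abs(z))),
        p_two_tailed=float(2 * stats.norm.sf(abs(z))),
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> CorrelationResult:
    """First-order partial correlation of x and y given one covariate.

    p-value from t on n-3 df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(covariate, float)
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5")
    if z.std() == 0:
        raise ValueError("constant covariate")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if 1 - r_xz**2 < 1e-12:
        raise ValueError("covariate is collinear with x")
    if 1 - r_yz**2 < 1e-12:
        # y carries no variance beyond the covariate: partial r is 0
        return CorrelationResult(r=0.0, n=n, p_two_tailed=1.0)
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) < 1.0:
        t = r * np.sqrt(df) / np.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t), df=df))
    else:
        p = 0.0
    return CorrelationResult(r=r, n=n, p_two_tailed=p)


def conjunction_omnibus(
    predicted_ps, unpredicted_ps, alpha: float = 0.05
) -> ConjunctionOmnibusResult:
    """Compound test over predicted and unpredicted correlation p-values.

    The conjunction statistic is the maximum predicted p (all predicted
    effects must be significant); the omnibus statistic is the minimum
    unpredicted p (no unpredicted effect may be). The compound null is
    rejected iff max(predicted) < alpha and min(unpredicted) >= alpha.
    """
    pred = np.asarray(list(predicted_ps), float)
    unpred = np.asarray(list(unpredicted_ps), float)
    if pred.size == 0 or unpred.size == 0:
        raise ValueError("both p-value lists must be non-empty")
    for arr in (pred, unpred):
        if np.any((arr <= 0) | (arr > 1)):
            raise ValueError("p-values must lie in (0, 1]")
    conj = float(pred.max())
    omni = float(unpred.min())
    return ConjunctionOmnibusResult(
        conjunction_statistic=conj,
        omnibus_statistic=omni,
        alpha=alpha,
        reject_compound_null=bool(conj < alpha and omni >= alpha),
    )


# ---------------------------------------------------------------------------
# mediation


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and their standard errors for y ~ design (with icept)."""
    X = np.column_stack([np.ones(len(y)), design])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef[1:], np.sqrt(np.diag(cov))[1:]


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    (a,), (se_a,) = _ols(x[:, None], m)
    (cp, b), (_, se_b) = _ols(np.column_stack([x, m]), y)
    (c,), _ = _ols(x[:, None], y)
    return a, b, c, cp, se_a, se_b


def kappa_squared(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> float:
    """Preacher-Kelley kappa-squared mediation effect size.

    |a*b| relative to its maximum attainable magnitude |a_max * b_max|,
    where each path bound holds the other paths at their observed values
    and requires both structural error variances to stay non-negative
    given the observed variances of X, M, Y. Lies in [0, 1]; 0 when either
    observed path is 0.
    """
    x, m, y = (np.asarray(v, float) for v in (x, m, y))
    sx2, sm2, sy2 = x.var(ddof=1), m.var(ddof=1), y.var(ddof=1)
    a, b, _, cp, _, _ = _paths(x, m, y)
    if a == 0 or b == 0:
        return 0.0

    # permissible a with b, c' fixed:
    #   sigma_eM^2 = sm2 - a^2*sx2 >= 0            -> |a| <= sqrt(sm2/sx2)
    #   sigma_eY^2 = sy2 - cp^2*sx2 - b^2*sm2 - 2*a*b*cp*sx2 >= 0
    a_lo, a_hi = -np.sqrt(sm2 / sx2), np.sqrt(sm2 / sx2)
    lin = 2.0 * b * cp * sx2
    rhs = sy2 - cp**2 * sx2 - b**2 * sm2
    if lin > 0:
        a_hi = min(a_hi, rhs / lin)
    elif lin < 0:
        a_lo = max(a_lo, rhs / lin)
    a_max = a_hi if a > 0 else a_lo

    # permissible b with a, c' fixed: quadratic sigma_eY^2(b) >= 0
    disc = (a * cp * sx2) ** 2 - sm2 * (cp**2 * sx2 - sy2)
    if disc < 0:
        return float("nan")
    root = np.sqrt(disc)
    b_lo = (-a * cp * sx2 - root) / sm2
    b_hi = (-a * cp * sx2 + root) / sm2
    b_max = b_hi if b > 0 else b_lo

    denom = abs(a_max * b_max)
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(min(abs(a * b) / denom, 1.0))


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Simple mediation X -> M -> Y by OLS with percentile bootstrap.

    a from M~X; b and the direct effect c' from Y~X+M; total effect c from
    Y~X; indirect = a*b with a seeded case-resampling percentile CI;
    P_M = indirect / c_total; Sobel Z with two-tailed normal p; kappa^2 per
    the constrained-maximum construction.
    """
    x, m, y = (np.asarray(v, float) for v in (x, m, y))
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10")
    if n_boot < 1000:
        raise ValueError("need n_boot >= 1000")
    for v in (x, m, y):
        if v.std() == 0:
            raise ValueError("zero variance input")
    a, b, c, cp, se_a, se_b = _paths(x, m, y)
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        j = idx[i]
        ab_i = _paths(x[j], m[j], y[j])
        boot[i] = ab_i[0] * ab_i[1]
    lo, hi = np.percentile(boot, [100 * (1 - ci_level) / 2,
                                  100 * (1 + ci_level) / 2])

    warns = []
    p_m = indirect / c if c != 0 else np.nan
    if not np.isfinite(p_m) or abs(p_m) > 2.0:
        warns.append("total effect small relative to indirect: P_M is unstable")
    sobel_z = indirect / np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    sobel_p = float(2 * stats.norm.sf(abs(sobel_z)))
    return MediationResult(
        a=float(a), b=float(b), c_total=float(c), c_prime=float(cp),
        indirect=float(indirect), boot_ci=(float(lo), float(hi)),
        p_m=float(p_m), sobel_z=float(sobel_z), sobel_p=sobel_p,
        kappa2=kappa_squared(x, m, y), n=n, n_boot=n_boot, seed=seed,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# reproducibility


def icc_a1(measurements: np.ndarray, ci_level: float = 0.95) -> ICCResult:
    """Single-measures two-way random absolute-agreement ICC (McGraw-Wong
    ICC(A,1)) with the F-based confidence interval.

    ``measurements`` is a complete (n_subjects, n_sessions) array.
    """
    tbl = np.asarray(measurements, float)
    if tbl.ndim != 2:
        raise ValueError("expected a 2-D subjects x sessions table")
    n, k = tbl.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 sessions")
    if not np.all(np.isfinite(tbl)):
        raise ValueError("table must be complete")

    grand = tbl.mean()
    row_means = tbl.mean(axis=1)
    col_means = tbl.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((tbl - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong (1996) CI for ICC(A,1)
    alpha = 1 - ci_level
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_common = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f_l * mse) / (f_l * denom_common + n * msr)
        upper = n * (f_u * msr - mse) / (denom_common + n * f_u * msr)
    else:
        lower = upper = 1.0
    return ICCResult(icc=float(icc), ci_low=float(lower), ci_high=float(upper),
                     n_subjects=n, n_sessions=k)
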