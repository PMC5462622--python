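"""Temporal-order-judgment psychometrics: logistic fit and JND.

Trials record a signed interstimulus interval (positive ISI = the target
finger was stimulated first) and a binary judgment. Per-ISI proportions are
fitted with a two-parameter logistic by unweighted least squares; the just
noticeable difference (JND) is half the ISI span between the 25% and 75%
points of the fitted curve, which for this parameterization is
slope * ln(3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PsychometricFit",
    "aggregate_proportions",
    "fit_logistic",
    "compute_jnd",
    "fit_trials",
]

logger = logging.getLogger(__name__)

LN3 = float(np.log(3.0))

#: accepted response codes; "no_response" rows are dropped with a logged count
RESPONSE_FIRST = frozenset({"first", "middle-first", "right-first", 1, "1", True})
RESPONSE_SECOND = frozenset({"second", "index-first", "left-first", 0, "0", False})
RESPONSE_MISSING = frozenset({"no_response", "none", ""})


@dataclass
class PsychometricFit:
    """Fitted logistic psychometric function.

    mu is the point of subjective simultaneity (ms); slope the logistic
    scale (ms); jnd = slope * ln 3 (ms). ``accepted`` reflects the
    r-squared > 0.4 quality-of-fit rule.
    """

    mu: float
    slope: float
    r_squared: float
    n_trials: int

    @property
    def jnd(self) -> float:
        return compute_jnd(self)

    @property
    def accepted(self) -> bool:
        return bool(self.r_squared > 0.4)


def _logistic(isi: np.ndarray, mu: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(isi - mu) / slope))


def aggregate_proportions(
    trials: pd.DataFrame, expected_isis=None
) -> pd.DataFrame:
    """Per-ISI proportion of 'first' judgments.

    Expects columns ``isi_ms`` and ``response``. Returns a frame indexed by
    ISI with columns ``prop`` and ``n``. Unknown response codes raise;
    missing-response trials are dropped and counted in the log. If
    ``expected_isis`` is given, an ISI left with no scorable trial raises.
    """
    if not {"isi_ms", "response"}.issubset(trials.columns):
        raise ValueError("trial table needs columns 'isi_ms' and 'response'")
    resp = trials["response"]

    def code(v):
        key = v.strip().lower() if isinstance(v, str) else v
        if key in RESPONSE_FIRST:
            return 1.0
        if key in RESPONSE_SECOND:
            return 0.0
        if key in RESPONSE_MISSING or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        raise ValueError(f"unknown response code {v!r}")

    coded = resp.map(code)
    n_dropped = int(coded.isna().sum())
    if n_dropped:
        logger.info("dropping %d no-response trials", n_dropped)
    kept = trials.assign(_y=coded).dropna(subset=["_y"])
    if kept.empty:
        raise ValueError("no scorable trials")
    grouped = kept.groupby("isi_ms")["_y"].agg(prop="mean", n="count")
    if expected_isis is not None:
        empty = sorted(set(float(v) for v in expected_isis) - set(grouped.index))
        if empty:
            raise ValueError(f"no scorable trials at ISI(s) {empty}")
    return grouped.sort_index()


def fit_logistic(proportions: pd.DataFrame) -> PsychometricFit:
    """Unweighted least-squares logistic fit to per-ISI proportions.

    ``proportions`` is the output of :func:`aggregate_proportions`. Requires
    at least 4 distinct ISIs spanning both signs. All-0 or all-1 proportions
    are non-identifiable and raise.
    """
    isi = proportions.index.to_numpy(dtype=float)
    p = proportions["prop"].to_numpy(dtype=float)
    n_trials = int(proportions["n"].sum())
    if isi.size < 4 or isi.min() >= 0 or isi.max() <= 0:
        raise ValueError("need >= 4 distinct ISIs spanning both signs")
    if np.all(p == p[0]):
        raise ValueError("constant proportions: logistic is non-identifiable")

    span = isi.max() - isi.min()

    def loss(theta):
        return _logistic(isi, theta[0], theta[1]) - p

    best = None
    for s0 in (span / 20, span / 8, span / 3):
        try:
            sol = optimize.least_squares(
                loss, x0=[0.0, s0],
                bounds=([isi.min(), 1e-6], [isi.max(), 10 * span]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("logistic fit failed from all starts")
    mu, slope = best.x
    fitted = _logistic(isi, mu, slope)
    ss_res = float(np.sum((p - fitted) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PsychometricFit(mu=float(mu), slope=float(slope),
                           r_squared=float(np.clip(r2, 0.0, 1.0)),
                           n_trials=n_trials)


def compute_jnd(fit: PsychometricFit) -> float:
    """JND (ms): half the ISI span between the 75% and 25% fitted points.

    ISI_p = mu + slope*ln(p/(1-p)), so the JND reduces to slope*ln(3)
    exactly; mu cancels.
    """
    if not (fit.slope > 0):
        raise ValueError("fit has non-positive slope")
    isi75 = fit.mu + fit.slope * np.log(0.75 / 0.25)
    isi25 = fit.mu + fit.slope * np.log(0.25 / 0.75)
    return float((isi75 - isi25) / 2.0)


def fit_trials(trials: pd.DataFrame) -> PsychometricFit:
    """Convenience: aggregate a trial table and fit in one step."""
    return fit_logistic(aggregate_proportions(trials))
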