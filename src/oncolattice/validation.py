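"""Growth-law validation: Gompertz tumour growth, sigmoid vessel growth,
exponential branching, least-squares calibration and forecast-error metrics.

The three reference laws are

    n(t) = n0 * exp[(alpha/beta) * (1 - e^{-beta t})]      (tumour cells)
    g(t) = g0 + alpha / (1 + e^{-(t - t_half)/beta})       (vessel length)
    b(t) = b0 + alpha * e^{beta t}                         (branch points)

and a simulated time series is judged by fitting the law with multi-start
nonlinear least squares and reporting RMSE, MAD (mean absolute deviation of
the errors) and MAPE alongside the fitted parameters.  For the Gompertz law
the fitted rate alpha and shape beta are additionally flagged against the
biological ranges [0.005, 0.016] and [0.121, 0.390] per hour reported for
real tumours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GompertzParams", "SigmoidGrowthParams", "BranchingParams", "ErrorReport",
    "FitResult", "gompertz", "sigmoid_growth", "branching", "error_metrics",
    "fit_growth_law", "GOMPERTZ_ALPHA_RANGE", "GOMPERTZ_BETA_RANGE",
]

log = logging.getLogger(__name__)

#: biological plausibility ranges for the Gompertz parameters [1/h]
GOMPERTZ_ALPHA_RANGE = (0.005, 0.016)
GOMPERTZ_BETA_RANGE = (0.121, 0.390)


@dataclass(frozen=True)
class GompertzParams:
    n0: float     # population at t = 0 [cells]
    alpha: float  # initial specific growth rate [1/h]
    beta: float   # deceleration rate [1/h]; plateau at n0 * e^(alpha/beta)

    def __post_init__(self) -> None:
        if not (self.n0 > 0 and self.alpha > 0 and self.beta > 0):
            raise ValueError("Gompertz parameters must be positive")


@dataclass(frozen=True)
class SigmoidGrowthParams:
    g0: float      # initial vessel length (bottom of the sigmoid)
    alpha: float   # range: top minus bottom
    beta: float    # slope time constant
    t_half: float  # time of the half-rise

    def __post_init__(self) -> None:
        if not (self.g0 >= 0 and self.alpha > 0 and self.beta > 0
                and self.t_half > 0):
            raise ValueError("sigmoid growth parameters out of range")


@dataclass(frozen=True)
class BranchingParams:
    b0: float     # branch points at t = 0
    alpha: float  # exponential scale
    beta: float   # branch-formation rate [1/h]

    def __post_init__(self) -> None:
        if not (self.b0 >= 0 and self.alpha > 0 and self.beta > 0):
            raise ValueError("branching parameters out of range")


def gompertz(t, params: GompertzParams):
    t = np.asarray(t, dtype=float)
    return params.n0 * np.exp(params.alpha / params.beta
                              * (1.0 - np.exp(-params.beta * t)))


def sigmoid_growth(t, params: SigmoidGrowthParams):
    t = np.asarray(t, dtype=float)
    return params.g0 + params.alpha / (1.0 + np.exp(-(t - params.t_half)
                                                    / params.beta))


def branching(t, params: BranchingParams):
    t = np.asarray(t, dtype=float)
    return params.b0 + params.alpha * np.exp(params.beta * t)


@dataclass(frozen=True)
class ErrorReport:
    """RMSE, MAD and MAPE (percent) of a predicted against an actual series."""

    rmse: float
    mad: float
    mape: float

    def __post_init__(self) -> None:
        if min(self.rmse, self.mad, self.mape) < 0:
            raise ValueError("error metrics must be >= 0")


def error_metrics(pred, actual) -> ErrorReport:
    """Forecast-error triple; MAPE averages only over non-zero actuals."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size == 0:
        raise ValueError("series must have equal non-zero length")
    err = pred - actual
    rmse = float(np.sqrt(np.mean(err**2)))
    mad = float(np.mean(np.abs(err)))
    nz = actual != 0.0
    if not nz.all():
        log.debug("MAPE skips %d zero-valued actuals", int((~nz).sum()))
    mape = float(np.mean(np.abs(err[nz] / actual[nz])) * 100.0) if nz.any() \
        else 0.0
    return ErrorReport(rmse, mad, mape)


@dataclass
class FitResult:
    law: str
    params: GompertzParams | SigmoidGrowthParams | BranchingParams
    error: ErrorReport
    in_biological_range: bool | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# Least-squares fitting with multi-start initial guesses

_TINY = 1e-12


def _fit_gompertz(t: np.ndarray, y: np.ndarray) -> tuple[GompertzParams, bool]:
    """Gompertz fit in log space (the model is linear in alpha/beta there)."""
    if (y <= 0).any():
        raise ValueError("Gompertz fitting needs strictly positive counts")
    logy = np.log(y)
    span = max(t[-1] - t[0], _TINY)
    ratio = max(np.log(max(y[-1], _TINY) / y[0]), _TINY)

    def resid(p):
        ln0, la, lb = p
        a, b = np.exp(la), np.exp(lb)
        return ln0 + (a / b) * (1.0 - np.exp(-b * t)) - logy

    best = None
    for b0 in (0.5 / span, 2.0 / span, 8.0 / span, 0.05, 0.3):
        a0 = max(ratio * b0, _TINY)
        p0 = [np.log(max(y[0], _TINY)), np.log(a0), np.log(b0)]
        try:
            sol = least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("Gompertz fit failed to converge from all starts")
    ln0, la, lb = best.x
    return GompertzParams(float(np.exp(ln0)), float(np.exp(la)),
                          float(np.exp(lb))), bool(best.success)


def _fit_sigmoid(t: np.ndarray, y: np.ndarray) -> tuple[SigmoidGrowthParams, bool]:
    span = max(t[-1] - t[0], _TINY)
    rng_y = max(y.max() - y.min(), _TINY)

    def resid(p):
        g0, a, b, th = p
        return g0 + a / (1.0 + np.exp(-(t - th) / max(b, _TINY))) - y

    best = None
    for frac in (0.25, 0.5, 0.75):
        p0 = [max(y.min(), 0.0), rng_y, span / 6.0, t[0] + frac * span]
        try:
            sol = least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                bounds=([0, _TINY, _TINY, _TINY],
                                        [np.inf] * 4), max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    g0, a, b, th = best.x
    return SigmoidGrowthParams(float(g0), float(a), float(b), float(th)), \
        bool(best.success)


def _fit_branching(t: np.ndarray, y: np.ndarray) -> tuple[BranchingParams, bool]:
    span = max(t[-1] - t[0], _TINY)
    rng_y = max(y.max() - y.min(), _TINY)

    def resid(p):
        b0, a, b = p
        return b0 + a * np.exp(b * t) - y

    best = None
    for b_init in (0.5 / span, 2.0 / span, 0.1):
        a0 = rng_y / max(np.exp(b_init * t[-1]) - np.exp(b_init * t[0]), _TINY)
        p0 = [max(y.min() - a0, 0.0), max(a0, _TINY), b_init]
        try:
            sol = least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                bounds=([0, _TINY, _TINY], [np.inf] * 3),
                                max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("branching fit failed to converge from all starts")
    b0, a, b = best.x
    return BranchingParams(float(b0), float(a), float(b)), bool(best.success)


def fit_growth_law(t, y, law: str) -> FitResult:
    """Fit one of the three growth laws to a (t, y) series.

    ``law`` is "gompertz", "sigmoid" or "branching".  At least four points
    are required; Gompertz additionally needs strictly positive counts.
    The Gompertz result carries an ``in_biological_range`` flag for the
    fitted (alpha, beta) against the published tumour ranges.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.size < 4:
        raise ValueError("need >= 4 (t, y) pairs of equal length")
    if law == "gompertz":
        params, ok = _fit_gompertz(t, y)
        fitted = gompertz(t, params)
        in_range = (GOMPERTZ_ALPHA_RANGE[0] <= params.alpha <= GOMPERTZ_ALPHA_RANGE[1]
                    and GOMPERTZ_BETA_RANGE[0] <= params.beta <= GOMPERTZ_BETA_RANGE[1])
    elif law == "sigmoid":
        params, ok = _fit_sigmoid(t, y)
        fitted = sigmoid_growth(t, params)
        in_range = None
    elif law == "branching":
        params, ok = _fit_branching(t, y)
        fitted = branching(t, params)
        in_range = None
    else:
        raise ValueError(f"unknown growth law {law!r}")
    return FitResult(law, params, error_metrics(fitted, y), in_range, ok)
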