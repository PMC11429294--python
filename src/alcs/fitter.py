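"""Fit the selection model to stage-wise viable-population fractions.

Flow-cytometry gating yields, at each stage end, the percentage of viable
cells that are transformed (GFP+) and non-transformed (GFP-).  With the
transformed growth rate mu1 fixed to its plate-derived value, the model
predicts the viable-only transformed percentage as

    %T(t) = 100 * c_x1(t) / (c_x1(t) + c_x2(t)),
    c_x1(t) = c_x10 * exp(mu1 * t),   c_x2(t) = (100 - c_x10) * exp(mu2 * t),

where c_x10 is expressed in percent of the initial viable population (the
initial non-transformed share is taken as 100 - c_x10).  The non-survival
rate mu2 and c_x10 are estimated by Levenberg-Marquardt damped least
squares (MINPACK via lmfit; box bounds mu2 <= 0, 0 <= c_x10 <= 100 are
handled by lmfit's parameter transformation).  Goodness of fit is reported
per curve as R^2 = 1 - SS_res/SS_tot.

Two fitting modes are provided: ``joint`` (default) stacks the residuals
of both curves and shares the two parameters; ``per_curve`` fits each
curve separately and reports c_x10 from the transformed curve and mu2 from
the non-transformed curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .exceptions import InsufficientDataError, InvalidParameterError


@dataclass(frozen=True)
class FractionObservations:
    """Viable-only population percentages at stage-end sampling times."""

    times: np.ndarray
    pct_viable_transformed: np.ndarray
    pct_viable_nontransformed: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("times", "pct_viable_transformed", "pct_viable_nontransformed"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.weights is not None:
            object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        n = self.times.size
        if self.pct_viable_transformed.size != n or self.pct_viable_nontransformed.size != n:
            raise InvalidParameterError("observation arrays must have equal length")
        if self.weights is not None and self.weights.size != n:
            raise InvalidParameterError("weights must match the number of observations")
        if np.any(np.diff(self.times) < 0):
            raise InvalidParameterError("times must be non-decreasing")
        for name in ("pct_viable_transformed", "pct_viable_nontransformed"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 100):
                raise InvalidParameterError(f"{name} must lie in [0, 100]")


@dataclass(frozen=True)
class FitResult:
    """Estimated mu2 [1/h] and c_x10 [% of initial viable cells], with R^2."""

    mu2_hat: float
    cx10_hat: float
    r_squared_transformed: float
    r_squared_nontransformed: float
    converged: bool
    n_iterations: int
    mode: str = "joint"


def predict_fractions(mu1: float, mu2: float, cx10_pct: float, times) -> np.ndarray:
    """Model-predicted viable-only transformed percentage at each time."""
    if not (0 <= cx10_pct <= 100):
        raise InvalidParameterError("cx10_pct must lie in [0, 100]")
    times = np.asarray(times, dtype=float)
    # Evaluate on the log scale to stay finite at large mu*t.
    log_c1 = np.where(cx10_pct > 0, math.log(max(cx10_pct, 1e-300)) + mu1 * times, -np.inf)
    log_c2 = np.where(
        cx10_pct < 100, math.log(max(100.0 - cx10_pct, 1e-300)) + mu2 * times, -np.inf
    )
    m = np.maximum(log_c1, log_c2)
    with np.errstate(invalid="ignore"):
        frac = np.exp(log_c1 - m) / (np.exp(log_c1 - m) + np.exp(log_c2 - m))
    return 100.0 * np.where(np.isfinite(m), frac, np.nan if np.ndim(m) == 0 else 0.0)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance observations: R^2 undefined", stacklevel=3)
        return math.nan
    return 1.0 - ss_res / ss_tot


def _make_params(mu1: float, first_obs: float, mu2_max: float) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    # The k-rule prior mu2 = -2.8*mu1 is the natural starting point.
    start_mu2 = min(-2.8 * mu1, mu2_max - 1e-8) if mu2_max <= 0 else -2.8 * mu1
    pars.add("mu2", value=start_mu2, min=-100.0, max=mu2_max)
    pars.add("cx10", value=float(np.clip(first_obs, 1e-2, 99.0)), min=0.0, max=100.0)
    return pars


def fit(
    obs: FractionObservations,
    mu1: float,
    *,
    mode: str = "joint",
    mu2_max: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> FitResult:
    """Estimate (mu2, c_x10) from gated stage fractions with mu1 fixed.

    Requires at least three observations.  Non-convergence returns the
    partial estimates with ``converged=False``; zero-variance observations
    yield NaN R^2 with a warning.
    """
    if obs.times.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if not (mu1 > 0):
        raise InvalidParameterError("mu1 must be positive")
    if mode not in ("joint", "per_curve"):
        raise InvalidParameterError(f"unknown fit mode {mode!r}")
    w = np.ones_like(obs.times) if obs.weights is None else obs.weights

    def residual(pars, which: str):
        pred_t = predict_fractions(mu1, pars["mu2"].value, pars["cx10"].value, obs.times)
        res = []
        if which in ("joint", "transformed"):
            res.append(w * (pred_t - obs.pct_viable_transformed))
        if which in ("joint", "nontransformed"):
            res.append(w * ((100.0 - pred_t) - obs.pct_viable_nontransformed))
        return np.concatenate(res)

    def minimize(which):
        return lmfit.minimize(
            residual,
            _make_params(mu1, obs.pct_viable_transformed[0], mu2_max),
            args=(which,),
            method="leastsq",
            xtol=tol,
            ftol=tol,
            max_nfev=max_iter * 10,
        )

    if mode == "joint":
        out = minimize("joint")
        mu2_hat = out.params["mu2"].value
        cx10_hat = out.params["cx10"].value
        pred_t = predict_fractions(mu1, mu2_hat, cx10_hat, obs.times)
        pred_nt = 100.0 - pred_t
        converged, n_iter = bool(out.success), int(out.nfev)
    else:
        out_t = minimize("transformed")
        out_nt = minimize("nontransformed")
        cx10_hat = out_t.params["cx10"].value
        mu2_hat = out_nt.params["mu2"].value
        pred_t = predict_fractions(
            mu1, out_t.params["mu2"].value, out_t.params["cx10"].value, obs.times
        )
        pred_nt = 100.0 - predict_fractions(
            mu1, mu2_hat, out_nt.params["cx10"].value, obs.times
        )
        converged = bool(out_t.success and out_nt.success)
        n_iter = int(out_t.nfev + out_nt.nfev)

    if not converged:
        warnings.warn("fit did not converge; returning partial estimates", stacklevel=2)
    return FitResult(
        mu2_hat=float(mu2_hat),
        cx10_hat=float(cx10_hat),
        r_squared_transformed=_r_squared(obs.pct_viable_transformed, pred_t),
        r_squared_nontransformed=_r_squared(obs.pct_viable_nontransformed, pred_nt),
        converged=converged,
        n_iterations=n_iter,
        mode=mode,
    )


def fit_report(result: FitResult) -> dict:
    """JSON-ready report of a fit."""
    return {
        "mu2_per_h": result.mu2_hat,
        "cx10_pct": result.cx10_hat,
        "r_squared_transformed": result.r_squared_transformed,
        "r_squared_nontransformed": result.r_squared_nontransformed,
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "mode": result.mode,
    }
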