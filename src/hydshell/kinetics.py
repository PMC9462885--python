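"""Arrhenius and super-Arrhenius (Vogel–Fulcher–Tammann) relaxation kinetics.

The temperature dependence of a relaxation time τ(T) is modelled either as

* Arrhenius: τ = τ0·exp(EA / kB·T), with activation energy EA, or
* super-Arrhenius (VFT): τ = τ0·exp(K·T0 / (T − T0)), where T0 is the
  relaxation-time divergence temperature and K measures fragility.

Both laws are linear in their transformed abscissa (1/kB·T and T0/(T−T0)
respectively), so fitting is a weighted linear regression of ln τ — exact,
reproducible, and matched to multiplicative noise on τ. T0 is always a
fixed input, never fitted: three-parameter VFT fits on a handful of points
are ill-conditioned, and the scientific question is usually a comparison
across literature T0 values.

Units: T in K, τ in ns, EA in meV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB_MEV_PER_K

__all__ = [
    "ArrheniusParams",
    "SuperArrheniusParams",
    "fit_arrhenius",
    "fit_super_arrhenius",
    "evaluate_tau",
    "crossover_temperature",
]


@dataclass
class ArrheniusParams:
    """τ(T) = tau0 · exp(EA / (kB·T)); tau0 in ns, EA in meV."""

    tau0: float
    EA: float
    tau0_err: float = math.nan
    EA_err: float = math.nan
    #: 2×2 covariance of (ln tau0, EA) from the linear fit
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")


@dataclass
class SuperArrheniusParams:
    """τ(T) = tau0 · exp(K·T0 / (T − T0)); valid only for T > T0.

    T0 (K) is a fixed input of the fit, not a fitted parameter.
    """

    tau0: float
    K: float
    T0: float
    tau0_err: float = math.nan
    K_err: float = math.nan
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, x]; returns (intercept, slope, cov)."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.sqrt(w)
    A = X * W[:, None]
    b = y * W
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = y - X @ coef
    dof = max(len(x) - 2, 1)
    s2 = float(np.sum(w * resid**2) / dof)
    XtWX = X.T @ (w[:, None] * X)
    try:
        cov = s2 * np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        raise ValueError("singular design matrix (all abscissae equal?)") from None
    return coef[0], coef[1], cov


def _log_weights(tau: np.ndarray, err) -> np.ndarray:
    if err is None:
        return np.ones_like(tau)
    err = np.asarray(err, dtype=float)
    sigma_ln = np.where(err > 0, err / tau, np.inf)
    finite = np.isfinite(sigma_ln)
    if not np.any(finite):
        return np.ones_like(tau)
    fallback = np.min(sigma_ln[finite])
    sigma_ln = np.where(finite, sigma_ln, fallback)
    return 1.0 / sigma_ln**2


def fit_arrhenius(T, tau, err=None) -> ArrheniusParams:
    """Weighted linear regression of ln τ on 1/(kB·T).

    Parameters are T (K), τ (ns) and optional one-sigma errors on τ (ns).
    The slope is EA in meV, the intercept ln τ0.
    """
    T = np.asarray(T, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least 2 points")
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    if np.all(T == T[0]):
        raise ValueError("singular design: all temperatures equal")
    x = 1.0 / (KB_MEV_PER_K * T)
    w = _log_weights(tau, err)
    ln_tau0, EA, cov = _weighted_linfit(x, np.log(tau), w)
    tau0 = math.exp(ln_tau0)
    return ArrheniusParams(
        tau0=tau0,
        EA=EA,
        tau0_err=tau0 * math.sqrt(max(cov[0, 0], 0.0)),
        EA_err=math.sqrt(max(cov[1, 1], 0.0)),
        cov=cov,
    )


def fit_super_arrhenius(T, tau, err=None, *, T0: float) -> SuperArrheniusParams:
    """Weighted linear regression of ln τ on T0/(T−T0) at fixed T0.

    The slope is the fragility constant K, the intercept ln τ0. Any
    temperature at or below T0 is a domain error.
    """
    T = np.asarray(T, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least 2 points")
    bad = T <= T0
    if np.any(bad):
        raise ValueError(
            f"temperature {T[bad][0]:g} K is at or below the divergence temperature T0={T0:g} K"
        )
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    x = T0 / (T - T0)
    w = _log_weights(tau, err)
    ln_tau0, K, cov = _weighted_linfit(x, np.log(tau), w)
    tau0 = math.exp(ln_tau0)
    return SuperArrheniusParams(
        tau0=tau0,
        K=max(K, 0.0),
        T0=T0,
        tau0_err=tau0 * math.sqrt(max(cov[0, 0], 0.0)),
        K_err=math.sqrt(max(cov[1, 1], 0.0)),
        cov=cov,
    )


def evaluate_tau(params, T: float) -> tuple[float, float]:
    """Evaluate τ(T) in ns with a first-order propagated uncertainty.

    Accepts either parameter type. For super-Arrhenius parameters T must
    exceed T0. Returns (tau, tau_err); the error is NaN when no covariance
    is attached (hand-built parameter sets).
    """
    if isinstance(params, ArrheniusParams):
        x = 1.0 / (KB_MEV_PER_K * T)
        tau = params.tau0 * math.exp(params.EA * x)
    elif isinstance(params, SuperArrheniusParams):
        if T <= params.T0:
            raise ValueError(f"T={T:g} K is at or below the divergence temperature T0={params.T0:g} K")
        x = params.T0 / (T - params.T0)
        tau = params.tau0 * math.exp(params.K * x)
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    if params.cov is not None:
        # ln τ = ln τ0 + slope·x ⇒ var(ln τ) = J Σ Jᵀ with J = (1, x)
        J = np.array([1.0, x])
        var_ln = float(J @ params.cov @ J)
        tau_err = tau * math.sqrt(max(var_ln, 0.0))
    else:
        tau_err = math.nan
    return tau, tau_err


def crossover_temperature(
    arr: ArrheniusParams,
    vft: SuperArrheniusParams,
    bracket: tuple[float, float],
    tol: float = 0.01,
) -> float:
    """Temperature where the Arrhenius and VFT laws cross.

    Bisection on g(T) = ln τ_Arr(T) − ln τ_VFT(T) to ``tol`` K. Both
    bracket ends must lie above the VFT divergence temperature and g must
    change sign across the bracket.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo >= hi:
        raise ValueError("bracket must satisfy lo < hi")
    if lo <= vft.T0:
        raise ValueError("bracket extends to or below the VFT divergence temperature")

    def g(T: float) -> float:
        return math.log(evaluate_tau(arr, T)[0]) - math.log(evaluate_tau(vft, T)[0])

    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if g_lo * g_hi > 0:
        raise ValueError("no sign change of ln τ difference on the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        if g_mid == 0.0:
            return mid
        if g_lo * g_mid < 0:
            hi = mid
        else:
            lo, g_lo = mid, g_mid
    return 0.5 * (lo + hi)
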