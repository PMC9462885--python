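"""QENS reduction: elastic scans, spectrum→ISF transformation, KWW fitting.

The chain implemented here turns reduced quasi-elastic spectra S(q, ΔE)
into relaxation times:

1. *Elastic scans* — the intensity inside the instrument's elastic energy
   window, summed over a q range and plotted against temperature; its
   downward bend (located by an exhaustive two-segment piecewise-linear
   fit) marks the apparent dynamical transition. Because the window is the
   instrument resolution, the onset temperature is resolution-dependent —
   a dynamic, not thermodynamic, signature.
2. *ISF extraction* — the intermediate scattering function F(q, t) is the
   (cosine) Fourier transform of S(q, ΔE); dividing by the transform of
   the measured resolution function deconvolves instrument broadening in
   the time domain. Spectra are treated as classical/symmetric
   (ħω ≪ kB·T), so the symmetrized cosine transform suffices.
3. *KWW fitting* — F(q, t) is fitted with the stretched exponential
   A·exp(−(t/τ)^β) (the relaxing-cage-model form); the Γ-weighted mean
   relaxation time ⟨τ⟩ = (τ/β)·Γ(1/β) and the bare τ are both reported.
4. *q scaling* — log–log regression of relaxation time on q; a power
   steeper than 2 signals sub-diffusive motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_func

from .constants import HBAR_UEV_PS
from .io import CurveTable, SpectrumTable

__all__ = [
    "ElasticScan",
    "ISFCurve",
    "KWWFit",
    "kww",
    "kww_mean_tau",
    "sum_elastic",
    "detect_onset",
    "isf_from_spectrum",
    "fit_kww",
    "fit_q_power",
]


@dataclass
class ElasticScan:
    """Summed elastic intensity vs temperature, normalized to the lowest T."""

    temperatures: np.ndarray
    intensity: np.ndarray
    q_range: tuple[float, float]
    energy_window: float

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not math.isclose(self.intensity[0], 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValueError("intensity must be normalized to 1 at the lowest temperature")


@dataclass
class ISFCurve:
    """Intermediate scattering function F(q, t), normalized so F(0) = 1.

    ``F_err`` (optional) carries per-point one-sigma uncertainties, e.g.
    propagated through the spectrum→time transform; fitting routines use
    it for weighting when present.
    """

    q: float
    times: np.ndarray
    F: np.ndarray
    temperature: float = math.nan
    F_err: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F_err is not None:
            self.F_err = np.asarray(self.F_err, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")


@dataclass
class KWWFit:
    """Stretched-exponential fit A·exp(−(t/τ)^β).

    ``mean_tau`` is the Γ-weighted mean relaxation time (τ/β)·Γ(1/β);
    ``tau`` the bare KWW time. β is the stretching exponent in (0, 1].
    """

    A: float
    tau: float
    beta: float
    A_err: float = math.nan
    tau_err: float = math.nan
    beta_err: float = math.nan
    redchi: float = math.nan

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.beta <= 1.0 + 1e-12):
            raise ValueError("beta must lie in (0, 1]")

    @property
    def mean_tau(self) -> float:
        return kww_mean_tau(self.tau, self.beta)


def kww(t, A: float, tau: float, beta: float) -> np.ndarray:
    """Stretched exponential A·exp(−(t/τ)^β); safe at t = 0 for β < 1."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-((t / tau) ** beta))


def kww_mean_tau(tau: float, beta: float) -> float:
    """⟨τ⟩ = ∫₀^∞ exp(−(t/τ)^β) dt = (τ/β)·Γ(1/β)."""
    return (tau / beta) * gamma_func(1.0 / beta)


# --------------------------------------------------------------------------
# elastic scans


def sum_elastic(spectra, q_range, energy_window: float) -> ElasticScan:
    """Build an elastic scan from per-temperature spectra.

    For each temperature, S is trapezoid-integrated over |ΔE| ≤
    ``energy_window`` (μeV) per q group, summed with uniform weight over q
    in ``q_range``, and the result divided by the lowest-temperature value.
    All spectra must share the same q set and ΔE grids.
    """
    spectra = sorted(spectra, key=lambda s: s.temperature)
    if not spectra:
        raise ValueError("no spectra given")
    q_lo, q_hi = q_range
    ref = spectra[0]
    ref_qs = [qv for qv in ref.q_values() if q_lo <= qv <= q_hi]
    if not ref_qs:
        raise ValueError("no q values inside q_range")
    # window must contain at least two grid points for a trapezoid
    dE0 = ref.group(ref_qs[0])[0]
    in_win = np.abs(dE0) <= energy_window
    if int(np.sum(in_win)) < 2:
        raise ValueError("energy_window narrower than the dE grid spacing")
    values = []
    for spec in spectra:
        qs = [qv for qv in spec.q_values() if q_lo <= qv <= q_hi]
        if len(qs) != len(ref_qs) or not np.allclose(qs, ref_qs):
            raise ValueError(
                f"inconsistent q grid at T={spec.temperature} (expected {ref_qs})"
            )
        total = 0.0
        for qv in qs:
            dE, S, _ = spec.group(qv)
            ref_dE = ref.group(qv)[0]
            if len(dE) != len(ref_dE) or not np.allclose(dE, ref_dE):
                raise ValueError(f"inconsistent dE grid at T={spec.temperature}, q={qv}")
            mask = np.abs(dE) <= energy_window
            total += float(np.trapezoid(S[mask], dE[mask]))
        values.append(total)
    values = np.array(values)
    if values[0] == 0:
        raise ValueError("zero elastic intensity at the lowest temperature")
    return ElasticScan(
        temperatures=np.array([s.temperature for s in spectra]),
        intensity=values / values[0],
        q_range=(q_lo, q_hi),
        energy_window=energy_window,
    )


def detect_onset(scan: ElasticScan, fit_range: tuple[float, float]):
    """Locate the downward bend of an elastic scan.

    Fits a continuous two-segment piecewise-linear model by exhaustive
    search over interior grid temperatures as candidate breakpoints (at
    least 4 points per segment), solving a 3-parameter linear least
    squares per candidate and keeping the SSE minimizer.

    Returns (T_onset, (slope_low, slope_high), sse).
    """
    lo, hi = fit_range
    mask = (scan.temperatures >= lo) & (scan.temperatures <= hi)
    T = scan.temperatures[mask]
    y = scan.intensity[mask]
    if len(T) < 8:
        raise ValueError("need at least 8 points in fit_range")
    min_seg = 4
    best = None
    for k in range(min_seg - 1, len(T) - min_seg):
        Tb = T[k]
        # continuous hinge: y = a + s1·(T−Tb) + (s2−s1)·max(T−Tb, 0)
        d = T - Tb
        X = np.column_stack([np.ones_like(T), d, np.maximum(d, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, Tb, coef)
    if best is None:
        raise ValueError("degenerate fit: fewer than 4 points per segment possible")
    sse, Tb, (a, s1, ds) = best
    return float(Tb), (float(s1), float(s1 + ds)), sse


# --------------------------------------------------------------------------
# ISF extraction


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2
    w[1:] += dx / 2
    return w


def _cosine_transform(dE: np.ndarray, S: np.ndarray, times: np.ndarray) -> np.ndarray:
    """F(t) = ∫ S(ΔE)·cos(ΔE·t/ħ) d(ΔE) by trapezoid on the measured window."""
    phase = np.outer(times, dE) / HBAR_UEV_PS
    integrand = S[None, :] * np.cos(phase)
    return np.trapezoid(integrand, dE, axis=1)


def _cosine_transform_err(dE: np.ndarray, err: np.ndarray, times: np.ndarray) -> np.ndarray:
    """One-sigma uncertainty of the trapezoid cosine transform for
    independent per-point spectrum errors."""
    w = _trapezoid_weights(dE)
    phase = np.outer(times, dE) / HBAR_UEV_PS
    var = np.sum((w[None, :] * err[None, :] * np.cos(phase)) ** 2, axis=1)
    return np.sqrt(var)


def isf_from_spectrum(
    sample: SpectrumTable,
    resolution: SpectrumTable,
    q: float,
    times,
    cutoff: float = 0.01,
) -> ISFCurve:
    """Extract F(q, t) from a measured spectrum by time-domain deconvolution.

    The sample and resolution row groups at ``q`` (shared ΔE grid) are
    cosine-transformed to the time domain; F(t) is their ratio, normalized
    so F(0) = 1. Time points where the resolution transform has decayed
    below ``cutoff``·F_res(0) are dropped (noise amplification guard);
    the number dropped is recorded in the curve metadata.
    """
    times = np.asarray(times, dtype=float)
    dE_s, S_s, err_s = sample.group(q)
    dE_r, S_r, _ = resolution.group(q)
    if len(dE_s) != len(dE_r) or not np.allclose(dE_s, dE_r):
        raise ValueError("sample and resolution must share the dE grid")
    res_integral = float(np.trapezoid(S_r, dE_r))
    if res_integral <= 0:
        raise ValueError("resolution integral must be positive")
    t_all = np.concatenate([[0.0], times]) if times[0] > 0 else times
    F_s = _cosine_transform(dE_s, S_s, t_all)
    F_r = _cosine_transform(dE_r, S_r, t_all)
    keep = np.abs(F_r) >= cutoff * F_r[0]
    keep[0] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(keep, F_s / np.where(F_r == 0, np.nan, F_r), np.nan)
    norm = ratio[0]
    ratio = ratio / norm
    sel = keep & np.isfinite(ratio)
    if times[0] > 0:
        sel[0] = False  # synthetic t=0 anchor, not requested
    n_dropped = int(len(times) - np.sum(sel[1:] if times[0] > 0 else sel))
    if not np.any(sel):
        raise ValueError("all time points beyond the resolution limit")
    if np.any(err_s > 0):
        sig = _cosine_transform_err(dE_s, err_s, t_all)
        with np.errstate(divide="ignore", invalid="ignore"):
            F_err = np.abs(sig / (F_r * norm))
        F_err = F_err[sel]
    else:
        F_err = None
    return ISFCurve(
        q=q,
        times=t_all[sel],
        F=ratio[sel],
        temperature=sample.temperature,
        F_err=F_err,
        metadata={"n_dropped": n_dropped, "resolution_cutoff": cutoff},
    )


# --------------------------------------------------------------------------
# KWW fitting


def fit_kww(
    curve: ISFCurve,
    beta_bounds: tuple[float, float] = (0.1, 1.0),
    weights=None,
) -> KWWFit:
    """Least-squares KWW fit of an ISF curve.

    Multi-start local optimization (β initialized at 0.3, 0.6, 0.9;
    Levenberg–Marquardt), tie-broken by SSE. Uncertainties come from the
    fit covariance. Requires ≥ 6 points with F in [−0.2, 1.2].
    """
    import lmfit

    t = np.asarray(curve.times, dtype=float)
    F = np.asarray(curve.F, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 points")
    if np.any(F < -0.2) or np.any(F > 1.2):
        raise ValueError("F values outside [-0.2, 1.2]; not a normalized ISF")
    pos = t > 0
    if weights is None and curve.F_err is not None and np.all(curve.F_err > 0):
        weights = 1.0 / curve.F_err
    if weights is not None:
        weights = np.asarray(weights, dtype=float)

    # crude τ initial: time of decay closest to A/e
    def tau_guess() -> float:
        target = F[0] / math.e
        below = np.flatnonzero(F <= target)
        if below.size:
            return max(float(t[below[0]]), 1e-6)
        return float(t[pos][-1]) if np.any(pos) else 1.0

    def residual(params):
        model = kww(t, params["A"].value, params["tau"].value, params["beta"].value)
        r = model - F
        return r * weights if weights is not None else r

    b_lo, b_hi = beta_bounds
    best = None
    errors = []
    for beta0 in (0.3, 0.6, 0.9):
        beta0 = min(max(beta0, b_lo + 1e-3), b_hi)
        params = lmfit.Parameters()
        params.add("A", value=float(F[0]), min=0.0, max=1.5)
        params.add("tau", value=tau_guess(), min=1e-9)
        params.add("beta", value=beta0, min=b_lo, max=b_hi)
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception as exc:  # pragma: no cover - lmfit internal failures
            errors.append(str(exc))
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not np.isfinite(best.chisqr):
        raise RuntimeError(f"KWW fit did not converge after restarts: {errors}")
    p = best.params

    def err_of(name: str) -> float:
        stderr = p[name].stderr
        return float(stderr) if stderr is not None else math.nan

    return KWWFit(
        A=p["A"].value,
        tau=p["tau"].value,
        beta=p["beta"].value,
        A_err=err_of("A"),
        tau_err=err_of("tau"),
        beta_err=err_of("beta"),
        redchi=float(best.redchi),
    )


def fit_q_power(qs, taus) -> tuple[float, float, float]:
    """Power-law scaling of relaxation time with momentum transfer.

    Ordinary least squares of ln τ on ln q. Returns (exponent, prefactor,
    stderr); the exponent is the signed slope (negative for sub-diffusive
    τ ∝ q^−n) and the prefactor is τ at q = 1.
    """
    qs = np.asarray(qs, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if len(qs) < 3:
        raise ValueError("need at least 3 (q, tau) pairs")
    if np.any(qs <= 0) or np.any(taus <= 0):
        raise ValueError("q and tau must be positive")
    x = np.log(qs)
    y = np.log(taus)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(x) - 2, 1)
    s2 = float(np.sum(resid**2)) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(coef[1]), float(math.exp(coef[0])), float(math.sqrt(max(cov[1, 1], 0.0)))
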