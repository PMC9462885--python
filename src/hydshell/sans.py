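"""Zero-average-contrast SANS modelling for isotopically mixed polymer solutions.

A mixture of hydrogenated and deuterated chains of the same length in an
H2O/D2O solvent scatters as

    dΣ/dΩ = (ρ_d − ρ_s)² (φ_d φ_h / φ_P²) n v P_S(q)
          + (ρ_d φ_d/φ_P + ρ_h φ_h/φ_P − ρ_s)² n φ_P v P_T(q),

with P_T = P_S + φ_P·P_I the total (single-chain plus inter-chain) form
factor. When the solvent scattering length density equals the composition-
averaged chain SLD, the second term vanishes (the zero-average-contrast,
ZAC, condition) and the measured intensity is pure single-chain scattering —
no extrapolation to zero concentration required. Sweeping the D2O fraction,
√I is piecewise linear in the fraction with a sign change at the match
point, which this module locates by a sign-unfolded weighted line fit.

Single chains are modelled with the excluded-volume form factor
(incomplete-gamma representation); its high-q log-log slope is −1/v, the
Porod exponent, with v = 3/5 a fully swollen chain, 1/2 a Gaussian coil
and 1/3 a collapsed globule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_func
from scipy.special import gammainc

__all__ = [
    "SLD",
    "ContrastModel",
    "FormFactorParams",
    "SANSFitResult",
    "COHERENT_LENGTH_FM",
    "ATOMIC_MASS",
    "sld_from_composition",
    "match_point",
    "lower_incomplete_gamma",
    "excluded_volume_form_factor",
    "zac_intensity",
    "partial_structure_factors",
    "fit_sans",
]

#: Bound coherent neutron scattering lengths, fm.
COHERENT_LENGTH_FM = {"H": -3.739, "D": 6.671, "C": 6.646, "O": 5.803}
#: Atomic masses, g/mol.
ATOMIC_MASS = {"H": 1.008, "D": 2.014, "C": 12.011, "O": 15.999}
_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class SLD:
    """Neutron scattering length density in Å⁻² with a composition label.

    Mixture SLDs are linear in volume fraction: ``0.5*a + 0.5*b`` via
    :meth:`mix`.
    """

    value: float
    label: str = ""

    @staticmethod
    def mix(components, fractions, label: str = "mixture") -> "SLD":
        fractions = np.asarray(fractions, dtype=float)
        if not math.isclose(float(fractions.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("volume fractions must sum to 1")
        value = float(sum(f * c.value for f, c in zip(fractions, components)))
        return SLD(value=value, label=label)


def sld_from_composition(formula: dict, density: float, label: str = "") -> SLD:
    """SLD of a compound from its formula (H and D distinguished) and mass density.

    ρ = Σᵢ bᵢ / v_mol with v_mol = M/(density·N_A). ``density`` in g/cm³;
    result in Å⁻².
    """
    if density <= 0:
        raise ValueError("density must be positive")
    unknown = set(formula) - set(COHERENT_LENGTH_FM)
    if unknown:
        raise ValueError(f"unknown element(s): {sorted(unknown)}")
    mass = sum(ATOMIC_MASS[el] * n for el, n in formula.items())  # g/mol
    vol_cm3 = mass / (density * _AVOGADRO)  # cm³ per formula unit
    vol_A3 = vol_cm3 * 1e24
    b_sum_A = sum(COHERENT_LENGTH_FM[el] * n for el, n in formula.items()) * 1e-5  # fm → Å
    return SLD(value=b_sum_A / vol_A3, label=label)


# --------------------------------------------------------------------------
# match point


def match_point(fractions, intensities, err=None) -> tuple[float, float]:
    """Contrast match point from an intensity-vs-D2O-fraction series.

    Intensity is quadratic in contrast, so √I is the absolute value of a
    line in the solvent fraction. The sign of √I is flipped past the
    intensity minimum — the two candidate flip positions (at the minimum
    or just after it) are both fitted and the lower-SSE assignment kept —
    and the match point is the root of the fitted line.

    Returns (f_match, stderr).
    """
    f = np.asarray(fractions, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 fractions")
    if np.any(I < 0):
        raise ValueError("intensities must be non-negative")
    order = np.argsort(f)
    f, I = f[order], I[order]
    if err is not None:
        err = np.asarray(err, dtype=float)[order]
    k_min = int(np.argmin(I))
    if k_min in (0, len(f) - 1):
        raise ValueError("intensity minimum not spanned by the fraction series")
    if np.all(I == I[0]):
        raise ValueError("degenerate fit: all intensities equal")
    root_I = np.sqrt(I)
    # σ(√I) = σ(I) / (2√I)
    if err is not None:
        with np.errstate(divide="ignore"):
            sigma = np.where(root_I > 0, err / (2 * root_I), np.inf)
        finite = np.isfinite(sigma) & (sigma > 0)
        if np.any(finite):
            sigma = np.where(finite, sigma, np.min(sigma[finite]))
            w = 1.0 / sigma**2
        else:
            w = np.ones_like(f)
    else:
        w = np.ones_like(f)

    best = None
    for flip_at in (k_min, k_min + 1):
        signs = np.where(np.arange(len(f)) < flip_at, 1.0, -1.0)
        y = signs * root_I
        X = np.column_stack([np.ones_like(f), f])
        A = X * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
        resid = y - X @ coef
        sse = float(np.sum(w * resid**2))
        if best is None or sse < best[0]:
            best = (sse, coef, w, y)
    sse, (a, b), w, y = best
    if b == 0:
        raise ValueError("degenerate fit: zero slope")
    f_match = -a / b
    X = np.column_stack([np.ones_like(f), f])
    dof = max(len(f) - 2, 1)
    s2 = sse / dof
    cov = s2 * np.linalg.inv(X.T @ (w[:, None] * X))
    # f_match = −a/b ⇒ J = (−1/b, a/b²)
    J = np.array([-1.0 / b, a / b**2])
    stderr = math.sqrt(max(float(J @ cov @ J), 0.0))
    return float(f_match), stderr


# --------------------------------------------------------------------------
# excluded-volume form factor


def lower_incomplete_gamma(a: float, x) -> np.ndarray:
    """γ(a, x) = ∫₀ˣ e^{−t} t^{a−1} dt via the regularized form Γ(a)·P(a, x)."""
    return gamma_func(a) * gammainc(a, np.asarray(x, dtype=float))


def _ev_series(U: np.ndarray, v: float) -> np.ndarray:
    """Small-U Taylor expansion of the excluded-volume form factor.

    Each term (1/v)·U^{−a}·γ(a,U) expands to
    (1/v)·(1/a − U/(a+1) + U²/(2(a+2)) − U³/(6(a+3))); the two-term
    difference is 1 − O(U), exact to O(U⁴).
    """

    def term(a: float) -> np.ndarray:
        return (1.0 / v) * (1.0 / a - U / (a + 1) + U**2 / (2 * (a + 2)) - U**3 / (6 * (a + 3)))

    return term(1.0 / (2 * v)) - term(1.0 / v)


def excluded_volume_form_factor(q, Rg: float, v: float) -> np.ndarray:
    """Form factor of an excluded-volume chain.

    P(q) = (1/(v·U^{1/2v}))·γ(1/2v, U) − (1/(v·U^{1/v}))·γ(1/v, U) with
    U = q²Rg²(2v+1)(2v+2)/6. The printed formula is 0/0 at q = 0; a Taylor
    expansion below U = 1e-4 keeps P(0) = 1 exactly.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if Rg <= 0:
        raise ValueError("Rg must be positive")
    if not (0.2 < v < 1.0):
        raise ValueError("excluded-volume parameter v must lie in (0.2, 1)")
    U = q**2 * Rg**2 * (2 * v + 1) * (2 * v + 2) / 6.0
    P = np.empty_like(U)
    small = U < 1e-4
    if np.any(small):
        P[small] = _ev_series(U[small], v)
    big = ~small
    if np.any(big):
        Ub = U[big]
        a1, a2 = 1.0 / (2 * v), 1.0 / v
        P[big] = (
            lower_incomplete_gamma(a1, Ub) / (v * Ub**a1)
            - lower_incomplete_gamma(a2, Ub) / (v * Ub**a2)
        )
    return P


@dataclass
class FormFactorParams:
    """Excluded-volume chain parameters.

    ``Rg`` in Å; ``v`` dimensionless; optionally the statistical segment
    length ``b`` (Å) and degree of polymerization ``n``, which determine
    Rg² = b²·n^{2v}/((2v+1)(2v+2)). The Porod exponent m = 1/v is derived.
    """

    Rg: float
    v: float
    b: float | None = None
    n: int | None = None
    Rg_err: float = math.nan
    v_err: float = math.nan

    def __post_init__(self) -> None:
        if self.b is not None and self.n is not None:
            rg2 = self.b**2 * self.n ** (2 * self.v) / ((2 * self.v + 1) * (2 * self.v + 2))
            if not math.isclose(self.Rg**2, rg2, rel_tol=1e-6):
                raise ValueError("Rg inconsistent with b, n, v")

    @property
    def porod_exponent(self) -> float:
        return 1.0 / self.v

    @staticmethod
    def from_segments(b: float, n: int, v: float) -> "FormFactorParams":
        rg = math.sqrt(b**2 * n ** (2 * v) / ((2 * v + 1) * (2 * v + 2)))
        return FormFactorParams(Rg=rg, v=v, b=b, n=n)


# --------------------------------------------------------------------------
# zero-average-contrast intensity


@dataclass
class ContrastModel:
    """Composition and form factors of an h/d chain mixture in H2O/D2O.

    Volume-fraction invariants: φ_PEG = φ_dPEG + φ_hPEG,
    φ_S = φ_H2O + φ_D2O, φ_PEG + φ_S = 1. ``P_S`` and ``P_I`` are callables
    of q (single-chain and inter-chain form factors); P_T = P_S + φ_PEG·P_I.
    ``n_chains`` is the chain number density (Å⁻³) and ``v_chain`` the chain
    volume (Å³).
    """

    rho_d: SLD
    rho_h: SLD
    rho_s: SLD
    phi_dPEG: float
    phi_hPEG: float
    phi_D2O: float
    phi_H2O: float
    n_chains: float
    v_chain: float
    P_S: object = field(default=lambda q: np.ones_like(np.atleast_1d(q)))
    P_I: object = field(default=lambda q: np.zeros_like(np.atleast_1d(q)))

    def __post_init__(self) -> None:
        for name in ("phi_dPEG", "phi_hPEG", "phi_D2O", "phi_H2O"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if not math.isclose(self.phi_PEG + self.phi_S, 1.0, abs_tol=1e-9):
            raise ValueError("volume fractions must sum to 1")

    @property
    def phi_PEG(self) -> float:
        return self.phi_dPEG + self.phi_hPEG

    @property
    def phi_S(self) -> float:
        return self.phi_D2O + self.phi_H2O

    @property
    def rho_peg_avg(self) -> float:
        """Composition-averaged chain SLD (the quantity matched at ZAC)."""
        return (
            self.rho_d.value * self.phi_dPEG + self.rho_h.value * self.phi_hPEG
        ) / self.phi_PEG

    def P_T(self, q) -> np.ndarray:
        return np.asarray(self.P_S(q)) + self.phi_PEG * np.asarray(self.P_I(q))


def zac_intensity(model: ContrastModel, q) -> np.ndarray:
    """Scattered intensity of the h/d mixture (two-term contrast form).

    First term: single-chain scattering weighted by the h/d contrast
    combination — survives at the match point. Second term: total
    scattering weighted by the average contrast against the solvent —
    vanishes when the solvent SLD equals the φ-averaged chain SLD.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    phi_p = model.phi_PEG
    if phi_p <= 0:
        raise ValueError("no polymer in the model")
    x_d = model.phi_dPEG / phi_p
    x_h = model.phi_hPEG / phi_p
    term1 = (
        (model.rho_d.value - model.rho_s.value) ** 2
        * x_d
        * x_h
        * model.n_chains
        * model.v_chain
        * np.asarray(model.P_S(q))
    )
    avg_contrast = model.rho_peg_avg - model.rho_s.value
    term2 = avg_contrast**2 * model.n_chains * phi_p * model.v_chain * model.P_T(q)
    return term1 + term2


def partial_structure_factors(model: ContrastModel, q):
    """Partial structure factors (S_dd, S_hh, S_hd) consistent with
    :func:`zac_intensity`.

    Decomposition: with S_T = n·φ_P·v·P_T and S_1 = n·v·P_S,
    S_dd = x_d²·S_T + x_d·x_h·S_1, S_hh = x_h²·S_T, S_hd = x_d·x_h·S_T.
    Substituting into the three-term contrast expansion
    (ρ_d−ρ_s)²S_dd + (ρ_h−ρ_s)²S_hh + 2(ρ_d−ρ_s)(ρ_h−ρ_s)S_hd reproduces
    the two-term form exactly.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    phi_p = model.phi_PEG
    x_d = model.phi_dPEG / phi_p
    x_h = model.phi_hPEG / phi_p
    S_T = model.n_chains * phi_p * model.v_chain * model.P_T(q)
    S_1 = model.n_chains * model.v_chain * np.asarray(model.P_S(q))
    S_dd = x_d**2 * S_T + x_d * x_h * S_1
    S_hh = x_h**2 * S_T
    S_hd = x_d * x_h * S_T
    return S_dd, S_hh, S_hd


# --------------------------------------------------------------------------
# curve fitting


@dataclass
class SANSFitResult:
    params: FormFactorParams
    scale: float
    background: float
    scale_err: float
    background_err: float
    chisqr: float
    redchi: float


def fit_sans(
    curve,
    *,
    fix_v: float | None = None,
    rg_init: float | None = None,
    max_restarts: int = 3,
) -> SANSFitResult:
    """Weighted nonlinear least squares of scale·P(q; Rg, v) + background.

    ``curve`` is a CurveTable of I(q) with positive errors. ``fix_v`` pins
    the excluded-volume parameter (e.g. 1/2 for a Gaussian coil, 3/5 for a
    swollen chain). Multi-start over Rg and v initials guards against local
    minima; non-convergence after all restarts raises.
    """
    import lmfit

    q = np.asarray(curve.x, dtype=float)
    I = np.asarray(curve.y, dtype=float)
    if curve.err is None or np.any(curve.err <= 0):
        raise ValueError("fit_sans requires positive errors on every point")
    sigma = np.asarray(curve.err, dtype=float)

    def model_fn(params, q):
        P = excluded_volume_form_factor(q, params["Rg"].value, params["v"].value)
        return params["scale"].value * P + params["background"].value

    def residual(params):
        return (model_fn(params, q) - I) / sigma

    if rg_init is None:
        rg_init = 1.0 / max(np.median(q), 1e-6)
    v_inits = [fix_v] if fix_v is not None else [0.42, 0.5, 0.6]
    best = None
    attempts = 0
    for rg0 in (rg_init, 0.5 * rg_init, 2.0 * rg_init):
        for v0 in v_inits:
            if attempts >= (max_restarts * len(v_inits)) and best is not None:
                break
            attempts += 1
            params = lmfit.Parameters()
            params.add("Rg", value=rg0, min=1e-3)
            params.add("v", value=v0, min=0.25, max=0.95, vary=fix_v is None)
            params.add("scale", value=float(np.max(I) - np.min(I)) or 1.0, min=0.0)
            params.add("background", value=float(np.min(I)))
            try:
                out = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
    if best is None or not np.isfinite(best.chisqr):
        raise RuntimeError("SANS fit did not converge after multi-start")
    p = best.params
    ff = FormFactorParams(
        Rg=p["Rg"].value,
        v=p["v"].value,
        Rg_err=p["Rg"].stderr if p["Rg"].stderr is not None else math.nan,
        v_err=p["v"].stderr if (fix_v is None and p["v"].stderr is not None) else math.nan,
    )
    return SANSFitResult(
        params=ff,
        scale=p["scale"].value,
        background=p["background"].value,
        scale_err=p["scale"].stderr if p["scale"].stderr is not None else math.nan,
        background_err=p["background"].stderr if p["background"].stderr is not None else math.nan,
        chisqr=float(best.chisqr),
        redchi=float(best.redchi),
    )
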