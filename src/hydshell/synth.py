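"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be emulated here with closed-form
oracles, so each analysis stage is testable without a spectrometer or an
MD engine:

* resolution-broadened KWW spectra with a power-law τ(q);
* two-state (telegraph) hydrogen-bond on/off kinetics;
* trap-and-jump water walkers (libration in a site, exponential residence,
  nearest-neighbour hops on a cubic lattice);
* excluded-volume SANS curves and contrast-variation series;
* two-phase boxes (slab or spheres of water points) for the volume
  distribution;
* bilinear elastic scans with an onset temperature.

Each generator takes a mandatory seed and returns a truth record (a plain
dict of the generating parameters and derived ground-truth values);
identical arguments including the seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import HBAR_UEV_PS
from .io import CurveTable, SpectrumTable, Topology, Trajectory
from .qens import ElasticScan, kww
from .sans import SLD, ContrastModel, excluded_volume_form_factor, zac_intensity
from .trajectory import HBondSeries

__all__ = [
    "GeneratorSpec",
    "generate",
    "gen_kww_spectra",
    "gen_telegraph",
    "gen_trap_jump_trajectory",
    "gen_sans_curve",
    "gen_contrast_series",
    "gen_two_phase_box",
    "gen_elastic_scan",
]

# SLDs of light and heavy water at their standard densities, Å⁻²
_RHO_H2O = -5.59e-7
_RHO_D2O = 6.37e-6


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative generator call: kind + parameters + mandatory seed."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _GENERATORS:
            raise ValueError(f"unknown generator kind '{self.kind}'")


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec; identical specs yield identical output."""
    return _GENERATORS[spec.kind](seed=spec.seed, **spec.parameters)


# --------------------------------------------------------------------------
# QENS spectra


def _kww_time_grid(tau: float, beta: float, sigma_e: float, n: int = 4000) -> np.ndarray:
    """Time grid reaching the point where KWW×resolution has decayed to ~1e-8."""
    t_res = math.sqrt(2 * math.log(1e8)) * HBAR_UEV_PS / sigma_e
    t_kww = tau * math.log(1e8) ** (1.0 / beta)
    return np.linspace(0.0, min(t_res, t_kww), n)


def gen_kww_spectra(
    qs,
    tau1: float,
    power: float,
    beta: float,
    resolution_fwhm: float,
    noise_frac: float,
    dE_grid,
    seed: int,
    temperature: float = 298.0,
):
    """Resolution-broadened spectra of a KWW relaxer with τ(q) = tau1·q^power.

    Per q the spectrum is the numeric cosine transform of
    exp(−(t/τ(q))^β) multiplied by the Gaussian resolution's time-domain
    envelope (equivalent to convolving in energy), plus multiplicative
    Gaussian noise of relative size ``noise_frac``. The companion
    resolution spectrum is the analytic Gaussian of FWHM
    ``resolution_fwhm`` (μeV).

    Returns (sample, resolution, truth).
    """
    if not (0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    if resolution_fwhm <= 0:
        raise ValueError("resolution_fwhm must be positive")
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    dE = np.asarray(dE_grid, dtype=float)
    sigma_e = resolution_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    rng = np.random.default_rng(seed)

    q_col, dE_col, S_col, err_col = [], [], [], []
    rq_col, rS_col = [], []
    res_shape = np.exp(-0.5 * (dE / sigma_e) ** 2) / (sigma_e * math.sqrt(2 * math.pi))
    taus = {}
    for q in qs:
        tau = tau1 * q**power
        taus[float(q)] = tau
        t = _kww_time_grid(tau, beta, sigma_e)
        envelope = np.exp(-0.5 * (sigma_e * t / HBAR_UEV_PS) ** 2)
        Ft = kww(t, 1.0, tau, beta) * envelope
        phase = np.outer(dE, t) / HBAR_UEV_PS
        S = np.trapezoid(Ft[None, :] * np.cos(phase), t, axis=1) / (math.pi * HBAR_UEV_PS)
        norm = float(np.trapezoid(S, dE))
        if norm < 0.9:
            raise ValueError(
                f"dE window too narrow at q={q:g}: captures {norm:.3f} of the analytic norm"
            )
        clean = S
        noisy = clean * (1.0 + noise_frac * rng.standard_normal(len(dE))) if noise_frac > 0 else clean
        err = noise_frac * np.abs(clean)
        q_col.append(np.full_like(dE, q))
        dE_col.append(dE)
        S_col.append(noisy)
        err_col.append(err)
        rq_col.append(np.full_like(dE, q))
        rS_col.append(res_shape)
    sample = SpectrumTable(
        temperature=temperature,
        q=np.concatenate(q_col),
        dE=np.concatenate(dE_col),
        S=np.concatenate(S_col),
        err=np.concatenate(err_col),
    )
    resolution = SpectrumTable(
        temperature=10.0,
        q=np.concatenate(rq_col),
        dE=np.concatenate([dE] * len(qs)),
        S=np.concatenate(rS_col),
        err=np.zeros(len(dE) * len(qs)),
    )
    truth = {
        "kind": "kww_spectra",
        "tau1": tau1,
        "power": power,
        "beta": beta,
        "resolution_fwhm": resolution_fwhm,
        "noise_frac": noise_frac,
        "tau_of_q": taus,
        "seed": seed,
    }
    return sample, resolution, truth


# --------------------------------------------------------------------------
# telegraph hydrogen-bond kinetics


def gen_telegraph(
    k_on: float,
    k_off: float,
    n_frames: int,
    timestep: float,
    n_pairs: int,
    seed: int,
) -> tuple[HBondSeries, dict]:
    """Stationary two-state Markov bond series with exact step transitions.

    Rates in 1/ps; chains start from the equilibrium occupancy
    p = k_on/(k_on+k_off). Requires timestep·max(rate) < 0.1 so the
    discrete chain tracks the continuous process.
    """
    if k_on < 0 or k_off < 0 or (k_on + k_off) <= 0:
        raise ValueError("rates must be non-negative with a positive sum")
    if timestep * max(k_on, k_off) >= 0.1:
        raise ValueError("timestep too coarse: timestep*max(rate) must be < 0.1")
    rng = np.random.default_rng(seed)
    k = k_on + k_off
    p = k_on / k
    e = math.exp(-k * timestep)
    p11 = p + (1 - p) * e  # stay on
    p01 = p * (1 - e)  # off → on
    h = np.empty((n_pairs, n_frames), dtype=np.uint8)
    state = (rng.random(n_pairs) < p).astype(np.uint8)
    h[:, 0] = state
    for t in range(1, n_frames):
        u = rng.random(n_pairs)
        stay = (state == 1) & (u < p11)
        flip_on = (state == 0) & (u < p01)
        state = (stay | flip_on).astype(np.uint8)
        h[:, t] = state
    pairs = [(i, i, i) for i in range(n_pairs)]
    truth = {
        "kind": "telegraph",
        "k_on": k_on,
        "k_off": k_off,
        "p_eq": p,
        "timestep": timestep,
        "seed": seed,
    }
    return HBondSeries(pairs=pairs, h=h, timestep=timestep), truth


# --------------------------------------------------------------------------
# trap-and-jump walkers


def gen_trap_jump_trajectory(
    n_walkers: int,
    site_spacing: float,
    mean_residence: float,
    libration_sigma: float,
    timestep: float,
    n_frames: int,
    box: float,
    seed: int,
):
    """Walkers librating in cubic-lattice traps with exponential residence.

    Each walker vibrates isotropically (Gaussian, σ = ``libration_sigma``)
    about its current site and, after an exponential residence of mean
    ``mean_residence`` ps, hops to one of the 6 nearest-neighbour sites
    (spacing ``site_spacing`` Å). Positions are wrapped into a cubic box;
    sites are tracked unwrapped so hop statistics stay exact. Roles are
    all OW (one bare-oxygen WAT molecule per walker).

    Returns (Trajectory, Topology, truth).
    """
    if libration_sigma >= 0.5 * site_spacing:
        raise ValueError("libration_sigma must be well below site_spacing")
    if mean_residence <= 0:
        raise ValueError("mean_residence must be positive")
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))
    sites = (rng.integers(0, max(int(box // site_spacing), 1), size=(n_walkers, 3))).astype(float)
    sites *= site_spacing
    p_jump = 0.0 if math.isinf(mean_residence) else 1.0 - math.exp(-timestep / mean_residence)
    positions = np.empty((n_frames, n_walkers, 3))
    n_jumps = np.zeros(n_walkers, dtype=int)
    axes = np.eye(3)
    for f in range(n_frames):
        if f > 0 and p_jump > 0:
            hop = rng.random(n_walkers) < p_jump
            if np.any(hop):
                n_jumps[hop] += 1
                axis = rng.integers(0, 3, size=int(hop.sum()))
                sign = rng.choice([-1.0, 1.0], size=int(hop.sum()))
                sites[hop] += sign[:, None] * axes[axis] * site_spacing
        positions[f] = sites + libration_sigma * rng.standard_normal((n_walkers, 3))
    positions %= box_vec
    traj = Trajectory(
        timestep=timestep,
        boxes=np.tile(box_vec, (n_frames, 1)),
        positions=positions,
    )
    top = Topology(
        index=np.arange(n_walkers),
        molecule_id=np.arange(n_walkers),
        molecule_type=np.array(["WAT"] * n_walkers, dtype=object),
        role=np.array(["OW"] * n_walkers, dtype=object),
    )
    truth = {
        "kind": "trap_jump",
        "site_spacing": site_spacing,
        "mean_residence": mean_residence,
        "libration_sigma": libration_sigma,
        "n_jumps": n_jumps,
        "seed": seed,
    }
    return traj, top, truth


# --------------------------------------------------------------------------
# SANS


def gen_sans_curve(
    q,
    Rg: float,
    v: float,
    scale: float,
    background: float,
    noise_frac: float,
    seed: int,
) -> tuple[CurveTable, dict]:
    """I(q) = scale·P(q; Rg, v) + background with multiplicative noise."""
    q = np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    clean = scale * excluded_volume_form_factor(q, Rg, v) + background
    err = np.maximum(noise_frac * clean, 1e-12 * max(scale, 1.0))
    noisy = clean + err * rng.standard_normal(len(q)) if noise_frac > 0 else clean
    curve = CurveTable(x=q, y=noisy, err=err, metadata={"label": "synthetic I(q)"})
    truth = {
        "kind": "sans_curve",
        "Rg": Rg,
        "v": v,
        "scale": scale,
        "background": background,
        "noise_frac": noise_frac,
        "seed": seed,
    }
    return curve, truth


def gen_contrast_series(
    fractions,
    target_fraction: float = 0.66,
    contrast_split: float = 0.0,
    phi_PEG: float = 0.014,
    n_chains: float = 1e-6,
    v_chain: float = 3000.0,
    noise_frac: float = 0.0,
    seed: int = 0,
    q_probe: float = 0.01,
) -> tuple[CurveTable, dict]:
    """Contrast-variation series I(f_D2O) with a constructed match point.

    The solvent SLD interpolates linearly between light and heavy water;
    the equimolar d/h chain pair is built so that its φ-averaged SLD equals
    the solvent SLD at ``target_fraction`` (ρ_avg ± ``contrast_split`` for
    the two species). With the default zero split the intensity is a
    perfect square in the fraction, so √I is exactly piecewise linear and
    vanishes at the match point; a positive split adds the non-vanishing
    single-chain floor seen in real contrast series. Intensity is
    evaluated at a single low q with unit form factors.
    """
    fractions = np.asarray(fractions, dtype=float)
    rng = np.random.default_rng(seed)
    rho_avg = target_fraction * _RHO_D2O + (1 - target_fraction) * _RHO_H2O
    rho_d = SLD(rho_avg + contrast_split, "d-chain")
    rho_h = SLD(rho_avg - contrast_split, "h-chain")
    intensities = []
    for f in fractions:
        rho_s = SLD(f * _RHO_D2O + (1 - f) * _RHO_H2O, f"solvent f_D2O={f:g}")
        model = ContrastModel(
            rho_d=rho_d,
            rho_h=rho_h,
            rho_s=rho_s,
            phi_dPEG=phi_PEG / 2,
            phi_hPEG=phi_PEG / 2,
            phi_D2O=(1 - phi_PEG) * f,
            phi_H2O=(1 - phi_PEG) * (1 - f),
            n_chains=n_chains,
            v_chain=v_chain,
        )
        intensities.append(float(zac_intensity(model, q_probe)[0]))
    I = np.array(intensities)
    err = np.maximum(noise_frac * I, 1e-15)
    noisy = np.abs(I + err * rng.standard_normal(len(I))) if noise_frac > 0 else I
    curve = CurveTable(x=fractions, y=noisy, err=err, metadata={"label": "contrast series"})
    truth = {
        "kind": "contrast_series",
        "f_match": target_fraction,
        "rho_d": rho_d.value,
        "rho_h": rho_h.value,
        "noise_frac": noise_frac,
        "seed": seed,
    }
    return curve, truth


# --------------------------------------------------------------------------
# two-phase boxes


def gen_two_phase_box(
    water_fraction: float,
    geometry: str,
    box: float,
    n_water_points: int,
    seed: int,
    sphere_radius: float = 5.0,
    water_radius: float = 1.7,
    n_truth_samples: int = 20000,
):
    """Water-point frame occupying a stated sub-volume of a cubic box.

    ``geometry`` is ``"slab"`` (points uniform in z < fraction·L) or
    ``"spheres"`` (points uniform in non-overlapping spheres of
    ``sphere_radius`` whose total volume approximates the fraction). The
    truth record carries the nominal fraction and a deterministic
    Monte-Carlo measurement of the fraction of the box actually covered by
    the union of ``water_radius`` spheres around the points.

    Returns (positions, Topology, truth).
    """
    if not (0.0 < water_fraction <= 1.0):
        raise ValueError("water_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    L = float(box)
    if geometry == "slab":
        # regular grid so the union of water_radius spheres tiles the slab:
        # a plane of points with spacing s fully covers down to
        # sqrt(w² − s²/2) below it, so insetting the grid by exactly that
        # depth makes the covered region ≈ the nominal slab [0, f·L]
        thickness = water_fraction * L
        s = (L * L * thickness / max(n_water_points, 8)) ** (1.0 / 3.0)
        if s >= water_radius * math.sqrt(2.0):
            raise ValueError("too few water points to tile the slab at this water_radius")
        d_full = math.sqrt(water_radius**2 - s**2 / 2.0)
        z_lo, z_hi = d_full, thickness - d_full
        if z_hi <= z_lo:
            raise ValueError("slab thinner than twice the water radius")
        nx = max(int(round(L / s)), 1)
        nz = max(int(round((z_hi - z_lo) / s)) + 1, 2)
        gx = (np.arange(nx) + 0.5) * (L / nx)
        gz = np.linspace(z_lo, z_hi, nz)
        X, Y, Z = np.meshgrid(gx, gx, gz, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        pts += rng.normal(0.0, 0.03 * s, size=pts.shape)
        pts %= L
        centers = None
    elif geometry == "spheres":
        target_vol = water_fraction * L**3
        sphere_vol = 4.0 / 3.0 * math.pi * sphere_radius**3
        n_spheres = max(int(round(target_vol / sphere_vol)), 1)
        centers = []
        attempts = 0
        while len(centers) < n_spheres and attempts < 20000:
            attempts += 1
            c = rng.uniform(0.0, L, size=3)
            ok = all(
                np.linalg.norm((c - o) - L * np.round((c - o) / L)) >= 2 * sphere_radius
                for o in centers
            )
            if ok:
                centers.append(c)
        centers = np.array(centers)
        per = max(n_water_points // len(centers), 1)
        inner = max(sphere_radius - water_radius, 0.1 * sphere_radius)
        direc = rng.normal(size=(len(centers), per, 3))
        direc /= np.linalg.norm(direc, axis=2, keepdims=True)
        radial = inner * rng.uniform(size=(len(centers), per, 1)) ** (1 / 3)
        pts = (centers[:, None, :] + direc * radial).reshape(-1, 3) % L
    else:
        raise ValueError("geometry must be 'slab' or 'spheres'")
    n = len(pts)
    top = Topology(
        index=np.arange(n),
        molecule_id=np.arange(n),
        molecule_type=np.array(["WAT"] * n, dtype=object),
        role=np.array(["OW"] * n, dtype=object),
    )
    tree = cKDTree(pts % L, boxsize=[L, L, L])
    samples = rng.uniform(0.0, L, size=(n_truth_samples, 3))
    d, _ = tree.query(samples, k=1)
    measured = float(np.mean(d <= water_radius))
    truth = {
        "kind": "two_phase_box",
        "geometry": geometry,
        "nominal_fraction": water_fraction,
        "measured_fraction": measured,
        "sphere_radius": sphere_radius if geometry == "spheres" else None,
        "water_radius": water_radius,
        "seed": seed,
    }
    return pts, top, truth


# --------------------------------------------------------------------------
# elastic scans


def gen_elastic_scan(
    T_grid,
    u2_slope_low: float,
    u2_slope_high: float,
    T_break: float,
    noise: float = 0.0,
    seed: int = 0,
    q_set=(0.5, 1.0, 1.5),
) -> tuple[ElasticScan, dict]:
    """Bilinear harmonic/inharmonic elastic scan.

    The mean-squared displacement ⟨u²⟩(T) grows piecewise-linearly in T
    (slopes in Å²/K) with a break at ``T_break``; the scan is the q-set
    average of exp(−q²⟨u²⟩/3), normalized to the lowest temperature after
    optional additive Gaussian noise.
    """
    T = np.asarray(T_grid, dtype=float)
    if u2_slope_low < 0 or u2_slope_high < 0:
        raise ValueError("slopes must be non-negative")
    if not (T[0] < T_break < T[-1]):
        raise ValueError("break must lie inside the temperature grid")
    rng = np.random.default_rng(seed)
    u2 = np.where(
        T <= T_break,
        u2_slope_low * T,
        u2_slope_low * T_break + u2_slope_high * (T - T_break),
    )
    qs = np.asarray(q_set, dtype=float)
    intensity = np.mean(np.exp(-np.outer(qs**2, u2) / 3.0), axis=0)
    if noise > 0:
        intensity = intensity + noise * rng.standard_normal(len(T))
    intensity = intensity / intensity[0]
    scan = ElasticScan(
        temperatures=T,
        intensity=intensity,
        q_range=(float(qs.min()), float(qs.max())),
        energy_window=math.nan,
    )
    truth = {
        "kind": "elastic_scan",
        "T_break": T_break,
        "u2_slope_low": u2_slope_low,
        "u2_slope_high": u2_slope_high,
        "noise": noise,
        "seed": seed,
    }
    return scan, truth


_GENERATORS = {
    "kww_spectra": gen_kww_spectra,
    "telegraph": gen_telegraph,
    "trap_jump": gen_trap_jump_trajectory,
    "sans_curve": gen_sans_curve,
    "contrast_series": gen_contrast_series,
    "two_phase_box": gen_two_phase_box,
    "elastic_scan": gen_elastic_scan,
}
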