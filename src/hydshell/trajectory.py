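"""Hydration-shell observables from MD-style trajectories.

Implements the trajectory-derived quantities used to characterise water
around a hydrophilic polymer:

* geometric hydrogen-bond detection (donor–acceptor distance and
  O–H···O angle at the hydrogen) and its intermittent/continuous time
  correlation functions C(t) and S(t), whose 1/e times are the structural
  relaxation time τ_R and the bond lifetime τ_HB;
* oxygen–oxygen radial distribution functions;
* the self (incoherent) intermediate scattering function of tagged atoms;
* the water volume-distribution function V(r) — the average fraction of a
  probe sphere of radius r, centred inside the water region, that is
  itself water — whose initial-slope x-intercept is the confining length
  of a water pool and whose large-r asymptote is the water volume
  fraction;
* mean-squared displacement with coarse-grained jump/residence
  statistics for the trap-and-jump (trapping-site diffusion) picture.

All geometry uses orthorhombic periodic boxes and the minimum-image
convention; ISF/MSD unwrap coordinates by accumulating per-step
minimum-image displacements (valid while per-frame moves stay below half
the box).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import CurveTable, Topology, Trajectory
from .qens import ISFCurve

__all__ = [
    "HBondCriterion",
    "HBondSeries",
    "CorrelationCurve",
    "RDFResult",
    "VolumeDistribution",
    "NoCrossingError",
    "minimum_image",
    "find_hbonds",
    "hbond_timeseries",
    "correlation_functions",
    "relax_time_1e",
    "rdf",
    "unwrap_positions",
    "incoherent_isf",
    "water_volume_distribution",
    "confining_length",
    "msd_and_jumps",
]

INV_E = 1.0 / math.e


class NoCrossingError(ValueError):
    """A correlation curve never decays to 1/e inside the sampled window."""

    def __init__(self, message: str, last_value: float):
        super().__init__(message)
        self.last_value = last_value


# --------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    A bond exists when the donor–acceptor O···O distance is at most
    ``max_da_distance`` (Å, default 3.5) and the O–H···O angle measured at
    the hydrogen is at least ``min_angle`` degrees (default 150;
    180° = linear).
    """

    max_da_distance: float = 3.5
    min_angle: float = 150.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not (90.0 < self.min_angle <= 180.0):
            raise ValueError("min_angle must lie in (90, 180]")


@dataclass
class HBondSeries:
    """Per-pair bonded/unbonded time series.

    ``pairs`` lists unique (donor O, H, acceptor O) index triples;
    ``h`` is the pairs × frames 0/1 occupancy matrix; ``timestep`` in ps.
    """

    pairs: list
    h: np.ndarray
    timestep: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h)
        if self.h.size and not np.all((self.h == 0) | (self.h == 1)):
            raise ValueError("h must be binary")
        if len(set(map(tuple, self.pairs))) != len(self.pairs):
            raise ValueError("pairs must be unique")
        if self.h.shape[0] != len(self.pairs):
            raise ValueError("h rows must match pairs")

    @property
    def n_frames(self) -> int:
        return self.h.shape[1]


@dataclass
class CorrelationCurve:
    """C(t) or S(t) with value(0) = 1; ``kind`` tags the estimator."""

    times: np.ndarray
    values: np.ndarray
    kind: str
    tau_1e: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not math.isclose(self.values[0], 1.0, abs_tol=1e-9):
            raise ValueError("correlation curve must start at 1")
        if self.kind == "continuous" and np.any(np.diff(self.values) > 1e-12):
            raise ValueError("continuous correlation must be non-increasing")


@dataclass
class RDFResult:
    r: np.ndarray
    g: np.ndarray
    pair: tuple
    n_frames: int


@dataclass
class VolumeDistribution:
    """Monte-Carlo water volume-distribution function V(r) ∈ [0, 1]."""

    r: np.ndarray
    V: np.ndarray
    V_err: np.ndarray
    n_probe_points: int
    water_radius: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if np.any(self.r <= 0):
            raise ValueError("probe radii must be positive")
        if np.any((self.V < 0) | (self.V > 1)):
            raise ValueError("V must lie in [0, 1]")


# --------------------------------------------------------------------------
# geometry helpers


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return disp - box * np.round(disp / box)


def _donor_hydrogens(top: Topology, donor_o: int) -> np.ndarray:
    mol = top.molecule_id[donor_o]
    mask = (top.molecule_id == mol) & (top.role == "HW")
    return top.index[mask]


def find_hbonds(
    positions: np.ndarray,
    box: np.ndarray,
    top: Topology,
    criterion: HBondCriterion = HBondCriterion(),
    donor_roles=("OW",),
    acceptor_roles=("O_ether",),
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor O, H, acceptor O) triples.

    Default selection is polymer–water: water O–H donates to the polymer
    ether oxygen (the polymer has no hydroxyl hydrogens in the role
    scheme). Water–water bonding is obtained with
    ``acceptor_roles=("OW",)``; intra-molecular pairs are excluded.
    """
    box = np.asarray(box, dtype=float)
    donors = top.select(donor_roles)
    acceptors = top.select(acceptor_roles)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("empty donor or acceptor selection (check role tokens)")
    cos_max = math.cos(math.radians(criterion.min_angle))
    bonds: list[tuple[int, int, int]] = []
    # D–A candidates by distance, then per-hydrogen angle check
    d_pos = positions[donors]
    a_pos = positions[acceptors]
    dvec = minimum_image(d_pos[:, None, :] - a_pos[None, :, :], box)
    dist = np.linalg.norm(dvec, axis=2)
    within = dist <= criterion.max_da_distance
    for i, j in zip(*np.nonzero(within)):
        d_o, a_o = int(donors[i]), int(acceptors[j])
        if d_o == a_o or top.molecule_id[d_o] == top.molecule_id[a_o]:
            continue
        for h in _donor_hydrogens(top, d_o):
            u = minimum_image(positions[d_o] - positions[h], box)
            v = minimum_image(positions[a_o] - positions[h], box)
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0 or nv == 0:
                continue
            # angle ≥ min_angle ⇔ cosθ ≤ cos(min_angle)
            if float(u @ v) / (nu * nv) <= cos_max:
                bonds.append((d_o, int(h), a_o))
    return sorted(bonds)


def hbond_timeseries(
    traj: Trajectory,
    top: Topology,
    criterion: HBondCriterion = HBondCriterion(),
    donor_roles=("OW",),
    acceptor_roles=("O_ether",),
) -> HBondSeries:
    """Bonded/unbonded matrix over all frames.

    The pair universe is every triple bonded in at least one frame; a
    trajectory with no bonds anywhere yields an empty series.
    """
    per_frame = [
        set(
            find_hbonds(
                traj.positions[k], traj.boxes[k], top, criterion, donor_roles, acceptor_roles
            )
        )
        for k in range(traj.n_frames)
    ]
    universe = sorted(set().union(*per_frame)) if per_frame else []
    h = np.zeros((len(universe), traj.n_frames), dtype=np.uint8)
    idx = {p: i for i, p in enumerate(universe)}
    for k, bonds in enumerate(per_frame):
        for p in bonds:
            h[idx[p], k] = 1
    return HBondSeries(pairs=universe, h=h, timestep=traj.timestep)


def correlation_functions(
    series: HBondSeries, max_lag: int
) -> tuple[CorrelationCurve, CorrelationCurve]:
    """Intermittent C(t) and continuous S(t) bond correlators.

    Multiple-time-origin estimators with a fixed origin window
    t0 ∈ [0, T−1−max_lag] (the same origins for every lag, so both curves
    equal 1 at t = 0 exactly and S is monotone):

        C(t) = Σ_{p,t0} h_p(t0)·h_p(t0+t) / Σ_{p,t0} h_p(t0)
        S(t) = Σ_{p,t0} Π_{t'=t0..t0+t} h_p(t') / Σ_{p,t0} h_p(t0)
    """
    h = series.h
    T = series.n_frames
    if T < 2:
        raise ValueError("need at least 2 frames")
    if not (1 <= max_lag <= T - 1):
        raise ValueError("max_lag must lie in [1, n_frames-1]")
    n_orig = T - max_lag
    origins = h[:, :n_orig].astype(np.float64)
    denom = float(origins.sum())
    if denom == 0:
        raise ValueError("mean bond occupancy is zero over the origin window")
    C = np.empty(max_lag + 1)
    S = np.empty(max_lag + 1)
    prod = origins.copy()
    for lag in range(max_lag + 1):
        shifted = h[:, lag : lag + n_orig]
        C[lag] = float((origins * shifted).sum()) / denom
        if lag > 0:
            prod *= shifted
        S[lag] = float(prod.sum()) / denom
    times = np.arange(max_lag + 1) * series.timestep
    c_curve = CorrelationCurve(times=times, values=C, kind="intermittent")
    s_curve = CorrelationCurve(times=times, values=S, kind="continuous")
    for curve in (c_curve, s_curve):
        try:
            curve.tau_1e = relax_time_1e(curve)
        except NoCrossingError:
            curve.tau_1e = None
    return c_curve, s_curve


def relax_time_1e(curve: CorrelationCurve) -> float:
    """Relaxation time: first crossing of 1/e, linearly interpolated."""
    v = curve.values
    t = curve.times
    if not math.isclose(v[0], 1.0, abs_tol=1e-9):
        raise ValueError("curve must start at 1")
    below = np.flatnonzero(v <= INV_E)
    if below.size == 0:
        raise NoCrossingError(
            f"correlation never decays to 1/e in the sampled window (last value {v[-1]:.4f})",
            last_value=float(v[-1]),
        )
    i = int(below[0])
    if i == 0:
        return float(t[0])
    frac = (v[i - 1] - INV_E) / (v[i - 1] - v[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


# --------------------------------------------------------------------------
# radial distribution function


def rdf(
    traj: Trajectory,
    top: Topology,
    species_pair=("OW", "OW"),
    dr: float = 0.05,
    r_max: float = 10.0,
) -> RDFResult:
    """Minimum-image pair histogram normalized by ideal-gas shell counts.

    Same-species pairs are counted once (i < j); distinct species count
    every A–B pair. ``r_max`` must not exceed half the smallest box edge.
    """
    role_a, role_b = species_pair
    sel_a = top.select(role_a)
    sel_b = top.select(role_b)
    if sel_a.size == 0:
        raise ValueError(f"empty selection for species '{role_a}'")
    if sel_b.size == 0:
        raise ValueError(f"empty selection for species '{role_b}'")
    min_edge = float(np.min(traj.boxes))
    if r_max > 0.5 * min_edge + 1e-9:
        raise ValueError(f"r_max={r_max} exceeds half the smallest box edge ({min_edge / 2})")
    edges = np.arange(0.0, r_max + dr, dr)
    n_bins = len(edges) - 1
    g_acc = np.zeros(n_bins)
    same = role_a == role_b
    for k in range(traj.n_frames):
        box = traj.boxes[k]
        vol = float(np.prod(box))
        pos_a = traj.positions[k, sel_a] % box
        if same:
            tree = cKDTree(pos_a, boxsize=box)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            if len(pairs):
                d = minimum_image(pos_a[pairs[:, 0]] - pos_a[pairs[:, 1]], box)
                dist = np.linalg.norm(d, axis=1)
            else:
                dist = np.empty(0)
            n_pairs_ideal = len(sel_a) * (len(sel_a) - 1) / 2.0
        else:
            pos_b = traj.positions[k, sel_b] % box
            tree_a = cKDTree(pos_a, boxsize=box)
            tree_b = cKDTree(pos_b, boxsize=box)
            mat = tree_a.sparse_distance_matrix(tree_b, r_max, output_type="coo_matrix")
            dist = mat.data
            n_pairs_ideal = float(len(sel_a) * len(sel_b))
        hist, _ = np.histogram(dist, bins=edges)
        shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ideal = n_pairs_ideal * shell_vol / vol
        with np.errstate(divide="ignore", invalid="ignore"):
            g_acc += np.where(ideal > 0, hist / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g_acc / traj.n_frames, pair=(role_a, role_b), n_frames=traj.n_frames)


# --------------------------------------------------------------------------
# self ISF and MSD


def unwrap_positions(traj: Trajectory, selection=None) -> np.ndarray:
    """Remove periodic wrapping by accumulating minimum-image steps.

    Valid while no atom moves more than half a box edge per frame.
    Returns (n_frames, n_sel, 3).
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    pos = traj.positions[:, sel, :]
    out = np.empty_like(pos)
    out[0] = pos[0]
    for k in range(1, traj.n_frames):
        step = minimum_image(pos[k] - pos[k - 1], traj.boxes[k])
        out[k] = out[k - 1] + step
    return out


def incoherent_isf(
    traj: Trajectory,
    top: Topology,
    selection_roles=("OW",),
    q_values=(1.0,),
    max_lag: int | None = None,
) -> list[ISFCurve]:
    """Self intermediate scattering function of selected atoms.

    Isotropically averaged: F(q, t) = ⟨ sinc(q·|Δr(t)|) ⟩ over atoms and
    all time origins, on unwrapped coordinates. One curve per q.
    """
    q_values = np.atleast_1d(np.asarray(q_values, dtype=float))
    if np.any(q_values <= 0):
        raise ValueError("q must be positive")
    sel = top.select(selection_roles)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    unw = unwrap_positions(traj, sel)
    T = traj.n_frames
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    F = np.ones((len(q_values), max_lag + 1))
    for lag in range(1, max_lag + 1):
        disp = unw[lag:] - unw[:-lag]
        dist = np.linalg.norm(disp, axis=2).ravel()
        for iq, q in enumerate(q_values):
            F[iq, lag] = float(np.mean(np.sinc(q * dist / math.pi)))
    times = np.arange(max_lag + 1) * traj.timestep
    return [
        ISFCurve(q=float(q), times=times, F=F[iq], metadata={"source": "trajectory"})
        for iq, q in enumerate(q_values)
    ]


def msd_and_jumps(
    traj: Trajectory,
    selection,
    coarse_window: int,
    jump_threshold: float,
    max_lag: int | None = None,
):
    """Mean-squared displacement plus trap-and-jump statistics.

    MSD(t) uses multiple origins on unwrapped coordinates. Positions are
    then coarse-grained by block averaging over ``coarse_window`` frames;
    a coarse displacement larger than ``jump_threshold`` (Å) between
    consecutive blocks counts as a jump, and residence times are the
    uncensored inter-jump durations (ps).

    Returns (msd_curve, jump_counts, residence_times).
    """
    if coarse_window < 2:
        raise ValueError("coarse_window must be at least 2 frames")
    if jump_threshold <= 0:
        raise ValueError("jump_threshold must be positive")
    sel = np.asarray(selection, dtype=int)
    unw = unwrap_positions(traj, sel)
    T = traj.n_frames
    if max_lag is None:
        max_lag = min(T - 1, 200)
    max_lag = min(max_lag, T - 1)
    msd = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        disp = unw[lag:] - unw[:-lag]
        msd[lag] = float(np.mean(np.sum(disp**2, axis=2)))
    times = np.arange(max_lag + 1) * traj.timestep
    msd_curve = CurveTable(x=times, y=msd, metadata={"kind": "msd", "timestep": traj.timestep})
    n_blocks = T // coarse_window
    jump_counts = np.zeros(len(sel), dtype=int)
    residences: list[float] = []
    block_dt = coarse_window * traj.timestep
    if n_blocks >= 2:
        blocks = unw[: n_blocks * coarse_window].reshape(n_blocks, coarse_window, len(sel), 3)
        coarse = blocks.mean(axis=1)  # (n_blocks, n_sel, 3)
        step = np.linalg.norm(np.diff(coarse, axis=0), axis=2)  # (n_blocks-1, n_sel)
        jumps = step > jump_threshold
        jump_counts = jumps.sum(axis=0)
        for a in range(len(sel)):
            where = np.flatnonzero(jumps[:, a])
            if len(where) >= 2:
                residences.extend((np.diff(where) * block_dt).tolist())
    return msd_curve, jump_counts, np.asarray(residences, dtype=float)


# --------------------------------------------------------------------------
# water volume distribution


def water_volume_distribution(
    positions: np.ndarray,
    box: np.ndarray,
    top: Topology,
    radii,
    water_radius: float = 1.7,
    n_probes: int = 200,
    n_sphere_samples: int = 128,
    seed: int | None = None,
) -> VolumeDistribution:
    """Monte-Carlo volume-distribution function of the water region.

    The water region is the periodic union of spheres of ``water_radius``
    around the water oxygens. Probe centres are drawn uniformly inside the
    region (rejection sampling); for each probe radius r, V(r) is the mean
    fraction of ``n_sphere_samples`` points, uniform in the radius-r
    sphere around each centre, that fall inside the region. ``V_err`` is
    the standard error over probe centres.
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("probe radii must be positive")
    box = np.asarray(box, dtype=float)
    water_o = top.select("OW")
    if water_o.size == 0:
        raise ValueError("no water oxygen atoms in the topology")
    rng = np.random.default_rng(seed)
    wpos = positions[water_o] % box
    tree = cKDTree(wpos, boxsize=box)

    def inside(points: np.ndarray) -> np.ndarray:
        d, _ = tree.query(points % box, k=1)
        return d <= water_radius

    centers = np.empty((0, 3))
    attempts = 0
    while len(centers) < n_probes:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not sample probe centres inside the water region")
        cand = rng.uniform(0.0, 1.0, size=(4 * n_probes, 3)) * box
        keep = cand[inside(cand)]
        centers = np.vstack([centers, keep])[:n_probes]

    V = np.empty(len(radii))
    V_err = np.empty(len(radii))
    for ir, r in enumerate(radii):
        # uniform points in a radius-r sphere around every centre
        direc = rng.normal(size=(n_probes, n_sphere_samples, 3))
        direc /= np.linalg.norm(direc, axis=2, keepdims=True)
        radial = r * rng.uniform(0.0, 1.0, size=(n_probes, n_sphere_samples, 1)) ** (1.0 / 3.0)
        pts = centers[:, None, :] + direc * radial
        frac = inside(pts.reshape(-1, 3)).reshape(n_probes, n_sphere_samples).mean(axis=1)
        V[ir] = float(frac.mean())
        V_err[ir] = float(frac.std(ddof=1) / math.sqrt(n_probes)) if n_probes > 1 else 0.0
    return VolumeDistribution(
        r=radii, V=V, V_err=V_err, n_probe_points=n_probes, water_radius=water_radius
    )


def confining_length(vd: VolumeDistribution, small_r_window: tuple[float, float]) -> float:
    """Confining length: x-intercept of the initial linear decay of V(r)."""
    lo, hi = small_r_window
    mask = (vd.r >= lo) & (vd.r <= hi)
    r = vd.r[mask]
    V = vd.V[mask]
    if len(r) < 3:
        raise ValueError("need at least 3 points in the small-r window")
    X = np.column_stack([np.ones_like(r), r])
    (a, b), *_ = np.linalg.lstsq(X, V, rcond=None)
    if b >= 0:
        raise ValueError("V(r) does not decay over the window (non-negative slope)")
    return float(-a / b)
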