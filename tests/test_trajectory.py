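"""H-bond detection/correlators, RDF, self-ISF, volume distribution, jumps."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from hydshell.io import Topology
from hydshell.trajectory import (
    CorrelationCurve,
    HBondCriterion,
    HBondSeries,
    NoCrossingError,
    confining_length,
    correlation_functions,
    find_hbonds,
    hbond_timeseries,
    incoherent_isf,
    minimum_image,
    msd_and_jumps,
    rdf,
    relax_time_1e,
    water_volume_distribution,
)
from hydshell.synth import (
    gen_telegraph,
    gen_trap_jump_trajectory,
    gen_two_phase_box,
)

from conftest import make_trajectory, walker_topology


def _water_peg_topology(n_water, n_ether):
    """n_water three-site waters followed by n_ether lone ether oxygens."""
    idx, mid, mtype, role = [], [], [], []
    a = 0
    for w in range(n_water):
        for r in ("OW", "HW", "HW"):
            idx.append(a); mid.append(w); mtype.append("WAT"); role.append(r)
            a += 1
    for e in range(n_ether):
        idx.append(a); mid.append(n_water + e); mtype.append("PEG"); role.append("O_ether")
        a += 1
    return Topology(
        index=np.array(idx),
        molecule_id=np.array(mid),
        molecule_type=np.array(mtype, dtype=object),
        role=np.array(role, dtype=object),
    )


class TestFindHbonds:
    box = np.array([20.0, 20.0, 20.0])

    def _frame(self, d_oa):
        """Collinear O_d–H···O_a along x with the given O···O distance."""
        top = _water_peg_topology(1, 1)
        pos = np.zeros((4, 3))
        pos[0] = [5.0, 5.0, 5.0]          # OW
        pos[1] = [6.0, 5.0, 5.0]          # HW on the bond axis
        pos[2] = [5.0, 5.8, 5.0]          # second HW, points away
        pos[3] = [5.0 + d_oa, 5.0, 5.0]   # ether O acceptor
        return pos, top

    def test_ideal_collinear_geometry_is_bonded(self):
        pos, top = self._frame(2.8)
        assert find_hbonds(pos, self.box, top) == [(0, 1, 3)]

    def test_distance_cut(self):
        pos, top = self._frame(3.6)
        assert find_hbonds(pos, self.box, top) == []

    def test_angle_cut(self):
        pos, top = self._frame(2.8)
        pos[1] = [5.5, 5.9, 5.0]  # bent O–H···O well below 150°
        assert find_hbonds(pos, self.box, top) == []

    def test_bond_across_periodic_boundary(self):
        pos, top = self._frame(2.8)
        shift = np.array([14.8, 0.0, 0.0])
        pos[3] = (pos[3] + shift) % self.box  # image distance unchanged
        pos[3] = pos[0] - np.array([2.8, 0, 0]) + self.box * np.array([1, 0, 0])
        pos[3] %= self.box
        pos[1] = pos[0] - np.array([1.0, 0, 0])  # H now points toward the image
        bonds = find_hbonds(pos, self.box, top)
        assert bonds == [(0, 1, 3)]

    def test_matches_brute_force_all_images_oracle(self, rng):
        """Random crowded frame vs an explicit 27-image reference check."""
        n_water, n_ether = 12, 8
        top = _water_peg_topology(n_water, n_ether)
        box = np.array([10.0, 10.0, 10.0])
        pos = np.empty((len(top), 3))
        a = 0
        for w in range(n_water):
            o = rng.uniform(0, 10, 3)
            pos[a] = o
            for k in (1, 2):
                d = rng.normal(size=3)
                pos[a + k] = o + d / np.linalg.norm(d)
            a += 3
        pos[a:] = rng.uniform(0, 10, size=(n_ether, 3))
        crit = HBondCriterion()
        result = set(find_hbonds(pos, box, top, crit))

        shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
        expected = set()
        donors = top.select("OW")
        acceptors = top.select("O_ether")
        for d_o in donors:
            hs = top.index[(top.molecule_id == top.molecule_id[d_o]) & (top.role == "HW")]
            for a_o in acceptors:
                images = pos[a_o] + shifts * box
                dists = np.linalg.norm(images - pos[d_o], axis=1)
                best = np.argmin(dists)
                if dists[best] > crit.max_da_distance:
                    continue
                acc = images[best]
                for h in hs:
                    # H may also sit in a periodic image: take its nearest image
                    h_images = pos[h] + shifts * box
                    h_pos = h_images[np.argmin(np.linalg.norm(h_images - pos[d_o], axis=1))]
                    u = pos[d_o] - h_pos
                    v = acc - h_pos
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= crit.min_angle:
                        expected.add((int(d_o), int(h), int(a_o)))
        assert result == expected


class TestHbondTimeseries:
    def test_static_bonded_frame(self):
        top = _water_peg_topology(1, 1)
        pos = np.zeros((4, 3))
        pos[0] = [5, 5, 5]; pos[1] = [6, 5, 5]; pos[2] = [5, 5.8, 5]; pos[3] = [7.8, 5, 5]
        traj = make_trajectory(np.repeat(pos[None], 10, axis=0), 20.0)
        series = hbond_timeseries(traj, top)
        assert series.pairs == [(0, 1, 3)]
        np.testing.assert_array_equal(series.h, np.ones((1, 10)))

    def test_toggling_bond_alternates(self):
        top = _water_peg_topology(1, 1)
        frames = []
        for k in range(6):
            pos = np.zeros((4, 3))
            pos[0] = [5, 5, 5]; pos[2] = [5, 5.8, 5]; pos[3] = [7.8, 5, 5]
            pos[1] = [6, 5, 5] if k % 2 == 0 else [5, 4.0, 5]  # swing H away
            frames.append(pos)
        series = hbond_timeseries(make_trajectory(np.array(frames), 20.0), top)
        np.testing.assert_array_equal(series.h, [[1, 0, 1, 0, 1, 0]])

    def test_no_bonds_gives_empty_series(self):
        top = _water_peg_topology(1, 1)
        pos = np.zeros((4, 3))
        pos[0] = [1, 1, 1]; pos[1] = [2, 1, 1]; pos[2] = [1, 2, 1]; pos[3] = [10, 10, 10]
        series = hbond_timeseries(make_trajectory(pos[None], 30.0), top)
        assert series.pairs == [] and series.h.shape == (0, 1)


def _brute_force_correlators(h, max_lag):
    """Origin-enumeration oracle for C(t) and S(t) with fixed origins."""
    n_pairs, T = h.shape
    n_orig = T - max_lag
    denom = sum(h[p, t0] for p in range(n_pairs) for t0 in range(n_orig))
    C, S = [], []
    for lag in range(max_lag + 1):
        c = s = 0.0
        for p in range(n_pairs):
            for t0 in range(n_orig):
                c += h[p, t0] * h[p, t0 + lag]
                s += np.prod(h[p, t0 : t0 + lag + 1])
        C.append(c / denom)
        S.append(s / denom)
    return np.array(C), np.array(S)


class TestCorrelators:
    def test_permanent_bond(self):
        series = HBondSeries(pairs=[(0, 0, 0)], h=np.ones((1, 12), dtype=np.uint8), timestep=1.0)
        C, S = correlation_functions(series, 6)
        np.testing.assert_allclose(C.values, 1.0)
        np.testing.assert_allclose(S.values, 1.0)

    def test_hand_series_against_enumeration_oracle(self):
        h = np.array([[1, 1, 0, 1]], dtype=np.uint8)
        series = HBondSeries(pairs=[(0, 0, 0)], h=h, timestep=1.0)
        C, S = correlation_functions(series, 2)
        C_exp, S_exp = _brute_force_correlators(h, 2)
        np.testing.assert_allclose(C.values, C_exp)
        np.testing.assert_allclose(S.values, S_exp)
        # frozen values from the oracle: origins {0,1}, denom = 2
        np.testing.assert_allclose(C.values, [1.0, 0.5, 0.5])
        np.testing.assert_allclose(S.values, [1.0, 0.5, 0.0])

    def test_random_series_against_enumeration_oracle(self, rng):
        h = (rng.random((3, 40)) < 0.6).astype(np.uint8)
        series = HBondSeries(pairs=[(i, i, i) for i in range(3)], h=h, timestep=0.5)
        C, S = correlation_functions(series, 15)
        C_exp, S_exp = _brute_force_correlators(h, 15)
        np.testing.assert_allclose(C.values, C_exp)
        np.testing.assert_allclose(S.values, S_exp)

    def test_telegraph_closed_forms(self):
        k = 0.01  # 1/ps, k_on = k_off
        series, truth = gen_telegraph(k, k, n_frames=60000, timestep=1.0, n_pairs=30, seed=11)
        max_lag = 400
        C, S = correlation_functions(series, max_lag)
        t = C.times
        p = truth["p_eq"]
        C_theory = p + (1 - p) * np.exp(-(2 * k) * t)
        S_theory = np.exp(-k * t)
        assert math.sqrt(np.mean((C.values - C_theory) ** 2)) < 0.02
        mask = t <= 200.0  # survival statistics degrade deep in the tail
        assert math.sqrt(np.mean((S.values[mask] - S_theory[mask]) ** 2)) < 0.02

    def test_intermittent_dominates_continuous(self, rng):
        for seed in range(3):
            series, _ = gen_telegraph(0.02, 0.01, 3000, 1.0, 10, seed=seed)
            C, S = correlation_functions(series, 500)
            assert np.all(C.values - S.values >= -1e-12)
            if C.tau_1e is not None and S.tau_1e is not None:
                assert C.tau_1e >= S.tau_1e

    def test_empty_occupancy_is_error(self):
        series = HBondSeries(pairs=[(0, 0, 0)], h=np.zeros((1, 10), dtype=np.uint8), timestep=1.0)
        with pytest.raises(ValueError, match="zero"):
            correlation_functions(series, 4)


class TestRelaxTime:
    def test_exponential(self):
        t = np.linspace(0, 30, 301)
        curve = CorrelationCurve(times=t, values=np.exp(-t / 5.0), kind="continuous")
        assert relax_time_1e(curve) == pytest.approx(5.0, abs=0.01)

    def test_hand_interpolation(self):
        curve = CorrelationCurve(
            times=[0.0, 4.0, 6.0], values=[1.0, 0.40, 0.30], kind="intermittent"
        )
        expected = 4.0 + 2.0 * (0.40 - 1 / math.e) / 0.10
        assert relax_time_1e(curve) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(4.64, abs=0.01)

    def test_floored_curve_errors(self):
        t = np.linspace(0, 10, 11)
        v = np.maximum(np.exp(-t), 0.5)
        with pytest.raises(NoCrossingError):
            relax_time_1e(CorrelationCurve(times=t, values=v, kind="intermittent"))


class TestRdf:
    def test_poisson_gas_is_flat(self, rng):
        n, box, frames = 500, 20.0, 50
        pos = rng.uniform(0, box, size=(frames, n, 3))
        traj = make_trajectory(pos, box)
        res = rdf(traj, walker_topology(n), ("OW", "OW"), dr=0.25, r_max=9.0)
        mask = res.r > 2.0
        np.testing.assert_allclose(res.g[mask], 1.0, atol=0.05)

    def test_single_pair_hand_normalization(self):
        box = 40.0
        pos = np.array([[[5.0, 5.0, 5.0], [8.0, 5.0, 5.0]]])
        traj = make_trajectory(pos, box)
        res = rdf(traj, walker_topology(2), ("OW", "OW"), dr=0.2, r_max=10.0)
        occupied = np.flatnonzero(res.g)
        assert len(occupied) == 1
        i = occupied[0]
        assert abs(res.r[i] - 3.0) < 0.2
        edges_lo = res.r[i] - 0.1
        shell = 4 / 3 * math.pi * ((edges_lo + 0.2) ** 3 - edges_lo**3)
        expected = 1.0 / (1.0 * shell / box**3)  # one pair, ideal = pairs·Vshell/V
        assert res.g[i] == pytest.approx(expected, rel=1e-6)

    def test_empty_selection_names_species(self):
        traj = make_trajectory(np.zeros((1, 2, 3)) + 1.0, 10.0)
        with pytest.raises(ValueError, match="O_ether"):
            rdf(traj, walker_topology(2), ("OW", "O_ether"), dr=0.1, r_max=4.0)

    def test_rmax_beyond_half_box(self):
        traj = make_trajectory(np.zeros((1, 2, 3)) + 1.0, 10.0)
        with pytest.raises(ValueError, match="half"):
            rdf(traj, walker_topology(2), ("OW", "OW"), dr=0.1, r_max=6.0)


class TestIncoherentIsf:
    def test_frozen_atoms_give_unity(self):
        pos = np.repeat(np.array([[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]]), 8, axis=0)
        traj = make_trajectory(pos, 10.0)
        curves = incoherent_isf(traj, walker_topology(2), ("OW",), [0.7, 1.4], max_lag=5)
        for c in curves:
            np.testing.assert_allclose(c.F, 1.0)

    def test_free_diffusion_gaussian_decay(self, rng):
        D, dt, box = 0.1, 0.5, 50.0
        n_walkers, n_frames = 300, 800
        steps = rng.normal(0, math.sqrt(2 * D * dt), size=(n_frames, n_walkers, 3))
        steps[0] = rng.uniform(0, box, size=(n_walkers, 3))
        pos = np.cumsum(steps, axis=0)
        traj = make_trajectory(pos, box, timestep=dt)
        (curve,) = incoherent_isf(traj, walker_topology(n_walkers), ("OW",), [1.0], max_lag=120)
        theory = np.exp(-(1.0**2) * D * curve.times)
        assert math.sqrt(np.mean((curve.F - theory) ** 2)) < 0.02

    def test_single_jump_plateau(self):
        box, d, T, k_jump = 30.0, 3.0, 12, 6
        pos = np.zeros((T, 1, 3)) + 5.0
        pos[k_jump:, 0, 0] += d
        traj = make_trajectory(pos, box, timestep=1.0)
        q = 1.0
        (curve,) = incoherent_isf(traj, walker_topology(1), ("OW",), [q], max_lag=T - 1)
        # exhaustive origin oracle
        for lag in range(1, T - 1):
            n_orig = T - lag
            n_straddle = sum(1 for t0 in range(n_orig) if t0 < k_jump <= t0 + lag)
            expected = (n_orig - n_straddle + n_straddle * math.sin(q * d) / (q * d)) / n_orig
            assert curve.F[lag] == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_q(self):
        traj = make_trajectory(np.zeros((2, 1, 3)) + 1.0, 10.0)
        with pytest.raises(ValueError, match="positive"):
            incoherent_isf(traj, walker_topology(1), ("OW",), [0.0])


class TestVolumeDistribution:
    def test_fully_wet_box(self, rng):
        box = 12.0
        grid = np.linspace(0.5, box - 0.5, 8)
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        vd = water_volume_distribution(
            pts, np.full(3, box), walker_topology(len(pts)), [1.0, 3.0, 6.0],
            water_radius=2.0, n_probes=50, seed=5,
        )
        np.testing.assert_allclose(vd.V, 1.0, atol=1e-12)

    def test_slab_asymptote_matches_constructed_fraction(self):
        box = 20.0
        pts, top, truth = gen_two_phase_box(0.35, "slab", box, 2000, seed=9)
        vd = water_volume_distribution(
            pts, np.full(3, box), top, [25.0, 30.0],
            water_radius=truth["water_radius"], n_probes=250, seed=17,
        )
        # large-r probe spheres wrap to a near-uniform box sample
        assert abs(vd.V[-1] - truth["measured_fraction"]) < 3 * (vd.V_err[-1] + 0.004)
        assert truth["measured_fraction"] == pytest.approx(0.35, abs=0.03)

    def test_isolated_sphere_matches_quadrature_oracle(self):
        """Region = one sphere of radius R; V(r) has a closed two-sphere
        overlap form averaged over probe centres inside the region."""
        box, R, r = 40.0, 4.0, 2.0
        pts = np.array([[20.0, 20.0, 20.0]])
        vd = water_volume_distribution(
            pts, np.full(3, box), walker_topology(1), [r],
            water_radius=R, n_probes=400, n_sphere_samples=256, seed=3,
        )

        def overlap(dist):
            if dist >= R + r:
                return 0.0
            if dist <= R - r:
                return 4 / 3 * math.pi * r**3
            return (
                math.pi
                * (R + r - dist) ** 2
                * (dist**2 + 2 * dist * r - 3 * r**2 + 2 * dist * R + 6 * r * R - 3 * R**2)
                / (12 * dist)
            )

        sphere_vol = 4 / 3 * math.pi * r**3
        expected = quad(
            lambda s: (3 * s**2 / R**3) * overlap(s) / sphere_vol, 0, R, limit=200
        )[0]
        assert vd.V[0] == pytest.approx(expected, abs=3 * vd.V_err[0] + 0.01)

    def test_no_water_is_error(self):
        top = _water_peg_topology(0, 2)
        with pytest.raises(ValueError, match="water"):
            water_volume_distribution(
                np.zeros((2, 3)) + 1.0, np.full(3, 10.0), top, [1.0], n_probes=10, seed=0
            )


class TestConfiningLength:
    def test_exact_linear_decay(self):
        r = np.linspace(0.2, 2.0, 10)
        vd = type("VD", (), {})()
        from hydshell.trajectory import VolumeDistribution

        vd = VolumeDistribution(
            r=r, V=1 - r / 5.0, V_err=np.zeros_like(r), n_probe_points=1, water_radius=1.7
        )
        assert confining_length(vd, (0.2, 2.0)) == pytest.approx(5.0, rel=1e-12)

    def test_noisy_estimator_unbiased(self, rng):
        from hydshell.trajectory import VolumeDistribution

        r = np.linspace(0.2, 2.0, 10)
        estimates = []
        for _ in range(100):
            V = np.clip(1 - r / 5.0 + 0.02 * rng.standard_normal(len(r)), 0, 1)
            vd = VolumeDistribution(
                r=r, V=V, V_err=np.zeros_like(r), n_probe_points=1, water_radius=1.7
            )
            estimates.append(confining_length(vd, (0.2, 2.0)))
        stderr = np.std(estimates) / 10.0
        assert abs(np.mean(estimates) - 5.0) < 3 * stderr + 0.02

    def test_flat_distribution_errors(self):
        from hydshell.trajectory import VolumeDistribution

        r = np.linspace(0.2, 2.0, 5)
        vd = VolumeDistribution(
            r=r, V=np.full_like(r, 0.5), V_err=np.zeros_like(r), n_probe_points=1,
            water_radius=1.7,
        )
        with pytest.raises(ValueError, match="slope"):
            confining_length(vd, (0.2, 2.0))


class TestMsdAndJumps:
    def test_static_atoms(self):
        pos = np.repeat(np.ones((1, 3, 3)), 20, axis=0)
        traj = make_trajectory(pos, 10.0)
        msd, jumps, residences = msd_and_jumps(traj, [0, 1, 2], 4, 1.0)
        np.testing.assert_allclose(msd.y, 0.0)
        assert jumps.sum() == 0 and len(residences) == 0

    def test_free_diffusion_einstein_slope(self, rng):
        D, dt = 0.1, 0.5
        steps = rng.normal(0, math.sqrt(2 * D * dt), size=(1500, 100, 3))
        steps[0] = rng.uniform(0, 50.0, size=(100, 3))
        traj = make_trajectory(np.cumsum(steps, axis=0), 50.0, timestep=dt)
        msd, _, _ = msd_and_jumps(traj, np.arange(100), 10, 100.0, max_lag=60)
        slope = np.polyfit(msd.x[1:], msd.y[1:], 1)[0]
        assert slope == pytest.approx(6 * D, rel=0.05)

    def test_trap_jump_residence_recovery(self):
        traj, top, truth = gen_trap_jump_trajectory(
            n_walkers=40, site_spacing=4.0, mean_residence=200.0,
            libration_sigma=0.4, timestep=1.0, n_frames=12000, box=40.0, seed=21,
        )
        msd, jumps, residences = msd_and_jumps(traj, np.arange(40), 10, 2.0, max_lag=10)
        assert np.mean(residences) == pytest.approx(200.0, rel=0.10)
        expected_jumps = truth["n_jumps"].sum()
        assert jumps.sum() == pytest.approx(expected_jumps, abs=3 * math.sqrt(expected_jumps))

    def test_infinite_residence_plateau(self):
        sigma = 0.4
        traj, top, _ = gen_trap_jump_trajectory(
            n_walkers=60, site_spacing=4.0, mean_residence=math.inf,
            libration_sigma=sigma, timestep=1.0, n_frames=600, box=40.0, seed=8,
        )
        msd, jumps, _ = msd_and_jumps(traj, np.arange(60), 10, 2.0, max_lag=30)
        assert jumps.sum() == 0
        # MSD of two independent Gaussian positions plateaus at 6σ²
        assert np.mean(msd.y[10:]) == pytest.approx(6 * sigma**2, rel=0.05)

    def test_libration_eisf_plateau(self):
        sigma = 0.3
        traj, top, _ = gen_trap_jump_trajectory(
            n_walkers=80, site_spacing=4.0, mean_residence=math.inf,
            libration_sigma=sigma, timestep=1.0, n_frames=500, box=40.0, seed=13,
        )
        q = 1.0
        (curve,) = incoherent_isf(traj, top, ("OW",), [q], max_lag=40)
        plateau = np.mean(curve.F[10:])
        assert plateau == pytest.approx(math.exp(-(q**2) * sigma**2), abs=0.02)
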