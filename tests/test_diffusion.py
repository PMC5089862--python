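"""MSD estimator, diffusion fits, size-scaling fits, surface diffusion."""

import numpy as np
import pytest

from cytocrowd.diffusion import (MSDCurve, classify_surface_diffusion,
                                 compute_msd, fit_dtr, fit_size_scaling,
                                 msd_brute_force)
from cytocrowd.io_core import SimulationBox, Trajectory
from cytocrowd.synthetic_data import gen_brownian_walkers


def _traj(positions, dt=10.0, L=1000.0, wrapped=False):
    f, n = positions.shape[:2]
    return Trajectory(times=np.arange(f) * dt, positions=positions,
                      labels=np.array([f"p{i}" for i in range(n)], dtype=object),
                      box=SimulationBox(L), wrapped=wrapped)


class TestComputeMSD:
    def test_static_particle_is_zero(self):
        traj = _traj(np.tile(np.array([[1.0, 2.0, 3.0]]), (50, 1, 1)))
        curve = compute_msd(traj, tau_max=200.0)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_ballistic_motion_is_quadratic(self):
        v = 0.25
        t = np.arange(60.0) * 10.0
        pos = np.zeros((60, 1, 3))
        pos[:, 0, 0] = v * t
        curve = compute_msd(_traj(pos), tau_max=300.0)
        np.testing.assert_allclose(curve.msd, (v * curve.tau) ** 2, rtol=1e-12)

    def test_matches_brute_force_double_loop_exactly(self):
        rng = np.random.default_rng(11)
        pos = np.cumsum(rng.normal(0, 1, (100, 5, 3)), axis=0)
        traj = _traj(pos, dt=10.0)
        curve = compute_msd(traj, tau_max=300.0, dt_origin=30.0)
        tau_ref, msd_ref = msd_brute_force(pos, traj.times, 300.0, 30.0)
        np.testing.assert_allclose(curve.tau, tau_ref)
        np.testing.assert_allclose(curve.msd, msd_ref, rtol=1e-12)

    def test_wrapped_trajectory_rejected(self):
        traj = _traj(np.full((20, 1, 3), 5.0), L=10.0, wrapped=True)
        with pytest.raises(ValueError, match="unwrapped"):
            compute_msd(traj, tau_max=50.0)

    def test_tau_max_must_be_shorter_than_span(self):
        traj = _traj(np.zeros((20, 1, 3)))
        with pytest.raises(ValueError, match="tau_max"):
            compute_msd(traj, tau_max=500.0)

    def test_walker_msd_slope_is_6d(self):
        traj = gen_brownian_walkers(100, 0.1, 10.0, 400, seed=4)
        curve = compute_msd(traj, tau_max=500.0)
        mask = curve.tau > 0
        np.testing.assert_allclose(curve.msd[mask] / curve.tau[mask], 0.6,
                                   rtol=0.1)


class TestFitDtr:
    def test_exact_linear_curve_inverts(self):
        tau = np.arange(0, 31) * 10.0
        curve = MSDCurve(tau=tau, msd=6 * 0.05 * tau, n_windows=1,
                         tau_max=300.0, dt_origin=10.0, t_end=1000.0)
        assert fit_dtr(curve).d_tr == pytest.approx(0.05, rel=1e-12)

    def test_walker_recovery_within_five_percent(self):
        traj = gen_brownian_walkers(100, 0.1, 10.0, 1000, seed=6)
        result = fit_dtr(compute_msd(traj, tau_max=1000.0))
        assert result.d_tr == pytest.approx(0.1, rel=0.05)

    def test_last_80_percent_beats_full_fit_on_contaminated_curve(self):
        # short-time caging transient on top of 6 D tau
        d_true = 0.05
        tau = np.arange(0, 101) * 10.0
        tau0 = 100.0
        msd = 6 * d_true * (tau - tau0 * (1 - np.exp(-tau / tau0)))
        curve = MSDCurve(tau=tau, msd=msd, n_windows=1, tau_max=1000.0,
                         dt_origin=10.0, t_end=5000.0)
        d_last = fit_dtr(curve, fit_fraction=0.8).d_tr
        d_full = fit_dtr(curve, fit_fraction=1.0).d_tr
        assert abs(d_last - d_true) < abs(d_full - d_true)

    def test_negative_slope_flagged_not_hidden(self):
        tau = np.arange(0, 21) * 10.0
        msd = np.concatenate([[0.0], 100.0 - 0.5 * tau[1:]])
        curve = MSDCurve(tau=tau, msd=msd, n_windows=1, tau_max=200.0,
                         dt_origin=10.0, t_end=1000.0)
        res = fit_dtr(curve)
        assert res.negative_slope
        assert res.d_tr < 0

    def test_invariant_under_rigid_translation_and_reindexing(self):
        traj = gen_brownian_walkers(20, 0.08, 10.0, 300, seed=9)
        d_ref = fit_dtr(compute_msd(traj, tau_max=500.0)).d_tr
        shifted = _traj(traj.positions + np.array([100.0, -50.0, 25.0]))
        assert fit_dtr(compute_msd(shifted, tau_max=500.0)).d_tr == pytest.approx(d_ref)
        perm = np.random.default_rng(0).permutation(20)
        reordered = _traj(traj.positions[:, perm, :])
        assert fit_dtr(compute_msd(reordered, tau_max=500.0)).d_tr == pytest.approx(d_ref)


class TestSizeScaling:
    def test_inverse_square_coefficient_recovered_exactly(self):
        rs = np.array([15.8, 24.0, 45.0, 85.0, 125.0])
        fit = fit_size_scaling(rs, 341.0 / rs ** 2, "A_over_Rs2")
        assert fit.coefficients["A"] == pytest.approx(341.0, rel=1e-12)

    def test_inverse_coefficient_recovered_exactly(self):
        rs = np.array([15.8, 24.0, 45.0, 85.0, 125.0])
        fit = fit_size_scaling(rs, 5.6 / rs, "B_over_Rs")
        assert fit.coefficients["B"] == pytest.approx(5.6, rel=1e-12)

    def test_power_law_free_exponent_recovered(self):
        mw = np.array([9e3, 2.5e4, 4.4e4, 2.3e5, 2.3e6])
        rs = 2.54 * mw ** 0.286
        fit = fit_size_scaling(mw, rs, "powerlaw_Rs_of_Mw")
        assert fit.coefficients["exponent"] == pytest.approx(0.286, rel=1e-9)
        assert fit.coefficients["prefactor"] == pytest.approx(2.54, rel=1e-9)

    def test_linear_crowding_slope_recovered_within_noise(self):
        rng = np.random.default_rng(5)
        nc = rng.uniform(0.5, 1.5, 200)
        m_true, n_true = -0.8, 1.8
        d = m_true * nc + n_true + rng.normal(0, 0.05, 200)
        fit = fit_size_scaling(nc, d, "linear_norm")
        assert fit.coefficients["m"] == pytest.approx(m_true, abs=0.05)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            fit_size_scaling(np.array([1.0, -2.0]), np.array([1.0, 2.0]),
                             "B_over_Rs")


class TestSurfaceDiffusion:
    def _macro_traj(self, n_frames, dt, L=2000.0):
        pos = np.tile(np.array([[L / 2, L / 2, L / 2]]), (n_frames, 1, 1))
        return Trajectory(times=np.arange(n_frames) * dt, positions=pos,
                          labels=np.array(["M"], dtype=object),
                          box=SimulationBox(L), wrapped=False)

    def test_distant_metabolite_has_no_surface_segments(self):
        n_frames, dt = 200, 50.0
        met = gen_brownian_walkers(5, 0.05, dt, n_frames - 1, seed=3,
                                   box_edge=2000.0)
        met.positions += 500.0  # keep far away from the macromolecule
        macro = self._macro_traj(n_frames, dt)
        res = classify_surface_diffusion(met, macro, cutoffs=8.0,
                                         min_residence=500.0,
                                         macro_radii=np.array([10.0]))
        assert res.segments == []
        assert res.d_bulk == pytest.approx(0.05, rel=0.15)
        assert res.d_surface is None

    def test_six_ns_bound_track_gives_exactly_one_segment(self):
        dt = 200.0
        n_frames = 100           # 20 ns span
        L = 2000.0
        macro = self._macro_traj(n_frames, dt, L)
        radius = 100.0
        pos = np.full((n_frames, 1, 3), L / 2)
        pos[:, 0, 0] += 500.0                      # far
        bound = slice(30, 61)                      # 30 frames = 6 ns bound
        pos[bound, 0, 0] = L / 2 + radius + 5.0    # within 8 A of the surface
        met = Trajectory(times=np.arange(n_frames) * dt, positions=pos,
                         labels=np.array(["m"], dtype=object),
                         box=SimulationBox(L), wrapped=False)
        res = classify_surface_diffusion(met, macro, cutoffs=8.0,
                                         min_residence=5000.0,
                                         macro_radii=np.array([radius]))
        assert len(res.segments) == 1
        seg = res.segments[0]
        assert (seg.start_frame, seg.end_frame) == (30, 60)

    def test_recovers_2d_and_3d_diffusion_from_mixed_populations(self):
        """Planar walk stapled to a sphere + free 3D walkers."""
        rng = np.random.default_rng(21)
        L, dt, n_frames = 4000.0, 10.0, 600
        radius = 295.0
        centre = np.array([L / 2, L / 2, L / 2])
        d2, d3 = 0.05, 0.2
        # spherical-surface random walk at radius+5 (curvature negligible
        # over the fitted lags)
        n_surf = 12
        surf = np.empty((n_frames, n_surf, 3))
        x = rng.normal(size=(n_surf, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        shell = radius + 5.0
        for f in range(n_frames):
            surf[f] = centre + shell * x
            step = rng.normal(0, np.sqrt(2 * d2 * dt), size=(n_surf, 3))
            # project the step onto the local tangent plane, then renormalise
            step -= (step * x).sum(axis=1, keepdims=True) * x
            x = x + step / shell
            x /= np.linalg.norm(x, axis=1, keepdims=True)
        # free walkers start in a cluster ~800 A from the sphere; their rms
        # displacement over the span (~85 A) cannot bring them near it
        free = (gen_brownian_walkers(12, d3, dt, n_frames - 1, seed=22,
                                     box_edge=200.0).positions
                + centre + np.array([800.0, -100.0, -100.0]))
        met_pos = np.concatenate([surf, free], axis=1)
        met = Trajectory(times=np.arange(n_frames) * dt, positions=met_pos,
                         labels=np.array(["s"] * n_surf + ["f"] * 12,
                                         dtype=object),
                         box=SimulationBox(L), wrapped=False)
        macro = self._macro_traj(n_frames, dt, L)
        res = classify_surface_diffusion(met, macro, cutoffs=8.0,
                                         min_residence=1000.0,
                                         macro_radii=np.array([radius]),
                                         tau_max=300.0)
        assert res.d_surface == pytest.approx(d2, rel=0.1)
        assert res.d_bulk == pytest.approx(d3, rel=0.1)

    def test_mismatched_time_grids_rejected(self):
        met = gen_brownian_walkers(2, 0.1, 10.0, 20, seed=1, box_edge=100.0)
        macro = self._macro_traj(30, 10.0, 100.0)
        with pytest.raises(ValueError, match="times"):
            classify_surface_diffusion(met, macro)
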