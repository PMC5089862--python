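"""BD engine: pair potential, integrators, neighbour search, hydrodynamics."""

import numpy as np
import pytest

from cytocrowd.bd_engine import (BDParams, InstabilityError, OverlapError,
                                 PotentialParams, SingularConfigurationError,
                                 bd_step, compute_forces, pair_energy,
                                 replace_positions, rpy_diffusion_matrix,
                                 run_simulation, suggest_timestep)
from cytocrowd.diffusion import compute_msd, fit_dtr
from cytocrowd.io_core import ParticleSystem, SimulationBox
from cytocrowd.units import stokes_einstein_d


def _one_particle(radius=10.0, edge=100.0):
    return ParticleSystem(positions=np.array([[50.0, 50.0, 50.0]]),
                          radii=np.array([radius]),
                          labels=np.array(["p"], dtype=object),
                          box=SimulationBox(edge))


class TestPairPotential:
    def test_contact_energy_is_five_kBT(self):
        e, f = pair_energy(40.0, 20.0, 20.0)
        assert e == 5.0
        assert f == pytest.approx(10.0)   # k * delta, repulsive

    def test_zero_at_and_beyond_cutoff(self):
        assert pair_energy(41.0, 20.0, 20.0) == (0.0, 0.0)
        assert pair_energy(60.0, 20.0, 20.0) == (0.0, 0.0)

    def test_half_buffer_value(self):
        e, _ = pair_energy(40.5, 20.0, 20.0)
        assert e == pytest.approx(0.5 * 10.0 * 0.5 ** 2)

    def test_continuity_at_cutoff(self):
        eps = 1e-8
        e_in, f_in = pair_energy(41.0 - eps, 20.0, 20.0)
        assert e_in == pytest.approx(0.0, abs=1e-12)
        assert f_in == pytest.approx(0.0, abs=1e-6)

    def test_zero_separation_is_singular(self):
        with pytest.raises(SingularConfigurationError):
            pair_energy(0.0, 5.0, 5.0)


class TestTimestepRule:
    def test_smallest_species_radius_gives_eight_ps(self):
        assert suggest_timestep(15.8) == pytest.approx(8.0, abs=1.0)

    def test_cubic_scaling(self):
        assert suggest_timestep(20.0) == pytest.approx(8 * suggest_timestep(10.0))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            suggest_timestep(0.0)


class TestBDStep:
    def test_zero_force_zero_noise_is_static(self):
        system = _one_particle()
        bd = BDParams(timestep=8.0, scheme="ermak_mccammon", seed=0, steps=1)
        new = bd_step(system, bd, noise=np.zeros((1, 3)))
        np.testing.assert_array_equal(new, system.positions)

    @pytest.mark.parametrize("scheme", ["ermak_mccammon", "iniesta_delatorre"])
    def test_drift_term_exact_with_zeroed_noise(self, scheme):
        system = _one_particle(radius=10.0)
        bd = BDParams(timestep=8.0, scheme=scheme, seed=0, steps=1)
        force = np.array([[1.0, -2.0, 0.5]])   # kBT/A, constant in space
        new = bd_step(system, bd, noise=np.zeros((1, 3)),
                      external_force=force)
        d = stokes_einstein_d(10.0)
        np.testing.assert_allclose(new - system.positions, d * force * 8.0,
                                   rtol=1e-12)

    def test_harmonic_well_matches_metropolis_oracle_and_corrector_bias_smaller(self):
        """Stationary variance in V = kappa x^2 / 2.

        Exact variance is 1/kappa (kBT units).  The first-order scheme
        overestimates it by ~b/2 with b = kappa D dt; the predictor-
        corrector bias is O(b^2) and must be smaller at equal dt.
        """
        kappa = 1.0          # kBT/A^2
        radius = 10.0
        d = stokes_einstein_d(radius)
        dt = 0.4 / (kappa * d)       # b = 0.4, strongly biased regime
        n_steps = 60_000
        rng_noise = np.random.Generator(np.random.Philox(77))
        noise = rng_noise.standard_normal((n_steps, 1, 3))
        centre = np.array([50.0, 50.0, 50.0])
        spring = lambda pos: -kappa * (pos - centre)  # noqa: E731
        variances = {}
        for scheme in ("ermak_mccammon", "iniesta_delatorre"):
            system = _one_particle(radius=radius)
            bd = BDParams(timestep=dt, scheme=scheme, seed=0, steps=1)
            samples = np.empty((n_steps, 3))
            pos = system.positions.copy()
            for s in range(n_steps):
                pos = bd_step(replace_positions(system, pos), bd,
                              noise=noise[s], external_force=spring)
                samples[s] = pos - centre
            variances[scheme] = samples[5000:].var()
        exact = 1.0 / kappa
        # independent Metropolis Monte-Carlo oracle for the same well
        rng = np.random.Generator(np.random.Philox(123))
        x = np.zeros(3)
        mc = np.empty((60_000, 3))
        for s in range(60_000):
            prop = x + rng.normal(0, 1.0, 3)
            if rng.random() < np.exp(-(0.5 * kappa * (prop ** 2).sum()
                                       - 0.5 * kappa * (x ** 2).sum())):
                x = prop
            mc[s] = x
        mc_var = mc[5000:].var()
        assert mc_var == pytest.approx(exact, rel=0.05)
        assert variances["iniesta_delatorre"] == pytest.approx(exact, rel=0.08)
        bias_em = abs(variances["ermak_mccammon"] - exact)
        bias_mid = abs(variances["iniesta_delatorre"] - exact)
        assert bias_mid < bias_em


class TestRunSimulation:
    def test_free_particle_recovers_stokes_einstein(self):
        system = _one_particle(radius=20.0)
        bd = BDParams(timestep=8.0, scheme="ermak_mccammon", seed=3,
                      steps=200_000, output_stride=10)
        traj = run_simulation(system, bd)
        result = fit_dtr(compute_msd(traj, tau_max=2000.0))
        assert result.d_tr == pytest.approx(stokes_einstein_d(20.0), rel=0.05)

    def test_two_sphere_distance_histogram_matches_boltzmann_quadrature(self):
        """Sampled pair-distance density vs exp(-V(r)) 4 pi r^2 (quadrature)."""
        a = 5.0
        L = 40.0
        system = ParticleSystem(
            positions=np.array([[10.0, 20.0, 20.0], [22.0, 20.0, 20.0]]),
            radii=np.array([a, a]),
            labels=np.array(["s", "s"], dtype=object), box=SimulationBox(L))
        bd = BDParams(timestep=0.5, seed=8, steps=400_000, output_stride=20)
        traj = run_simulation(system, bd)
        from cytocrowd.io_core import minimum_image
        d = minimum_image(traj.positions[:, 0] - traj.positions[:, 1], L)
        r = np.sqrt((d * d).sum(axis=1))
        edges = np.arange(6.0, 19.0, 1.0)
        hist, _ = np.histogram(r[r < edges[-1]], bins=edges, density=True)
        centres = 0.5 * (edges[:-1] + edges[1:])

        def boltzmann(rv):
            v = np.where(rv < 2 * a + 1.0,
                         0.5 * 10.0 * (rv - 2 * a - 1.0) ** 2, 0.0)
            return np.exp(-v) * 4 * np.pi * rv ** 2

        # quadrature normalisation over the same range
        grid = np.linspace(edges[0], edges[-1], 2000)
        norm = np.trapezoid(boltzmann(grid), grid)
        expected = boltzmann(centres) / norm
        np.testing.assert_allclose(hist, expected, atol=0.015)

    def test_same_seed_bit_identical(self):
        system = _one_particle()
        bd = BDParams(seed=5, steps=500, output_stride=50)
        a = run_simulation(system, bd)
        b = run_simulation(system, bd)
        assert np.array_equal(a.positions, b.positions)

    def test_overlapping_start_rejected_without_soft_start(self):
        system = ParticleSystem(
            positions=np.array([[10.0, 10.0, 10.0], [12.0, 10.0, 10.0]]),
            radii=np.array([5.0, 5.0]),
            labels=np.array(["s", "s"], dtype=object),
            box=SimulationBox(50.0))
        with pytest.raises(OverlapError, match="soft_start"):
            run_simulation(system, BDParams(steps=10))

    def test_instability_names_the_particle(self):
        system = _one_particle(radius=2.0, edge=50.0)
        bd = BDParams(timestep=1e7, seed=1, steps=100, output_stride=10)
        with pytest.raises(InstabilityError, match="particle 0"):
            run_simulation(system, bd)


class TestNeighbourSearch:
    def test_cell_list_equals_brute_force_exactly(self, random_particle_system):
        fb, eb = compute_forces(random_particle_system, method="brute")
        fc, ec = compute_forces(random_particle_system, method="cell")
        np.testing.assert_allclose(fc, fb, rtol=0, atol=1e-12)
        assert ec == pytest.approx(eb, abs=1e-10)

    def test_energy_nonnegative_and_zero_without_contacts(self, random_particle_system):
        _, e = compute_forces(random_particle_system)
        assert e >= 0.0
        sparse = ParticleSystem(
            positions=np.array([[10.0, 10, 10], [40.0, 40, 40]]),
            radii=np.array([3.0, 3.0]),
            labels=np.array(["s", "s"], dtype=object), box=SimulationBox(100.0))
        assert compute_forces(sparse)[1] == 0.0

    def test_lj_forms_also_agree(self, random_particle_system):
        params = PotentialParams(form="lennard_jones", cutoff=12.0)
        fb, _ = compute_forces(random_particle_system, params, method="brute")
        fc, _ = compute_forces(random_particle_system, params, method="cell")
        # identical pair terms; only the summation order differs
        np.testing.assert_allclose(fc, fb, rtol=0,
                                   atol=1e-12 * np.abs(fb).max())


class TestRPYMobility:
    def test_isolated_particle_self_mobility(self):
        d = rpy_diffusion_matrix(np.array([[0.0, 0, 0]]), np.array([4.0]))
        np.testing.assert_allclose(d, stokes_einstein_d(4.0) * np.eye(3),
                                   rtol=1e-12)

    def test_two_equal_spheres_match_far_field_expansion(self):
        """Off-diagonal block vs the independently-coded two-body formula."""
        a, r = 3.0, 10.0
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        d = rpy_diffusion_matrix(pos, np.array([a, a]))
        c1 = stokes_einstein_d(1.0)
        # kBT/(8 pi eta r) [(1 + 2a^2/(3r^2)) I + (1 - 2a^2/r^2) rr^T]
        pref = 0.75 * c1 / r
        expected = np.diag([
            pref * ((1 + 2 * a * a / (3 * r * r)) + (1 - 2 * a * a / (r * r))),
            pref * (1 + 2 * a * a / (3 * r * r)),
            pref * (1 + 2 * a * a / (3 * r * r)),
        ])
        np.testing.assert_allclose(d[0:3, 3:6], expected, rtol=1e-12)

    def test_random_configuration_positive_definite(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 200, (20, 3))
        radii = np.full(20, 3.0)
        # retry-free construction: spread particles far apart
        d = rpy_diffusion_matrix(pos, radii)
        assert np.linalg.eigvalsh(d).min() > 0

    def test_overlap_rejected(self):
        with pytest.raises(OverlapError):
            rpy_diffusion_matrix(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                                 np.array([3.0, 3.0]))

    def test_rpy_scheme_dilute_diffusion(self):
        system = _one_particle(radius=10.0)
        bd = BDParams(timestep=8.0, scheme="fixman_rpy", seed=2, steps=20_000,
                      output_stride=5)
        traj = run_simulation(system, bd)
        result = fit_dtr(compute_msd(traj, tau_max=600.0))
        assert result.d_tr == pytest.approx(stokes_einstein_d(10.0), rel=0.1)
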