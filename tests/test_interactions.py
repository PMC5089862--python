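"""Coordination numbers and quinary-interaction statistics."""

import numpy as np
import pytest

from cytocrowd.interactions import (coordination_series,
                                    group_interaction_matrix,
                                    instantaneous_coordination,
                                    pair_distance_change)
from cytocrowd.io_core import SimulationBox, SpeciesTable, Trajectory


def _traj(positions, labels, L=200.0, dt=100.0, wrapped=False):
    f = positions.shape[0]
    return Trajectory(times=np.arange(f) * dt, positions=positions,
                      labels=np.asarray(labels, dtype=object),
                      box=SimulationBox(L), wrapped=wrapped)


class TestCoordination:
    def test_isolated_target_counts_zero(self):
        pos = np.array([[10.0, 10, 10], [150.0, 150, 150]])
        nc = instantaneous_coordination(pos, 200.0, [np.array([0])],
                                        np.arange(2), np.array([0, 1]),
                                        cutoff=50.0)
        assert nc[0] == 0

    def test_crafted_frame_counts_exactly_seven(self):
        rng = np.random.default_rng(6)
        target = np.array([[100.0, 100.0, 100.0]])
        inside = target + rng.uniform(-20, 20, (7, 3))      # within 50 A
        outside = target + 120.0 + rng.uniform(0, 5, (4, 3))
        pos = np.concatenate([target, inside, outside])
        nc = instantaneous_coordination(pos, 400.0, [np.array([0])],
                                        np.arange(12), np.arange(12),
                                        cutoff=50.0)
        assert nc[0] == 7

    def test_matches_all_pairs_recount_exactly(self):
        """KD-tree counts vs a plain double loop on a 50-particle frame."""
        rng = np.random.default_rng(8)
        L = 120.0
        pos = rng.uniform(0, L, (50, 3))
        molecule_of = np.arange(50)
        targets = [np.array([i]) for i in range(50)]
        nc = instantaneous_coordination(pos, L, targets, np.arange(50),
                                        molecule_of, cutoff=50.0)
        # oracle: brute-force minimum-image double loop
        brute = np.zeros(50, dtype=int)
        for i in range(50):
            for j in range(50):
                if i == j:
                    continue
                d = pos[i] - pos[j]
                d -= L * np.rint(d / L)
                if np.sqrt((d * d).sum()) <= 50.0:
                    brute[i] += 1
        np.testing.assert_array_equal(nc, brute)

    def test_window_averaging_and_normalisation(self):
        pos = np.zeros((10, 2, 3))
        pos[:, 1, 0] = 30.0          # neighbour always within cutoff
        traj = _traj(pos, ["a", "b"], dt=500.0)
        series = coordination_series(traj, [np.array([0])], np.arange(2),
                                     np.array([0, 1]), cutoff=50.0,
                                     window=2000.0, stride=500.0)
        assert np.all(series.values == 1.0)
        assert np.all(series.normalized() == 1.0)

    def test_empty_reference_selection_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            instantaneous_coordination(np.zeros((2, 3)), 10.0,
                                       [np.array([0])], np.array([], int),
                                       np.array([0, 1]))


class TestPairDistanceChange:
    def test_static_pair_zero(self):
        pos = np.zeros((20, 2, 3))
        pos[:, 1, 0] = 60.0
        rec = pair_distance_change(_traj(pos, ["a", "b"]), 0, 1,
                                   tau_short=300.0)
        assert rec.delta_d == 0.0

    def test_growing_pair_reports_plus_five(self):
        pos = np.zeros((21, 2, 3))
        pos[:, 1, 0] = 40.0
        pos[-3:, 1, 0] = 45.0        # final window average 45
        rec = pair_distance_change(_traj(pos, ["a", "b"]), 0, 1,
                                   tau_short=250.0)   # 3-frame windows
        assert rec.delta_d == pytest.approx(5.0)

    def test_scaled_distance_arithmetic(self):
        pos = np.zeros((10, 2, 3))
        pos[:, 1, 0] = 60.0
        rec = pair_distance_change(_traj(pos, ["a", "b"]), 0, 1,
                                   tau_short=200.0,
                                   radii=np.array([20.0, 20.0]))
        assert rec.rbar_initial == pytest.approx(3.0)

    def test_tau_short_must_fit_in_half_span(self):
        pos = np.zeros((10, 2, 3))
        with pytest.raises(ValueError, match="tau_short"):
            pair_distance_change(_traj(pos, ["a", "b"]), 0, 1, tau_short=500.0)

    def test_antisymmetric_under_time_reversal(self):
        rng = np.random.default_rng(13)
        pos = np.cumsum(rng.normal(0, 1, (40, 2, 3)), axis=0) + 100.0
        traj = _traj(pos, ["a", "b"])
        fwd = pair_distance_change(traj, 0, 1, tau_short=500.0)
        rev = pair_distance_change(_traj(pos[::-1].copy(), ["a", "b"]), 0, 1,
                                   tau_short=500.0)
        assert rev.delta_d == pytest.approx(-fwd.delta_d)


def _mixture_table():
    return SpeciesTable.from_records([
        dict(name="g", stokes_radius=20.0, copies=8, group="glycolytic"),
        dict(name="p", stokes_radius=20.0, copies=8, group="protein"),
        dict(name="r", stokes_radius=20.0, copies=8, group="RNA"),
    ])


class TestInteractionMatrix:
    def test_constant_configuration_gives_zero_with_zero_se(self):
        table = _mixture_table()
        rng = np.random.default_rng(3)
        frame = rng.uniform(0, 150, (24, 3))
        pos = np.tile(frame, (30, 1, 1))
        traj = _traj(pos, table.particle_labels(), L=150.0, dt=500.0)
        mat = group_interaction_matrix(traj, table, tau_short=1000.0, seed=1)
        for key, val in mat.delta_d.items():
            assert val == 0.0
            assert mat.stderr[key] == 0.0

    def test_ideal_gas_mixture_is_null_within_two_se(self):
        """Non-interacting diffusers: dd consistent with zero.

        Two regime requirements make this a clean null: a non-overlapping
        start (as for real macromolecules), and displacements per span
        small against initial separations — otherwise selecting
        initially-proximal pairs biases free diffusion toward positive
        distance changes.  All species are exchangeable, so the pooled
        single-group estimate carries the statistics.
        """
        from cytocrowd.synthetic_data import gen_packed_configuration

        table = SpeciesTable.from_records([
            dict(name=f"s{i}", stokes_radius=20.0, copies=8, group="protein")
            for i in range(3)])
        rng = np.random.default_rng(17)
        start = gen_packed_configuration(
            table, box=SimulationBox(150.0), seed=17).positions[None]
        steps = rng.normal(0, 0.25, (40, 24, 3))
        pos = np.concatenate([start, start + np.cumsum(steps, axis=0)])
        traj = _traj(pos, table.particle_labels(), L=150.0, dt=500.0)
        mat = group_interaction_matrix(traj, table, tau_short=2000.0, seed=2,
                                       groups=("protein",))
        val, se = mat.get("protein", "protein")
        assert se > 0
        assert abs(val) <= 2.0 * se, (val, se)

    def test_group_without_pairs_flagged_absent(self):
        table = SpeciesTable.from_records([
            dict(name="g", stokes_radius=20.0, copies=4, group="glycolytic"),
            dict(name="h", stokes_radius=30.0, copies=1, group="huge"),
        ])
        # single huge copy: no huge-huge pair can exist
        rng = np.random.default_rng(5)
        pos = np.tile(rng.uniform(0, 100, (5, 3)), (20, 1, 1))
        traj = _traj(pos, table.particle_labels(), L=100.0, dt=500.0)
        mat = group_interaction_matrix(traj, table, tau_short=1000.0,
                                       groups=("glycolytic", "huge"))
        assert ("huge", "huge") in mat.absent
        with pytest.raises(KeyError):
            mat.get("huge", "huge")

    def test_selection_invariant_under_uniform_rescaling(self):
        table = _mixture_table()
        rng = np.random.default_rng(19)
        start = rng.uniform(0, 150, (1, 24, 3))
        steps = rng.normal(0, 1.0, (30, 24, 3))
        pos = np.concatenate([start, start + np.cumsum(steps, axis=0)])
        traj = _traj(pos, table.particle_labels(), L=150.0, dt=500.0)
        mat = group_interaction_matrix(traj, table, tau_short=1000.0, seed=3)
        scaled_table = SpeciesTable.from_records([
            dict(name=r["name"], stokes_radius=2 * r["stokes_radius"],
                 copies=r["copies"], group=r["group"])
            for _, r in table.frame.iterrows()])
        traj2 = _traj(2 * pos, scaled_table.particle_labels(), L=300.0, dt=500.0)
        mat2 = group_interaction_matrix(traj2, scaled_table, tau_short=1000.0,
                                        seed=3)
        assert mat.n_pairs == mat2.n_pairs
        for key, val in mat.delta_d.items():
            assert mat2.delta_d[key] == pytest.approx(2 * val, rel=1e-9)

    def test_generative_group_attraction_recovered_with_correct_sign(self):
        """Pairs of one group given a deterministic -2 A approach are
        reported near -2 A; untouched groups stay null (the machinery
        behind group-resolved weak-association matrices)."""
        table = _mixture_table()
        n_frames = 41
        rng = np.random.default_rng(29)
        # 4 glycolytic pairs approach along x by 2 A over the span; the
        # protein and RNA particles sit far apart (no qualifying pairs at
        # moderate separation drift)
        L = 400.0
        start = np.empty((24, 3))
        for p in range(4):                      # glycolytic pairs at rc = 50
            base = np.array([60.0, 60.0 + 180.0 * (p % 2),
                             60.0 + 180.0 * (p // 2)])
            start[2 * p] = base
            start[2 * p + 1] = base + np.array([50.0, 0.0, 0.0])
        start[8:] = rng.uniform(0, L, (16, 3))  # protein + RNA background
        pos = np.tile(start, (n_frames, 1, 1))
        pos += np.cumsum(rng.normal(0, 0.1, (n_frames, 24, 3)), axis=0)
        approach = np.linspace(0, 1.0, n_frames)   # 1 A each -> dd = -2 A
        for p in range(4):
            pos[:, 2 * p, 0] += approach
            pos[:, 2 * p + 1, 0] -= approach
        traj = _traj(pos, table.particle_labels(), L=L, dt=500.0)
        mat = group_interaction_matrix(traj, table, tau_short=2000.0, seed=5)
        dd_gg, _ = mat.get("glycolytic", "glycolytic")
        assert dd_gg == pytest.approx(-2.0, abs=0.5)
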