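"""Shared fixtures: small systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cytocrowd.io_core import (ParticleSystem, SimulationBox, SpeciesTable,
                               Trajectory)


@pytest.fixture
def two_species_table() -> SpeciesTable:
    return SpeciesTable.from_records([
        dict(name="A", stokes_radius=20.0, copies=10, group="protein"),
        dict(name="B", stokes_radius=100.0, copies=1, group="huge"),
    ])


@pytest.fixture
def small_trajectory() -> Trajectory:
    """3 frames x 5 particles, deterministic coordinates."""
    rng = np.random.default_rng(7)
    pos = rng.uniform(0, 50, size=(3, 5, 3))
    return Trajectory(times=np.array([0.0, 10.0, 20.0]), positions=pos,
                      labels=np.array(["A", "A", "A", "B", "B"], dtype=object),
                      box=SimulationBox(50.0), wrapped=True)


@pytest.fixture
def random_particle_system() -> ParticleSystem:
    """150 small spheres in a box large enough for an active cell list."""
    rng = np.random.default_rng(1)
    n = 150
    return ParticleSystem(positions=rng.uniform(0, 100, (n, 3)),
                          radii=rng.uniform(2.0, 4.0, n),
                          labels=np.array(["x"] * n, dtype=object),
                          box=SimulationBox(100.0))
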