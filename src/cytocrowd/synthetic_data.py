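"""Synthetic inputs with known ground truth.

Every generator is a pure function of its parameters and an integer seed
(counter-based Philox streams), producing:

* free Brownian walkers and rigid rotors with known D / Drot for validating
  the diffusion and rotation estimators;
* packed polydisperse sphere configurations emulating a coarse-grained
  bacterial cytoplasm at cytoplasmic volume fraction (the ``mg_like``
  composition below is a synthetic stand-in for the real composition, which
  is consumed from a species table when available);
* two-component Lennard-Jones mixtures for depletion-force experiments
  (small 'A' particles with an equal-volume partner component of varying
  particle size);
* toy bead-macromolecule + point-metabolite systems for the spatial and
  structural metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io_core import (AtomGroupSelection, ParticleSystem, SimulationBox,
                      SpeciesTable, Trajectory, minimum_image)

__all__ = [
    "gen_brownian_walkers",
    "gen_rigid_rotor",
    "gen_packed_configuration",
    "gen_lj_mixture",
    "gen_toy_cell",
    "mg_like_species_table",
    "packed_box_edge",
    "PackingError",
    "LJ_CASES",
]


class PackingError(RuntimeError):
    """Random insertion failed; advise soft-start equilibration."""


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(int(seed)))


# ---------------------------------------------------------------------------
# free diffusers and rotors
# ---------------------------------------------------------------------------

def gen_brownian_walkers(n: int, d_true: float, dt: float, steps: int,
                         seed: int, box_edge: float | None = None,
                         label: str = "walker") -> Trajectory:
    """Independent Gaussian random walks with per-axis step variance 2 D dt."""
    if d_true < 0:
        raise ValueError(f"d_true must be >= 0, got {d_true}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = _rng(seed)
    if box_edge is None:
        box_edge = max(100.0, 20.0 * math.sqrt(max(6 * d_true * dt * steps, 1.0)))
    start = rng.uniform(0, box_edge, size=(1, n, 3))
    steps_arr = rng.normal(0.0, math.sqrt(2 * d_true * dt), size=(steps, n, 3))
    pos = np.concatenate([start, start + np.cumsum(steps_arr, axis=0)], axis=0)
    return Trajectory(times=np.arange(steps + 1) * dt, positions=pos,
                      labels=np.array([label] * n, dtype=object),
                      box=SimulationBox(box_edge), wrapped=False)


def gen_rigid_rotor(drot_true: float, dt: float, steps: int, seed: int,
                    n_bodies: int = 1) -> Trajectory:
    """Isotropic small-angle rotational diffusion of rigid bodies.

    Orientation operators are proper rotations (orthonormal, det +1) at
    every frame; the first-rank orientation autocorrelation of each body
    axis decays as exp(-2 Drot tau).
    """
    if drot_true < 0:
        raise ValueError(f"drot_true must be >= 0, got {drot_true}")
    rng = _rng(seed)
    sd = math.sqrt(2 * drot_true * dt)
    mats = np.empty((steps + 1, n_bodies, 3, 3))
    current = Rotation.identity(n_bodies)
    mats[0] = current.as_matrix()
    for s in range(steps):
        dphi = rng.normal(0.0, sd, size=(n_bodies, 3))
        current = Rotation.from_rotvec(dphi) * current
        mats[s + 1] = current.as_matrix()
    return Trajectory(times=np.arange(steps + 1) * dt,
                      positions=np.zeros((steps + 1, n_bodies, 3)),
                      labels=np.array([f"rotor{i}" for i in range(n_bodies)],
                                      dtype=object),
                      box=SimulationBox(100.0), wrapped=False,
                      orientations=mats)


# ---------------------------------------------------------------------------
# packed crowded configurations
# ---------------------------------------------------------------------------

#: synthetic composition emulating one cytoplasm subsection: ribosome- and
#: GroEL-sized complexes, tRNA-sized RNA and a protein size spectrum down to
#: the smallest species (15.8 A, the radius at which the production timestep
#: rule 0.0005 a^2/D evaluates to 8 ps).  Copy numbers give 216 spheres and
#: a Stokes-sphere volume fraction of ~0.39 under the x8-copies box
#: convention of :func:`packed_box_edge`.
_MG_LIKE_ROWS = [
    dict(name="ribosome", stokes_radius=125.0, copies=3, group="huge",
         charge=0.0, molecular_weight=2.3e6),
    dict(name="groel", stokes_radius=85.0, copies=3, group="huge",
         charge=0.0, molecular_weight=8.0e5),
    dict(name="trna", stokes_radius=24.0, copies=30, group="RNA",
         charge=0.0, molecular_weight=2.5e4),
    dict(name="if1_like", stokes_radius=15.8, copies=30, group="protein",
         charge=0.0, molecular_weight=9.0e3),
    dict(name="small_enzyme", stokes_radius=20.0, copies=40, group="protein",
         charge=0.0, molecular_weight=2.5e4),
    dict(name="pgk_like", stokes_radius=29.0, copies=30, group="glycolytic",
         charge=0.0, molecular_weight=4.4e4),
    dict(name="eno_like", stokes_radius=33.0, copies=25, group="glycolytic",
         charge=0.0, molecular_weight=9.0e4),
    dict(name="medium_protein", stokes_radius=35.0, copies=20, group="protein",
         charge=0.0, molecular_weight=1.1e5),
    dict(name="pyk_like", stokes_radius=40.0, copies=20, group="glycolytic",
         charge=0.0, molecular_weight=2.3e5),
    dict(name="acka_like", stokes_radius=45.0, copies=10, group="protein",
         charge=0.0, molecular_weight=3.2e5),
    dict(name="large_complex", stokes_radius=55.0, copies=5, group="protein",
         charge=0.0, molecular_weight=6.0e5),
]

#: box edge (A) holding 8 subunit copies in the scaled-up coarse-grained box
_MGCG_EDGE_8X = 1062.0


def mg_like_species_table() -> SpeciesTable:
    """The synthetic cytoplasm-like composition (see module docstring)."""
    return SpeciesTable.from_records(_MG_LIKE_ROWS)


def packed_box_edge(table: SpeciesTable, scale_factor: int) -> float:
    """Box edge for ``scale_factor`` copies of the composition.

    Follows the coarse-grained convention of 8 subunit copies in a
    (106.2 nm)^3 box: edge = 1062 A x (scale/8)^(1/3), which keeps the
    sphere volume fraction independent of the scale factor.
    """
    return _MGCG_EDGE_8X * (scale_factor / 8.0) ** (1.0 / 3.0)


def gen_packed_configuration(table: SpeciesTable,
                             box: SimulationBox | None = None,
                             seed: int = 0,
                             scale_factor: int = 1,
                             max_attempts: int = 500,
                             relax: bool = True,
                             relax_steps: int = 6000) -> ParticleSystem:
    """Overlap-free random packing of the composition in a periodic box.

    Copy numbers are multiplied by ``scale_factor``.  Particles are inserted
    largest-first by random sequential insertion; leftover particles (dense
    packings) are placed randomly and relaxed with capped-force BD until no
    pair has centre distance < ai + aj.  With ``relax=False`` insertion
    failure raises :class:`PackingError` advising soft-start equilibration.
    """
    scaled = table.scaled(scale_factor)
    if box is None:
        box = SimulationBox(packed_box_edge(table, scale_factor))
    radii = scaled.particle_radii()
    labels = scaled.particle_labels()
    charges = scaled.particle_charges()
    phi = (4.0 / 3.0) * np.pi * (radii ** 3).sum() / box.volume
    if phi > 0.55:
        raise PackingError(
            f"requested sphere volume fraction {phi:.3f} exceeds 0.55; "
            "not packable by insertion -- reduce copies or enlarge the box"
        )
    order = np.argsort(-radii)
    inv = np.argsort(order)
    rs = radii[order]
    L = box.edge_length
    rng = _rng(seed)
    placed = np.empty((len(rs), 3))
    n_placed = 0
    failed: list[int] = []
    for idx in range(len(rs)):
        ok = False
        for _ in range(max_attempts):
            cand = rng.uniform(0, L, size=3)
            if n_placed:
                d = minimum_image(placed[:n_placed] - cand, L)
                rij = np.sqrt((d * d).sum(axis=1))
                if np.any(rij < rs[:n_placed] + rs[idx]):
                    continue
            placed[n_placed] = cand
            n_placed += 1
            ok = True
            break
        if not ok:
            failed.append(idx)
            placed[n_placed] = rng.uniform(0, L, size=3)
            n_placed += 1
    pos = placed[inv]
    system = ParticleSystem(positions=pos, radii=radii, labels=labels,
                            box=box, charges=charges, table=scaled,
                            meta={"seed": int(seed), "scale_factor": int(scale_factor),
                                  "volume_fraction": float(phi)})
    if failed:
        if not relax:
            raise PackingError(
                f"random insertion failed for {len(failed)} particles at "
                f"volume fraction {phi:.3f}; rerun with relax=True "
                "(soft-start capped-force equilibration)"
            )
        system = _relax_overlaps(system, seed, relax_steps)
    return system


def _with_positions(system: ParticleSystem, pos: np.ndarray) -> ParticleSystem:
    return ParticleSystem(positions=pos, radii=system.radii,
                          labels=system.labels, box=system.box,
                          charges=system.charges, table=system.table,
                          meta=system.meta)


def _descend_to_contact(system: ParticleSystem, dt: float = 4.0,
                        force_cap: float = 10.0,
                        max_iter: int = 4000) -> ParticleSystem:
    """Zero-noise capped-force descent until no pair overlaps.

    At thermal equilibrium the soft 5 kBT contact penalty leaves a few
    pairs transiently interpenetrating, so a noisy relaxation never
    produces an overlap-free snapshot; a short deterministic descent does.
    """
    from .bd_engine import compute_forces, particle_diffusion_constants, BDParams

    dpart = particle_diffusion_constants(system.radii, BDParams())
    pos = system.positions.copy()
    current = system
    for it in range(max_iter):
        forces, energy = compute_forces(current)
        if energy == 0.0 and current.min_surface_gap() >= 0:
            return current
        norm = np.sqrt((forces ** 2).sum(axis=1, keepdims=True))
        big = norm[:, 0] > force_cap
        forces[big] *= force_cap / norm[big]
        pos = pos + dpart[:, None] * forces * dt
        current = _with_positions(current, pos)
        if it % 25 == 24 and current.min_surface_gap() >= 0:
            return current
    if current.min_surface_gap() >= 0:
        return current
    raise PackingError(
        "capped-force relaxation did not remove all hard overlaps; "
        "increase relax_steps or reduce the volume fraction"
    )


def _relax_overlaps(system: ParticleSystem, seed: int, relax_steps: int) -> ParticleSystem:
    from .bd_engine import BDParams, run_simulation

    batch = 2000
    done = 0
    current = system
    while True:
        bd = BDParams(timestep=4.0, scheme="ermak_mccammon",
                      seed=(int(seed) + 7919 + done) % (2 ** 31),
                      steps=batch, output_stride=batch)
        traj = run_simulation(current, bd, soft_start=True, force_cap=10.0)
        pos = np.mod(traj.positions[-1], system.box.edge_length)
        current = _with_positions(system, pos)
        done += batch
        if current.min_surface_gap() >= 0:
            return current
        if done >= relax_steps:
            # noisy phase spread particles out; finish deterministically
            return _descend_to_contact(current)


# ---------------------------------------------------------------------------
# Lennard-Jones depletion mixtures
# ---------------------------------------------------------------------------

#: particle radii (A) for the mixture cases; each component occupies the
#: same nominal volume of 3400 A^3 in an (18.666 A)^3 box.  In AD_rep the
#: 'D' particles carry a unit charge to create repulsion.
LJ_CASES = {
    "AB": ("B", 2.0, 0.0),
    "AC": ("C", 3.509, 0.0),
    "AD": ("D", 5.570, 0.0),
    "AD_rep": ("D", 5.570, 1.0),
}

_LJ_BOX_EDGE = 18.666
_LJ_COMPONENT_VOLUME = 3400.0
_LJ_A_RADIUS = 2.0


def _lj_count(radius: float) -> int:
    return int(round(_LJ_COMPONENT_VOLUME / ((4.0 / 3.0) * math.pi * radius ** 3)))


def gen_lj_mixture(case: str, seed: int = 0) -> ParticleSystem:
    """Two-component LJ mixture for the depletion experiments.

    'A' particles (radius 2 A) plus an equal-nominal-volume partner: 'B'
    (2 A), 'C' (3.509 A) or 'D' (5.570 A); counts are
    round(3400 / particle volume).  Positions are random with a loose
    overlap rejection; equilibrate with capped forces before production
    (see :func:`cytocrowd.bd_engine.run_simulation` ``soft_start``).
    """
    if case not in LJ_CASES:
        raise ValueError(f"unknown mixture case '{case}'; allowed {sorted(LJ_CASES)}")
    partner, pr, pq = LJ_CASES[case]
    n_a = _lj_count(_LJ_A_RADIUS)
    n_p = _lj_count(pr)
    radii = np.concatenate([np.full(n_a, _LJ_A_RADIUS), np.full(n_p, pr)])
    labels = np.array(["A"] * n_a + [partner] * n_p, dtype=object)
    charges = np.concatenate([np.zeros(n_a), np.full(n_p, pq)])
    box = SimulationBox(_LJ_BOX_EDGE)
    rng = _rng(seed)
    order = np.argsort(-radii)
    inv = np.argsort(order)
    rs = radii[order]
    placed = np.empty((len(rs), 3))
    for idx in range(len(rs)):
        best = None
        best_metric = -np.inf
        for _ in range(200):
            cand = rng.uniform(0, _LJ_BOX_EDGE, size=3)
            if idx == 0:
                best = cand
                break
            d = minimum_image(placed[:idx] - cand, _LJ_BOX_EDGE)
            rij = np.sqrt((d * d).sum(axis=1))
            metric = float((rij - rs[:idx] - rs[idx]).min())
            if metric > best_metric:
                best_metric = metric
                best = cand
            if metric >= -0.5:  # mild overlap tolerated; removed by soft start
                break
        placed[idx] = best
    return ParticleSystem(positions=placed[inv], radii=radii, labels=labels,
                          box=box, charges=charges,
                          meta={"case": case, "seed": int(seed),
                                "n_A": int(n_a), f"n_{partner}": int(n_p),
                                "size_convention": "radii; LJ Rmin_ij = ai+aj"})


# ---------------------------------------------------------------------------
# toy cells for spatial/structure metrics
# ---------------------------------------------------------------------------

@dataclass
class ToyCell:
    """Bead-cluster macromolecules plus point metabolites."""

    trajectory: Trajectory
    selections: list[AtomGroupSelection]
    macro_indices: np.ndarray        # bead indices of all macromolecules
    metabolite_indices: np.ndarray
    bead_radius: float


_CLUSTER_UNIT = np.array([
    [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
    [-1, 1, 1], [-1, 1, -1], [-1, -1, 1], [-1, -1, -1],
], dtype=float) / math.sqrt(3.0)


def gen_toy_cell(n_macromolecules: int, n_metabolites: int, seed: int = 0,
                 box_edge: float = 100.0, cluster_radius: float = 8.0,
                 bead_radius: float = 4.0, uniform_fraction: float = 1.0,
                 shell_distance: float = 5.0, n_frames: int = 1) -> ToyCell:
    """Toy system: 8-bead macromolecule clusters + point metabolites.

    A ``uniform_fraction`` of the metabolites is placed uniformly at random
    (ideal gas; re-sampled every frame so that downstream g(r) ~= 1), the
    remainder at exactly ``shell_distance`` from the surface of a random
    macromolecule bead.  Macromolecules are static across frames.  Each
    macromolecule carries core / ligand-site selections.
    """
    if n_macromolecules < 1 or n_metabolites < 1:
        raise ValueError("counts must be >= 1")
    rng = _rng(seed)
    beads_per = _CLUSTER_UNIT.shape[0]
    n_beads = n_macromolecules * beads_per
    centers = rng.uniform(0, box_edge, size=(n_macromolecules, 3))
    macro = (centers[:, None, :] + cluster_radius * _CLUSTER_UNIT[None]).reshape(-1, 3)
    macro = np.mod(macro, box_edge)
    n_uniform = int(round(uniform_fraction * n_metabolites))

    frames = np.empty((n_frames, n_beads + n_metabolites, 3))
    for f in range(n_frames):
        mets = np.empty((n_metabolites, 3))
        mets[:n_uniform] = rng.uniform(0, box_edge, size=(n_uniform, 3))
        for m in range(n_uniform, n_metabolites):
            b = rng.integers(0, n_beads)
            bead = macro[b]
            # outward radial direction so this bead is the nearest one
            direction = minimum_image(bead - centers[b // beads_per], box_edge)
            direction /= np.linalg.norm(direction)
            mets[m] = np.mod(bead + (bead_radius + shell_distance) * direction,
                             box_edge)
        frames[f, :n_beads] = macro
        frames[f, n_beads:] = mets

    labels = np.array(
        [f"macro{i // beads_per}" for i in range(n_beads)]
        + ["met"] * n_metabolites, dtype=object)
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      positions=frames, labels=labels,
                      box=SimulationBox(box_edge), wrapped=True)
    selections = []
    for i in range(n_macromolecules):
        base = i * beads_per
        idx = tuple(range(base, base + beads_per))
        selections.append(AtomGroupSelection(f"macro{i}_core", idx, "core"))
        selections.append(AtomGroupSelection(f"macro{i}_site1", idx[:2], "ligand_site_1"))
        selections.append(AtomGroupSelection(f"macro{i}_site2", idx[-2:], "ligand_site_2"))
    return ToyCell(trajectory=traj, selections=selections,
                   macro_indices=np.arange(n_beads),
                   metabolite_indices=np.arange(n_beads, n_beads + n_metabolites),
                   bead_radius=bead_radius)
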