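"""Brownian dynamics of polydisperse sphere systems.

The engine propagates overdamped Langevin (position) dynamics of spheres
whose dilute-limit mobility follows Stokes-Einstein, D = kBT/(6 pi eta a).
Excluded volume between macromolecule spheres is a half-harmonic repulsion

    V(r) = k/2 (r - ai - aj - delta)^2   for r < ai + aj + delta,  else 0

with defaults k = 10 kBT/delta^2 and delta = 1 A, i.e. V = 5 kBT when two
spheres touch (r = ai + aj).  Lennard-Jones and charged Lennard-Jones forms
are available for small-particle mixture experiments.  Two integration
schemes are provided: the first-order Ermak-McCammon update and the
second-order predictor-corrector of Iniesta and de la Torre which averages
forces between the predictor endpoints while reusing the same noise
realisation.  An optional far-field hydrodynamic variant propagates with the
Rotne-Prager-Yamakawa diffusion matrix and Cholesky-correlated noise
(dense-matrix cost; intended for small systems).

Randomness comes from a counter-based Philox stream keyed by the run seed,
so trajectories are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .io_core import ParticleSystem, Trajectory
from .units import (DEFAULT_TEMPERATURE, DEFAULT_VISCOSITY, bjerrum_length,
                    stokes_einstein_d)

__all__ = [
    "PotentialParams",
    "BDParams",
    "pair_energy",
    "suggest_timestep",
    "compute_forces",
    "bd_step",
    "run_simulation",
    "rpy_diffusion_matrix",
    "SingularConfigurationError",
    "InstabilityError",
    "OverlapError",
]

_FORMS = {"half_harmonic": 0, "lennard_jones": 1, "lj_coulomb": 2}
_SCHEMES = ("ermak_mccammon", "iniesta_delatorre", "fixman_rpy")


class SingularConfigurationError(ValueError):
    """Two particles at zero separation."""


class InstabilityError(RuntimeError):
    """A particle moved too far in a single step."""


class OverlapError(ValueError):
    """Initial configuration contains hard overlaps."""


@dataclass(frozen=True)
class PotentialParams:
    """Pair-potential parameters (energies in kBT, lengths in A)."""

    form: str = "half_harmonic"
    k: float = 10.0            # kBT/A^2 (default 10 kBT/delta^2 with delta = 1)
    delta: float = 1.0         # buffer distance, A
    epsilon: float = 0.2       # LJ well depth, kBT
    rel_permittivity: float = 80.0
    cutoff: float | None = None  # LJ/Coulomb cutoff; defaults to min(L/2, 5 a_max)

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown potential form '{self.form}'")
        if self.k <= 0 or self.delta <= 0:
            raise ValueError("k and delta must be positive")


@dataclass(frozen=True)
class BDParams:
    """Integrator parameters."""

    timestep: float = 8.0                  # ps
    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY   # mPa*s
    scheme: str = "iniesta_delatorre"
    seed: int = 0
    steps: int = 1000
    output_stride: int = 100

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be positive")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme '{self.scheme}'; allowed {_SCHEMES}")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")


# ---------------------------------------------------------------------------
# pair potential
# ---------------------------------------------------------------------------

def pair_energy(rij: float, ai: float, aj: float,
                params: PotentialParams | None = None) -> tuple[float, float]:
    """Pair energy (kBT) and force magnitude (kBT/A, positive = repulsive).

    Zero at and beyond the interaction range; continuous and once
    differentiable at the cutoff for the half-harmonic form.
    """
    params = params or PotentialParams()
    if rij <= 0:
        raise SingularConfigurationError(f"rij must be positive, got {rij}")
    pot = _FORMS[params.form]
    rcut = params.cutoff if params.cutoff is not None else np.inf
    lb = bjerrum_length(rel_permittivity=params.rel_permittivity)
    e, f = _kernels._pair_ef(rij, ai, aj, 0.0, 0.0, pot, params.k, params.delta,
                             params.epsilon, lb, rcut)
    return float(e), float(f)


def suggest_timestep(a_min: float, bd: BDParams | None = None) -> float:
    """Timestep 0.0005 a_min^2 / D(a_min) for the smallest particle (ps).

    With water viscosity at 298 K and a_min ~= 15.8 A this evaluates to
    ~= 8 ps, the production timestep used for crowded sphere systems.
    """
    if a_min <= 0:
        raise ValueError(f"a_min must be positive, got {a_min}")
    bd = bd or BDParams()
    d = stokes_einstein_d(a_min, bd.temperature, bd.viscosity)
    return 0.0005 * a_min ** 2 / d


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _interaction_range(radii: np.ndarray, params: PotentialParams, L: float) -> float:
    amax = float(radii.max())
    if params.form == "half_harmonic":
        return 2 * amax + params.delta
    if params.cutoff is not None:
        return params.cutoff
    return min(L / 2.0, 5.0 * amax)


def compute_forces(system: ParticleSystem, params: PotentialParams | None = None,
                   method: str = "auto") -> tuple[np.ndarray, float]:
    """Forces (kBT/A) and total energy (kBT) for one configuration.

    ``method``: 'brute' (all pairs), 'cell' (linked cells; requires the box
    to hold >= 4 cells of the interaction range) or 'auto'.  Both paths are
    exact with respect to the cutoff and agree to round-off.
    """
    params = params or PotentialParams()
    L = system.box.edge_length
    rcut = _interaction_range(system.radii, params, L)
    ncell = int(L // rcut) if rcut > 0 else 0
    if method == "cell" and ncell < 4:
        raise ValueError(
            f"cell list needs >= 4 cells per edge (got {ncell}); use 'brute'"
        )
    use_cells = (method == "cell") or (method == "auto" and ncell >= 4)
    pot = _FORMS[params.form]
    lb = bjerrum_length(rel_permittivity=params.rel_permittivity)
    out = np.empty((system.n_particles, 3))
    if use_cells:
        e = _kernels.forces_cells(system.positions, system.radii, system.charges,
                                  L, pot, params.k, params.delta, params.epsilon,
                                  lb, rcut, ncell, out)
    else:
        e = _kernels.forces_brute(system.positions, system.radii, system.charges,
                                  L, pot, params.k, params.delta, params.epsilon,
                                  lb, rcut, out)
    if np.isnan(e):
        raise SingularConfigurationError("two particles at zero separation")
    return out, float(e)


def system_energy(system: ParticleSystem, params: PotentialParams | None = None) -> float:
    return compute_forces(system, params)[1]


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def particle_diffusion_constants(radii: np.ndarray, bd: BDParams) -> np.ndarray:
    return np.array([stokes_einstein_d(a, bd.temperature, bd.viscosity)
                     for a in np.asarray(radii, float)])


def bd_step(system: ParticleSystem, bd: BDParams,
            params: PotentialParams | None = None,
            noise: np.ndarray | None = None,
            external_force: np.ndarray | None = None) -> np.ndarray:
    """One BD step; returns new positions (does not mutate the system).

    ``noise`` is an (N, 3) array of standard normal variates (pass zeros to
    isolate the drift term); drawn from a fresh Philox stream when omitted.
    ``external_force`` (kBT/A) is added to the pair forces: either a fixed
    (N, 3) array or a callable positions -> forces, re-evaluated at the
    predictor endpoint by the corrector scheme.
    """
    params = params or PotentialParams()
    n = system.n_particles
    dt = bd.timestep
    dpart = particle_diffusion_constants(system.radii, bd)
    if noise is None:
        rng = np.random.Generator(np.random.Philox(bd.seed))
        noise = rng.standard_normal((n, 3))
    noise = np.asarray(noise, float)

    def total_force(pos):
        sys_t = replace_positions(system, pos)
        f, _ = compute_forces(sys_t, params)
        if external_force is not None:
            if callable(external_force):
                f = f + np.asarray(external_force(pos), float)
            else:
                f = f + external_force
        return f

    f0 = total_force(system.positions)
    amp = np.sqrt(2.0 * dpart * dt)[:, None]
    drift0 = dpart[:, None] * f0 * dt
    rnd = amp * noise
    if bd.scheme == "ermak_mccammon":
        return system.positions + drift0 + rnd
    # predictor-corrector: same noise in both half-updates
    pred = system.positions + drift0 + rnd
    f1 = total_force(pred)
    return system.positions + 0.5 * dpart[:, None] * (f0 + f1) * dt + rnd


def replace_positions(system: ParticleSystem, positions: np.ndarray) -> ParticleSystem:
    return ParticleSystem(positions=positions, radii=system.radii,
                          labels=system.labels, box=system.box,
                          charges=system.charges, table=system.table,
                          meta=system.meta)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_simulation(system: ParticleSystem, bd: BDParams,
                   params: PotentialParams | None = None, *,
                   soft_start: bool = False,
                   equilibration_steps: int = 0,
                   force_cap: float = 10.0,
                   chunk_steps: int = 4000,
                   return_report: bool = False):
    """Propagate ``bd.steps`` BD steps and record every ``bd.output_stride``.

    The initial configuration must be free of hard overlaps unless
    ``soft_start`` is set, in which case forces are capped at ``force_cap``
    kBT/A during ``equilibration_steps`` un-recorded relaxation steps (and
    during production if overlaps could recur).  Output positions are
    unwrapped (continuous paths); wrap with
    :func:`cytocrowd.io_core.wrap_trajectory` for spatial analyses.
    """
    params = params or PotentialParams()
    if bd.scheme == "fixman_rpy":
        return _run_rpy(system, bd, params, return_report)
    if params.form == "half_harmonic" and not soft_start:
        gap = system.min_surface_gap()
        if gap < 0:
            raise OverlapError(
                f"initial configuration has hard overlaps (worst gap {gap:.3g} A); "
                "use soft_start=True with equilibration_steps for capped-force relaxation"
            )
    n = system.n_particles
    L = system.box.edge_length
    dt = bd.timestep
    pot = _FORMS[params.form]
    rcut = _interaction_range(system.radii, params, L)
    ncell = int(L // rcut)
    lb = bjerrum_length(rel_permittivity=params.rel_permittivity)
    dpart = particle_diffusion_constants(system.radii, bd)
    scheme = 0 if bd.scheme == "ermak_mccammon" else 1
    max_disp = L / 4.0
    rng = np.random.Generator(np.random.Philox(bd.seed))

    pos = system.positions.astype(float).copy()
    dummy_frames = np.empty((1, n, 3))
    dummy_times = np.empty(1)
    dummy_e = np.empty(1)

    # relaxation (not recorded, forces capped)
    done = 0
    while done < equilibration_steps:
        ns = min(chunk_steps, equilibration_steps - done)
        noise = rng.standard_normal((ns, n, 3))
        status, _ = _kernels.propagate(
            pos, system.radii, system.charges, dpart, L, dt, pot, params.k,
            params.delta, params.epsilon, lb, rcut, scheme, ncell, noise,
            force_cap if (soft_start or force_cap > 0) else 0.0, max_disp,
            0, equilibration_steps + 1, dummy_frames, dummy_times, dummy_e, 0)
        _check_status(status, done)
        done += ns

    stride = bd.output_stride
    n_frames = 1 + bd.steps // stride
    frames = np.empty((n_frames, n, 3))
    frame_times = np.empty(n_frames)
    energies = np.empty(n_frames)
    frames[0] = pos
    frame_times[0] = 0.0
    energies[0] = compute_forces(replace_positions(system, pos), params)[1]
    nframes = 1
    done = 0
    fcap_prod = force_cap if soft_start else 0.0
    while done < bd.steps:
        ns = min(chunk_steps, bd.steps - done)
        noise = rng.standard_normal((ns, n, 3))
        status, nframes = _kernels.propagate(
            pos, system.radii, system.charges, dpart, L, dt, pot, params.k,
            params.delta, params.epsilon, lb, rcut, scheme, ncell, noise,
            fcap_prod, max_disp, done, stride, frames, frame_times, energies,
            nframes)
        _check_status(status, done)
        done += ns

    traj = Trajectory(times=frame_times[:nframes], positions=frames[:nframes],
                      labels=system.labels, box=system.box, wrapped=False)
    if not return_report:
        return traj
    report = {
        "scheme": bd.scheme,
        "seed": bd.seed,
        "steps": bd.steps,
        "timestep_ps": dt,
        "output_stride": stride,
        "n_frames": int(nframes),
        "volume_fraction": system.volume_fraction(),
        "neighbor_search": "cell" if ncell >= 4 else "brute",
        "energy_trace_kBT": energies[:nframes].tolist(),
        "stable": True,
    }
    return traj, report


def _check_status(status: int, step_base: int) -> None:
    if status == _kernels.STATUS_OK:
        return
    if status == -2:
        raise SingularConfigurationError(
            f"zero pair separation near step {step_base}"
        )
    raise InstabilityError(
        f"particle {status} moved more than a quarter box in one step "
        f"near step {step_base}; reduce the timestep"
    )


# ---------------------------------------------------------------------------
# far-field hydrodynamics (Rotne-Prager-Yamakawa)
# ---------------------------------------------------------------------------

def rpy_diffusion_matrix(positions: np.ndarray, radii: np.ndarray,
                         temperature: float = DEFAULT_TEMPERATURE,
                         viscosity: float = DEFAULT_VISCOSITY) -> np.ndarray:
    """kBT x far-field RPY mobility (3N x 3N, A^2/ps).

    Self blocks are the Stokes-Einstein D = kBT/(6 pi eta a) times identity;
    off-diagonal blocks use the unequal-sphere far-field expansion, valid
    (and symmetric positive-definite) for non-overlapping pairs.
    """
    positions = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    n = positions.shape[0]
    c1 = stokes_einstein_d(1.0, temperature, viscosity)  # kBT/(6 pi eta), A^3/ps... per 1/a
    out = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i in range(n):
        out[3 * i:3 * i + 3, 3 * i:3 * i + 3] = (c1 / radii[i]) * eye
    for i in range(n - 1):
        for j in range(i + 1, n):
            rvec = positions[i] - positions[j]
            r = float(np.linalg.norm(rvec))
            if r < radii[i] + radii[j]:
                raise OverlapError(
                    f"particles {i} and {j} overlap (r={r:.3g} < "
                    f"{radii[i] + radii[j]:.3g}); far-field RPY is invalid -- "
                    "reject the configuration or use an overlap-corrected kernel"
                )
            rh = rvec / r
            outer = np.outer(rh, rh)
            a2 = radii[i] ** 2 + radii[j] ** 2
            # kBT/(8 pi eta r) [...] = (3/4) c1 / r [...]
            block = (0.75 * c1 / r) * ((1.0 + a2 / (3 * r * r)) * eye
                                       + (1.0 - a2 / (r * r)) * outer)
            out[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            out[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
    return out


def _run_rpy(system: ParticleSystem, bd: BDParams, params: PotentialParams,
             return_report: bool):
    """Midpoint BD with the far-field RPY diffusion matrix (small N only).

    The RPY tensor is divergence-free, so no extra drift term is needed;
    noise is Cholesky-correlated at the step start and reused in the
    corrector half-update.
    """
    n = system.n_particles
    dt = bd.timestep
    rng = np.random.Generator(np.random.Philox(bd.seed))
    pos = system.positions.astype(float).copy()
    stride = bd.output_stride
    frames = [pos.copy()]
    times = [0.0]
    for step in range(bd.steps):
        dmat = rpy_diffusion_matrix(pos, system.radii, bd.temperature, bd.viscosity)
        chol = np.linalg.cholesky(dmat)
        f0, _ = compute_forces(replace_positions(system, pos), params)
        xi = chol @ rng.standard_normal(3 * n)
        rnd = math.sqrt(2.0 * dt) * xi.reshape(n, 3)
        drift0 = (dmat @ f0.ravel()).reshape(n, 3) * dt
        pred = pos + drift0 + rnd
        try:
            dmat1 = rpy_diffusion_matrix(pred, system.radii, bd.temperature,
                                         bd.viscosity)
            f1, _ = compute_forces(replace_positions(system, pred), params)
            drift1 = (dmat1 @ f1.ravel()).reshape(n, 3) * dt
            pos = pos + 0.5 * (drift0 + drift1) + rnd
        except OverlapError:
            # predictor stepped into overlap: fall back to first order
            pos = pred
        if (step + 1) % stride == 0:
            frames.append(pos.copy())
            times.append((step + 1) * dt)
    traj = Trajectory(times=np.array(times), positions=np.stack(frames),
                      labels=system.labels, box=system.box, wrapped=False)
    if not return_report:
        return traj
    return traj, {"scheme": "fixman_rpy", "seed": bd.seed, "steps": bd.steps,
                  "stable": True}
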