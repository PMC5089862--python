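"""Structural observables: core RMSD with flexibility filtering, radius of
gyration, ligand-site distance and bound charge, and contact-pair counts.

RMSD is computed on backbone-equivalent atoms after best-fit superposition,
with highly flexible atoms removed first: atoms whose mean-square
fluctuation about the time-mean structure exceeds a threshold (3.0 A^2 for
proteins, 4.0 A^2 for tRNA) are excluded from the core, iterating
filter -> re-superpose to convergence (at most 5 rounds).  The radius of
gyration always uses all backbone atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AtomGroupSelection, Trajectory, minimum_image
from .rotation import kabsch_rotation

__all__ = [
    "StructureMetrics",
    "core_rmsd_rg",
    "radius_of_gyration",
    "ligand_site_metrics",
    "contact_pairs",
    "RMSF_THRESHOLDS",
]


def radius_of_gyration(positions: np.ndarray) -> np.ndarray:
    """Unweighted Rg per frame for (F, n, 3) or a single (n, 3) frame."""
    pos = np.asarray(positions, float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    if pos.shape[1] < 2:
        raise ValueError("Rg needs at least 2 atoms")
    centred = pos - pos.mean(axis=1, keepdims=True)
    rg = np.sqrt((centred ** 2).sum(axis=2).mean(axis=1))
    return rg[0] if single else rg

#: mean-square fluctuation thresholds (A^2) for core-atom filtering
RMSF_THRESHOLDS = {"protein": 3.0, "tRNA": 4.0}


@dataclass
class StructureMetrics:
    rmsd: np.ndarray             # A per frame, core atoms
    rg: np.ndarray               # A per frame, all atoms
    rmsf: np.ndarray             # A^2 per atom (mean-square fluctuation)
    core_atoms: np.ndarray       # indices into the selection retained
    kind: str


def _superpose_onto(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    rot = kabsch_rotation(frame, reference)
    return (rot @ (frame - frame.mean(axis=0)).T).T + reference.mean(axis=0)


def _msf(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Mean-square fluctuation per atom about the time mean, after
    superposing every frame onto ``reference``."""
    fitted = np.stack([_superpose_onto(f, reference) for f in frames])
    mean_structure = fitted.mean(axis=0)
    return ((fitted - mean_structure) ** 2).sum(axis=2).mean(axis=0)


def core_rmsd_rg(traj: Trajectory, reference: np.ndarray,
                 selection: np.ndarray | None = None,
                 kind: str = "protein", max_iterations: int = 5) -> StructureMetrics:
    """Core RMSD (flexible atoms filtered) and all-atom radius of gyration.

    ``reference`` holds the reference coordinates of the selected atoms.
    """
    if kind not in RMSF_THRESHOLDS:
        raise ValueError(f"kind must be one of {sorted(RMSF_THRESHOLDS)}")
    threshold = RMSF_THRESHOLDS[kind]
    sel = (np.arange(traj.n_particles) if selection is None
           else np.asarray(selection, int))
    frames = traj.positions[:, sel, :]
    reference = np.asarray(reference, float)
    if reference.shape != frames.shape[1:]:
        raise ValueError("reference must match the atom selection")

    core = np.arange(sel.size)
    msf_full = _msf(frames, reference)
    for _ in range(max_iterations):
        msf = _msf(frames[:, core], reference[core])
        keep = msf <= threshold
        if keep.all():
            break
        core = core[keep]
        if core.size < 3:
            raise ValueError(
                f"fewer than 3 core atoms remain after the {threshold} A^2 "
                "flexibility filter"
            )

    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fitted = _superpose_onto(frames[f, core], reference[core])
        rmsd[f] = np.sqrt(((fitted - reference[core]) ** 2).sum(axis=1).mean())

    rg = radius_of_gyration(frames)
    return StructureMetrics(rmsd=rmsd, rg=rg, rmsf=msf_full,
                            core_atoms=sel[core], kind=kind)


def ligand_site_metrics(traj: Trajectory, site1: AtomGroupSelection,
                        site2: AtomGroupSelection,
                        charged_entities: list[tuple[np.ndarray, float]] | None = None,
                        site_cutoff: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Inter-site distance d_lig and bound charge Q_tot per frame.

    ``charged_entities`` is a list of (atom-index array, total charge);
    an entity's charge counts toward Q_tot in a frame when the minimum
    distance from any of its atoms to any site atom is strictly below
    ``site_cutoff``.
    """
    site1.validate_for(traj.n_particles)
    site2.validate_for(traj.n_particles)
    idx1 = np.asarray(site1.indices, int)
    idx2 = np.asarray(site2.indices, int)
    L = traj.box.edge_length
    site_atoms = np.concatenate([idx1, idx2])
    d_lig = np.empty(traj.n_frames)
    q_tot = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        com1 = pos[idx1].mean(axis=0)
        com2 = pos[idx2].mean(axis=0)
        d_lig[f] = float(np.sqrt((minimum_image(com1 - com2, L) ** 2).sum()))
        if charged_entities:
            site_pos = pos[site_atoms]
            for atoms, charge in charged_entities:
                apos = pos[np.asarray(atoms, int)]
                d = minimum_image(apos[:, None, :] - site_pos[None, :, :], L)
                if float(np.sqrt((d * d).sum(axis=2)).min()) < site_cutoff:
                    q_tot[f] += charge
    return d_lig, q_tot


def contact_pairs(traj: Trajectory, selection_a: np.ndarray,
                  selection_b: np.ndarray, cutoff: float) -> np.ndarray:
    """Cross-selection atom pairs within ``cutoff`` per frame (minimum image)."""
    a = np.asarray(selection_a, int)
    b = np.asarray(selection_b, int)
    if np.intersect1d(a, b).size:
        raise ValueError("selections must be disjoint")
    L = traj.box.edge_length
    out = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        d = minimum_image(traj.positions[f, a][:, None, :]
                          - traj.positions[f, b][None, :, :], L)
        r = np.sqrt((d * d).sum(axis=2))
        out[f] = int((r < cutoff).sum())
    return out
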