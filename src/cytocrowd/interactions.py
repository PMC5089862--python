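"""Crowder coordination numbers and quinary-interaction statistics.

Local crowding around a target molecule is quantified by the instantaneous
coordination number Nc: the number of reference atoms (backbone-equivalent
beads in coarse-grained systems) of *other* macromolecules within a cutoff
(50 A default) of the target's closest reference atoms; the metabolite
variant Nc* counts crowder atoms within 25 A of the metabolite's centre of
mass.  Series are averaged over sliding windows (10 ns advanced by 500 ps
by default).

Weak, transient ("quinary") association between macromolecule groups is
measured by the centre-of-mass distance change over a trajectory,

    dd(alpha, beta) = <rc(alpha,beta)>_end - <rc(alpha,beta)>_start

with short-window (tau_short) time averages at both ends, restricted to
initially proximal pairs selected by the scaled distance
rbar = 2 rc / (Rs(alpha) + Rs(beta)) below a cutoff Rcut, averaged over
Rcut in [2, 3] to reduce noise.  Uncertainties come from repeated random
half-sampling of qualifying pairs (50 repeats; SE = SD/2).  Negative
dd_AB means effective attraction between groups A and B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.spatial import cKDTree

from .io_core import SpeciesTable, Trajectory, minimum_image

__all__ = [
    "CoordinationSeries",
    "PairDistanceRecord",
    "InteractionMatrix",
    "instantaneous_coordination",
    "coordination_series",
    "pair_distance_change",
    "group_interaction_matrix",
    "GLYCOLYTIC_ENZYMES",
]

#: glycolysis-pathway enzymes forming the 'glycolytic' group in real
#: composition tables (HPr kinase/phosphorylase, pyruvate kinase,
#: triosephosphate isomerase, GAPDH, phosphofructokinase, FBP aldolase,
#: enolase, G6P isomerase, phosphoglycerate mutase and kinase)
GLYCOLYTIC_ENZYMES = frozenset({
    "HPRK", "PYK", "TPIA", "GAPA", "PFKA", "FBA", "ENO", "PGI", "PGM", "PGK",
})

INTERACTION_GROUPS = ("glycolytic", "protein", "RNA", "huge")


@dataclass
class CoordinationSeries:
    """Window-averaged coordination numbers for a set of targets."""

    values: np.ndarray          # (n_windows, n_targets)
    window_times: np.ndarray    # ps, window centres
    cutoff: float
    window: float
    stride: float
    mode: str                   # 'macromolecule' or 'metabolite'

    def normalized(self) -> np.ndarray:
        """Per-target series scaled by the target's trajectory mean."""
        mean = self.values.mean(axis=0, keepdims=True)
        return self.values / np.where(mean > 0, mean, 1.0)


def instantaneous_coordination(frame_pos: np.ndarray, box_edge: float,
                               target_atoms: np.ndarray,
                               reference_atoms: np.ndarray,
                               molecule_of: np.ndarray,
                               cutoff: float = 50.0,
                               mode: str = "macromolecule") -> np.ndarray:
    """Nc per target molecule for one frame.

    ``target_atoms``: list of atom-index arrays, one per target.
    ``reference_atoms``: indices of all candidate crowder atoms.
    ``molecule_of``: molecule id per atom (crowder atoms of the target's own
    molecule are excluded).  In 'metabolite' mode the target position is its
    centre of mass.
    """
    if len(reference_atoms) == 0:
        raise ValueError("empty reference selection")
    wrapped = np.mod(frame_pos, box_edge)
    tree = cKDTree(wrapped[reference_atoms], boxsize=box_edge)
    out = np.zeros(len(target_atoms), dtype=int)
    ref_mol = molecule_of[reference_atoms]
    for t, atoms in enumerate(target_atoms):
        atoms = np.asarray(atoms, int)
        if atoms.size == 0:
            raise ValueError(f"target {t} has an empty atom selection")
        own = molecule_of[atoms[0]]
        if mode == "metabolite":
            com = _periodic_com(frame_pos[atoms], box_edge)
            neigh = tree.query_ball_point(np.mod(com, box_edge), cutoff)
            idx = np.unique(np.asarray(neigh, dtype=int))
        else:
            neigh = tree.query_ball_point(wrapped[atoms], cutoff)
            idx = np.unique(np.concatenate([np.asarray(n, dtype=int)
                                            for n in neigh])) if len(neigh) else np.array([], int)
        if idx.size:
            out[t] = int((ref_mol[idx] != own).sum())
    return out


def _periodic_com(pos: np.ndarray, box_edge: float) -> np.ndarray:
    """Centre of mass robust to wrapping (unwrap about the first atom)."""
    rel = minimum_image(pos - pos[0], box_edge)
    return pos[0] + rel.mean(axis=0)


def coordination_series(traj: Trajectory, target_atoms: list[np.ndarray],
                        reference_atoms: np.ndarray, molecule_of: np.ndarray,
                        cutoff: float = 50.0, window: float = 10_000.0,
                        stride: float = 500.0,
                        mode: str = "macromolecule") -> CoordinationSeries:
    """Sliding-window time averages of the instantaneous coordination number."""
    dt_frame = traj.frame_interval()
    per_frame = np.stack([
        instantaneous_coordination(traj.positions[f], traj.box.edge_length,
                                   target_atoms, reference_atoms, molecule_of,
                                   cutoff, mode)
        for f in range(traj.n_frames)
    ]).astype(float)
    w = max(1, int(round(window / dt_frame)))
    s = max(1, int(round(stride / dt_frame)))
    starts = np.arange(0, traj.n_frames - w + 1, s)
    if starts.size == 0:
        starts = np.array([0])
        w = traj.n_frames
    vals = np.stack([per_frame[a:a + w].mean(axis=0) for a in starts])
    centres = traj.times[starts] + 0.5 * (w - 1) * dt_frame
    return CoordinationSeries(values=vals, window_times=centres, cutoff=cutoff,
                              window=window, stride=stride, mode=mode)


# ---------------------------------------------------------------------------
# pair distance changes
# ---------------------------------------------------------------------------

@dataclass
class PairDistanceRecord:
    pair: tuple[int, int]
    rc_initial: float        # A, tau_short-averaged
    rc_final: float
    rbar_initial: float      # scaled distance 2 rc / (Rs_a + Rs_b)
    delta_d: float           # A
    tau_short: float


def _com_distance_series(traj: Trajectory, i: int, j: int) -> np.ndarray:
    d = minimum_image(traj.positions[:, i, :] - traj.positions[:, j, :],
                      traj.box.edge_length)
    return np.sqrt((d * d).sum(axis=1))


def pair_distance_change(traj: Trajectory, alpha: int, beta: int,
                         tau_short: float, radii: np.ndarray | None = None) -> PairDistanceRecord:
    """Centre-of-mass distance change between first and last tau_short windows."""
    dt_frame = traj.frame_interval()
    span = traj.times[-1] - traj.times[0]
    if tau_short >= span / 2:
        raise ValueError(f"tau_short ({tau_short} ps) must be < half the span ({span} ps)")
    nw = max(1, int(round(tau_short / dt_frame)))
    rc = _com_distance_series(traj, alpha, beta)
    rc0 = float(rc[:nw].mean())
    rc1 = float(rc[-nw:].mean())
    if radii is not None:
        rbar = 2.0 * rc0 / (radii[alpha] + radii[beta])
    else:
        rbar = np.nan
    return PairDistanceRecord(pair=(alpha, beta), rc_initial=rc0, rc_final=rc1,
                              rbar_initial=rbar, delta_d=rc1 - rc0,
                              tau_short=tau_short)


# ---------------------------------------------------------------------------
# group interaction matrix
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Group-pair dd_AB (A) with standard errors; symmetric in group order."""

    delta_d: dict[tuple[str, str], float]
    stderr: dict[tuple[str, str], float]
    n_pairs: dict[tuple[str, str], int]
    absent: set[tuple[str, str]] = field(default_factory=set)
    rcut_profile: dict[tuple[str, str], dict[float, float]] = field(default_factory=dict)

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        return tuple(sorted((a, b)))  # type: ignore[return-value]

    def get(self, a: str, b: str) -> tuple[float, float]:
        k = self.key(a, b)
        if k in self.absent:
            raise KeyError(f"no qualifying pairs for group pair {k}")
        return self.delta_d[k], self.stderr[k]


def group_interaction_matrix(traj: Trajectory, table: SpeciesTable,
                             tau_short: float,
                             rcut_values: np.ndarray | None = None,
                             n_resample: int = 50,
                             selection_rcut: float = 3.0,
                             seed: int = 0,
                             groups: tuple[str, ...] = INTERACTION_GROUPS,
                             instantaneous_selection: bool = False) -> InteractionMatrix:
    """dd_AB across macromolecule groups with resampled standard errors.

    Pairs qualify by initial scaled distance rbar < Rcut (tau_short-averaged
    by default; ``instantaneous_selection`` uses the first frame only);
    dd_AB(Rcut) is averaged over ``rcut_values`` (default 2..3 in steps of
    0.25).  Uncertainty: ``n_resample`` random halves of the qualifying
    pairs (sampling without replacement, seeded), SE = SD/2.  A group pair
    with no qualifying pairs is flagged absent, not zero.
    """
    if rcut_values is None:
        rcut_values = np.arange(2.0, 3.01, 0.25)
    rcut_values = np.asarray(rcut_values, float)
    dt_frame = traj.frame_interval()
    nw = max(1, int(round(tau_short / dt_frame)))
    radii = np.array([table.radius_of(l) for l in traj.labels])
    group_of = np.array([table.group_of(l) for l in traj.labels], dtype=object)
    n = traj.n_particles
    span = traj.times[-1] - traj.times[0]
    if tau_short >= span / 2:
        raise ValueError("tau_short must be < half the trajectory span")

    # initial/final window-averaged pair distances for candidate pairs
    keep = np.flatnonzero(np.isin(group_of, groups))
    rng = np.random.Generator(np.random.Philox(int(seed)))
    records: dict[tuple[str, str], list[tuple[float, float]]] = {}
    L = traj.box.edge_length
    pos0 = traj.positions[:nw][:, keep, :]
    pos1 = traj.positions[-nw:][:, keep, :]
    first = traj.positions[0][keep]
    for ii in range(len(keep) - 1):
        i = keep[ii]
        d0 = minimum_image(pos0[:, ii + 1:, :] - pos0[:, ii:ii + 1, :], L)
        r0 = np.sqrt((d0 * d0).sum(axis=2)).mean(axis=0)
        if instantaneous_selection:
            di = minimum_image(first[ii + 1:] - first[ii], L)
            rsel = np.sqrt((di * di).sum(axis=1))
        else:
            rsel = r0
        d1 = minimum_image(pos1[:, ii + 1:, :] - pos1[:, ii:ii + 1, :], L)
        r1 = np.sqrt((d1 * d1).sum(axis=2)).mean(axis=0)
        jj_all = np.arange(ii + 1, len(keep))
        j_idx = keep[jj_all]
        rbar = 2.0 * rsel / (radii[i] + radii[j_idx])
        sel = rbar < selection_rcut
        for off in np.flatnonzero(sel):
            j = j_idx[off]
            key = InteractionMatrix.key(str(group_of[i]), str(group_of[j]))
            records.setdefault(key, []).append(
                (float(rbar[off]), float(r1[off] - r0[off])))

    delta_d: dict[tuple[str, str], float] = {}
    stderr: dict[tuple[str, str], float] = {}
    n_pairs: dict[tuple[str, str], int] = {}
    absent: set[tuple[str, str]] = set()
    profile: dict[tuple[str, str], dict[float, float]] = {}
    for a, b in combinations_with_replacement(sorted(set(groups)), 2):
        key = InteractionMatrix.key(a, b)
        recs = records.get(key, [])
        rbars = np.array([r[0] for r in recs])
        dds = np.array([r[1] for r in recs])
        qualifying = rbars < rcut_values.max()
        if not recs or qualifying.sum() == 0:
            absent.add(key)
            continue
        n_pairs[key] = int(qualifying.sum())
        prof = {}
        for rc in rcut_values:
            m = rbars < rc
            prof[float(rc)] = float(dds[m].mean()) if m.any() else np.nan
        profile[key] = prof
        delta_d[key] = float(np.nanmean(list(prof.values())))
        # resampling: random halves of the qualifying pair set
        qual_idx = np.flatnonzero(qualifying)
        estimates = []
        for _ in range(n_resample):
            half = rng.choice(qual_idx, size=max(1, qual_idx.size // 2),
                              replace=False)
            vals = []
            for rc in rcut_values:
                m = rbars[half] < rc
                if m.any():
                    vals.append(float(dds[half][m].mean()))
            if vals:
                estimates.append(float(np.mean(vals)))
        sd = float(np.std(estimates, ddof=1)) if len(estimates) > 1 else 0.0
        stderr[key] = sd / 2.0
    return InteractionMatrix(delta_d=delta_d, stderr=stderr, n_pairs=n_pairs,
                             absent=absent, rcut_profile=profile)
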