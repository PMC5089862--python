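"""Spatial distributions of small molecules around macromolecules.

The proximal radial distribution function g(r) resolves small-molecule
density as a function of the distance to the *nearest* macromolecule
surface, normalised shell-by-shell by the theoretically accessible volume
V(r):

    g(r) = n(r) / ( V(r) * rho_inf )

where n(r) counts target atoms in the shell at nearest-surface distance r
(0.5 A histogram bins), V(r) is obtained by dividing the periodic box into
1 A voxels and counting those whose centre falls in the shell (voxels
inside the van der Waals surface are excluded), and rho_inf is the density
averaged over the far-field plateau (20-25 A by default).  Per-atom radii
come from a configurable table; for coarse-grained fixtures the sphere
radius itself plays the role of the van der Waals radius, and zero radii
reproduce plain nearest-atom distances.

Three-dimensional number-density grids around a target body are
accumulated after removing the body's rigid motion (best-fit superposition
onto a reference), with optional symmetry averaging through a coordinate
map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_core import SimulationBox, Trajectory, minimum_image
from .rotation import kabsch_rotation

__all__ = [
    "AccessibleVolume",
    "ProximalRDF",
    "DensityGrid",
    "nearest_surface_distances",
    "accessible_volume_profile",
    "proximal_rdf",
    "density_grid3d",
]


def nearest_surface_distances(points: np.ndarray, macro_pos: np.ndarray,
                              macro_radii: np.ndarray, box_edge: float) -> np.ndarray:
    """Distance from each point to the nearest macromolecule atom surface.

    Minimum-image metric; with all radii zero this is the nearest-atom
    distance.  Negative values lie inside the van der Waals surface.
    """
    points = np.mod(np.asarray(points, float), box_edge)
    macro_pos = np.mod(np.asarray(macro_pos, float), box_edge)
    macro_radii = np.asarray(macro_radii, float)
    if macro_pos.shape[0] == 0:
        raise ValueError("no macromolecule atoms")
    best = np.full(points.shape[0], np.inf)
    # group atoms by radius so a KD-tree nearest query is exact per group
    for radius in np.unique(macro_radii):
        sel = macro_radii == radius
        tree = cKDTree(macro_pos[sel], boxsize=box_edge)
        d, _ = tree.query(points)
        np.minimum(best, d - radius, out=best)
    return best


@dataclass
class AccessibleVolume:
    """Voxel-counted shell volumes V(r) by nearest-surface distance."""

    bin_edges: np.ndarray       # A, width 0.5 by default
    volume: np.ndarray          # A^3 per shell
    excluded_volume: float      # voxels inside the van der Waals surface
    beyond_volume: float        # voxels past r_max
    voxel_volume: float
    box_volume: float

    def conservation_error(self) -> float:
        """| sum V + excluded + beyond - box | in voxel units (0 exactly)."""
        total = self.volume.sum() + self.excluded_volume + self.beyond_volume
        return abs(total - self.box_volume)


def accessible_volume_profile(macro_pos: np.ndarray, macro_radii: np.ndarray,
                              box: SimulationBox, grid: float = 1.0,
                              r_max: float = 25.0, bin_width: float = 0.5) -> AccessibleVolume:
    """V(r) by counting 1 A voxels whose centre lies in each distance shell.

    Every voxel of the box is assigned exactly once: to a shell, to the
    excluded (inside-surface) volume, or to the beyond-r_max volume, so the
    total is conserved exactly in voxel units.
    """
    L = box.edge_length
    n_side = max(1, int(round(L / grid)))
    gs = L / n_side
    centers_1d = (np.arange(n_side) + 0.5) * gs
    xx, yy, zz = np.meshgrid(centers_1d, centers_1d, centers_1d, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    d = nearest_surface_distances(centers, macro_pos, macro_radii, L)
    vox = gs ** 3
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    excluded = float((d < 0).sum()) * vox
    beyond = float((d >= edges[-1]).sum()) * vox
    return AccessibleVolume(bin_edges=edges, volume=counts.astype(float) * vox,
                            excluded_volume=excluded, beyond_volume=beyond,
                            voxel_volume=vox, box_volume=float(n_side ** 3) * vox)


@dataclass
class ProximalRDF:
    bin_edges: np.ndarray      # A
    n_r: np.ndarray            # mean counts per shell per frame
    v_r: np.ndarray            # A^3, frame-averaged accessible volume
    rho_r: np.ndarray          # A^-3
    rho_inf: float             # far-field plateau density
    g_r: np.ndarray            # rho / rho_inf
    interacting_fraction: float
    interaction_cutoff: float
    plateau_flat: bool         # warning flag: False if the plateau has slope

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def proximal_rdf(traj: Trajectory, metabolite_selection: np.ndarray,
                 macromolecule_selection: np.ndarray,
                 macro_radii: np.ndarray | None = None,
                 plateau_range: tuple[float, float] = (20.0, 25.0),
                 r_max: float = 25.0, bin_width: float = 0.5,
                 grid: float = 1.0, frame_stride: int = 1,
                 interaction_cutoff: float = 8.0) -> ProximalRDF:
    """Proximal g(r) of metabolites vs distance to the nearest surface.

    Also reports the interacting fraction: the share of metabolite samples
    with nearest-surface distance below ``interaction_cutoff``.
    """
    if plateau_range[1] > r_max:
        raise ValueError("plateau range must lie within r_max")
    met = np.asarray(metabolite_selection, int)
    mac = np.asarray(macromolecule_selection, int)
    if macro_radii is None:
        macro_radii = np.zeros(mac.size)
    macro_radii = np.asarray(macro_radii, float)
    L = traj.box.edge_length
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    vol = np.zeros(edges.size - 1)
    frames = range(0, traj.n_frames, frame_stride)
    n_frames = 0
    n_interacting = 0
    n_total = 0
    # static crowders (common in fixtures): V(r) is frame-independent
    macro_static = bool(np.all(traj.positions[:, mac, :]
                               == traj.positions[0, mac, :]))
    av_static = None
    for f in frames:
        pos = traj.positions[f]
        d = nearest_surface_distances(pos[met], pos[mac], macro_radii, L)
        c, _ = np.histogram(d, bins=edges)
        counts += c
        if macro_static:
            if av_static is None:
                av_static = accessible_volume_profile(
                    pos[mac], macro_radii, traj.box, grid=grid, r_max=r_max,
                    bin_width=bin_width)
            av = av_static
        else:
            av = accessible_volume_profile(pos[mac], macro_radii, traj.box,
                                           grid=grid, r_max=r_max,
                                           bin_width=bin_width)
        vol += av.volume
        n_interacting += int((d < interaction_cutoff).sum())
        n_total += d.size
        n_frames += 1
    counts /= n_frames
    vol /= n_frames
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(vol > 0, counts / vol, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    plateau = (centers >= plateau_range[0]) & (centers < plateau_range[1]) & (vol > 0)
    if not plateau.any() or rho[plateau].sum() == 0:
        raise ValueError("empty plateau: cannot normalise g(r)")
    rho_inf = float(rho[plateau].mean())
    # slope test on the plateau band: warn (flag) if rho_inf would be biased
    slope = np.polyfit(centers[plateau], rho[plateau], 1)[0]
    flat = abs(slope) * (plateau_range[1] - plateau_range[0]) < 0.2 * rho_inf
    return ProximalRDF(bin_edges=edges, n_r=counts, v_r=vol, rho_r=rho,
                       rho_inf=rho_inf, g_r=rho / rho_inf,
                       interacting_fraction=n_interacting / max(n_total, 1),
                       interaction_cutoff=interaction_cutoff,
                       plateau_flat=bool(flat))


# ---------------------------------------------------------------------------
# 3D density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    counts: np.ndarray          # voxel counts (after optional symmetry doubling)
    n_frames: int
    n_accumulated: int          # ligand samples accumulated before symmetry
    voxel_volume: float
    skipped_frames: list[int]

    def density(self) -> np.ndarray:
        """Number density in A^-3 (counts / frames / voxel volume),
        divided by 2 when symmetry duplication doubled the counts."""
        dup = self.counts.sum() / max(self.n_accumulated, 1)
        return self.counts / (self.n_frames * self.voxel_volume * dup)

    def to_opendx(self, path) -> None:
        """Write the number density as an OpenDX scalar field (text)."""
        dens = self.density()
        nx, ny, nz = dens.shape
        ex, ey, ez = self.edges
        dx = float(ex[1] - ex[0])
        origin = (float(ex[0] + dx / 2), float(ey[0] + dx / 2),
                  float(ez[0] + dx / 2))
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin %.6f %.6f %.6f\n" % origin)
            fh.write(f"delta {dx:.6f} 0 0\ndelta 0 {dx:.6f} 0\ndelta 0 0 {dx:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items "
                     f"{dens.size} data follows\n")
            flat = dens.ravel()
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.8e}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')
            fh.write('component "positions" value 1\n')
            fh.write('component "connections" value 2\n')
            fh.write('component "data" value 3\n')


def density_grid3d(traj: Trajectory, target_body: np.ndarray,
                   ligand_selection: np.ndarray,
                   reference: np.ndarray | None = None,
                   grid: float = 1.0, extent: float = 30.0,
                   symmetry_map=None, frame_stride: int = 1,
                   rmsd_threshold: float = np.inf) -> DensityGrid:
    """Voxel-accumulated ligand density in the target's reference frame.

    Each frame, the rigid motion of ``target_body`` is removed by best-fit
    superposition onto ``reference`` (default: the first frame) and ligand
    positions are transformed with the same operator before accumulation
    into 1 A voxels centred on the reference centroid.  Frames whose
    post-fit RMSD exceeds ``rmsd_threshold`` are skipped (logged).  With a
    ``symmetry_map`` (callable on (n, 3) reference-frame coordinates),
    counts are duplicated through the map before normalisation.
    """
    tb = np.asarray(target_body, int)
    lig = np.asarray(ligand_selection, int)
    if reference is None:
        reference = traj.positions[0, tb]
    reference = np.asarray(reference, float)
    ref_centroid = reference.mean(axis=0)
    half = extent / 2.0
    n_side = max(1, int(round(extent / grid)))
    edges_1d = np.linspace(-half, half, n_side + 1)
    counts = np.zeros((n_side, n_side, n_side))
    L = traj.box.edge_length
    skipped: list[int] = []
    n_frames = 0
    n_acc = 0
    for f in range(0, traj.n_frames, frame_stride):
        body = traj.positions[f, tb]
        rot = kabsch_rotation(body, reference)
        body_centroid = body.mean(axis=0)
        fitted = (rot @ (body - body_centroid).T).T + ref_centroid
        rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
        if rmsd > rmsd_threshold:
            skipped.append(f)
            continue
        # ligand coordinates relative to the body, minimum image
        rel = minimum_image(traj.positions[f, lig] - body_centroid, L)
        lab = (rot @ rel.T).T  # reference-frame offsets from the centroid
        samples = [lab]
        if symmetry_map is not None:
            samples.append(np.asarray(symmetry_map(lab), float))
        for s in samples:
            h, _ = np.histogramdd(s, bins=(edges_1d, edges_1d, edges_1d))
            counts += h
        n_acc += lab.shape[0]
        n_frames += 1
    if n_frames == 0:
        raise ValueError("all frames skipped; rmsd_threshold too strict")
    return DensityGrid(edges=(edges_1d, edges_1d, edges_1d), counts=counts,
                       n_frames=n_frames, n_accumulated=n_acc,
                       voxel_volume=float(grid ** 3), skipped_frames=skipped)
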