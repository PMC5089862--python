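"""Data model, file formats and periodic-boundary geometry.

Everything downstream works on three containers:

* :class:`SpeciesTable` -- per-species Stokes radii, copy numbers, group
  labels and charges (the source of dilute diffusion constants and packing);
* :class:`SimulationBox` -- a cubic periodic box;
* :class:`Trajectory` -- frames x particles x 3 coordinates with times,
  per-particle species labels and a wrapped/unwrapped flag.

Coordinates are stored wrapped on disk; analysis stages that need unbroken
paths (mean-square displacements) unwrap on load.  All distances use the
minimum-image convention in a cubic box; triclinic cells are not supported.

Canonical text format for trajectories is extended XYZ (human-diffable);
DCD is supported for bulk runs via MDAnalysis with a JSON sidecar carrying
species labels and times (DCD itself stores neither).  Species tables are
TSV, configuration is YAML/JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SpeciesTable",
    "SimulationBox",
    "Trajectory",
    "ParticleSystem",
    "AtomGroupSelection",
    "SpeciesTableError",
    "TrajectoryFormatError",
    "UnwrapAmbiguityError",
    "read_species_table",
    "minimum_image",
    "minimum_image_distance",
    "write_trajectory",
    "read_trajectory",
    "trajectory_roundtrip",
    "unwrap_trajectory",
    "wrap_trajectory",
]

#: closed set of species group labels
GROUPS = frozenset({"glycolytic", "protein", "RNA", "huge", "metabolite", "ion"})

#: roles for atom-group selections
SELECTION_ROLES = frozenset(
    {"core", "ligand_site_1", "ligand_site_2", "active_site", "reference_atoms"}
)


class SpeciesTableError(ValueError):
    """Malformed or invalid species table."""


class TrajectoryFormatError(ValueError):
    """Trajectory file does not conform to the requested format."""


class UnwrapAmbiguityError(ValueError):
    """Per-frame displacements too large to unwrap unambiguously."""


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, edge_length: float) -> np.ndarray:
    """Minimum-image displacement vector(s) in a cubic box."""
    delta = np.asarray(delta, dtype=float)
    return delta - edge_length * np.rint(delta / edge_length)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, edge_length: float) -> np.ndarray:
    """Minimum-image distance between points ``a`` and ``b``."""
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), edge_length)
    return np.sqrt((d * d).sum(axis=-1))


@dataclass(frozen=True)
class SimulationBox:
    """Cubic periodic simulation box with edge length in A."""

    edge_length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if not self.edge_length > 0:
            raise ValueError(f"edge_length must be positive, got {self.edge_length}")

    @property
    def volume(self) -> float:
        return float(self.edge_length) ** 3

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L)."""
        return np.mod(np.asarray(x, dtype=float), self.edge_length)

    def minimum_image(self, delta: np.ndarray) -> np.ndarray:
        return minimum_image(delta, self.edge_length)

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return minimum_image_distance(a, b, self.edge_length)


# ---------------------------------------------------------------------------
# species table
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("name", "stokes_radius", "copies", "group")


@dataclass
class SpeciesTable:
    """Validated per-species table.

    Columns: ``name`` (unique identifier), ``stokes_radius`` (A, > 0),
    ``copies`` (non-negative int), ``group`` (one of :data:`GROUPS`),
    ``charge`` (elementary charges, default 0) and optional
    ``molecular_weight`` (Da) for the Rs--Mw power-law fit.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in _REQUIRED_COLS:
            if col not in df.columns:
                raise SpeciesTableError(f"missing required column '{col}'")
        if "charge" not in df.columns:
            df["charge"] = 0.0
        if "molecular_weight" not in df.columns:
            df["molecular_weight"] = np.nan
        try:
            df["stokes_radius"] = df["stokes_radius"].astype(float)
            df["copies"] = df["copies"].astype(int)
            df["charge"] = df["charge"].astype(float)
            df["molecular_weight"] = df["molecular_weight"].astype(float)
        except (TypeError, ValueError) as exc:
            raise SpeciesTableError(f"malformed numeric field: {exc}") from exc
        if df["name"].duplicated().any():
            dupes = df.loc[df["name"].duplicated(), "name"].tolist()
            raise SpeciesTableError(f"duplicate species names: {dupes}")
        bad_r = df.index[~(df["stokes_radius"] > 0)].tolist()
        if bad_r:
            raise SpeciesTableError(
                f"stokes_radius must be > 0; offending rows (0-based): {bad_r}"
            )
        if (df["copies"] < 0).any():
            raise SpeciesTableError("copies must be non-negative")
        bad_g = sorted(set(df["group"]) - GROUPS)
        if bad_g:
            raise SpeciesTableError(
                f"unknown group labels {bad_g}; allowed: {sorted(GROUPS)}"
            )
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SpeciesTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            df = pd.read_csv(path, sep="\t", comment="#")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise SpeciesTableError(f"cannot parse {path}: {exc}") from exc
        if df.empty or df.columns.size == 0:
            raise SpeciesTableError(f"{path}: no header row / empty table")
        return cls(df)

    def to_tsv(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}: {value}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    # -- accessors --------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return self.frame["name"].tolist()

    @property
    def n_species(self) -> int:
        return len(self.frame)

    @property
    def total_particles(self) -> int:
        return int(self.frame["copies"].sum())

    def row(self, name: str) -> pd.Series:
        sel = self.frame[self.frame["name"] == name]
        if sel.empty:
            raise KeyError(name)
        return sel.iloc[0]

    def radius_of(self, name: str) -> float:
        return float(self.row(name)["stokes_radius"])

    def group_of(self, name: str) -> str:
        return str(self.row(name)["group"])

    def charge_of(self, name: str) -> float:
        return float(self.row(name)["charge"])

    def particle_labels(self) -> np.ndarray:
        """Per-particle species name, copies expanded in table order."""
        out: list[str] = []
        for _, r in self.frame.iterrows():
            out.extend([r["name"]] * int(r["copies"]))
        return np.array(out, dtype=object)

    def particle_radii(self) -> np.ndarray:
        out: list[float] = []
        for _, r in self.frame.iterrows():
            out.extend([float(r["stokes_radius"])] * int(r["copies"]))
        return np.array(out, dtype=float)

    def particle_charges(self) -> np.ndarray:
        out: list[float] = []
        for _, r in self.frame.iterrows():
            out.extend([float(r["charge"])] * int(r["copies"]))
        return np.array(out, dtype=float)

    def sphere_volume(self) -> float:
        """Total volume of all spheres, sum over copies of (4/3) pi Rs^3."""
        r = self.frame["stokes_radius"].to_numpy()
        n = self.frame["copies"].to_numpy()
        return float((4.0 / 3.0) * np.pi * (r ** 3 * n).sum())

    def scaled(self, scale_factor: int) -> "SpeciesTable":
        """Copy with all copy numbers multiplied by ``scale_factor``."""
        if scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        df = self.frame.copy()
        df["copies"] = df["copies"] * int(scale_factor)
        return SpeciesTable(df)


def read_species_table(path: str | Path) -> SpeciesTable:
    """Read and validate a TSV species table (see :class:`SpeciesTable`)."""
    return SpeciesTable.from_tsv(path)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomGroupSelection:
    """Named particle-index selection with a functional role."""

    label: str
    indices: tuple[int, ...]
    role: str = "core"

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError(f"selection '{self.label}' is empty")
        if self.role not in SELECTION_ROLES:
            raise ValueError(f"unknown role '{self.role}'; allowed: {sorted(SELECTION_ROLES)}")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))

    def validate_for(self, n_particles: int) -> None:
        if min(self.indices) < 0 or max(self.indices) >= n_particles:
            raise IndexError(
                f"selection '{self.label}' has indices outside [0, {n_particles})"
            )

    def to_dict(self) -> dict:
        return {"label": self.label, "indices": list(self.indices), "role": self.role}

    @classmethod
    def from_dict(cls, d: dict) -> "AtomGroupSelection":
        return cls(label=d["label"], indices=tuple(d["indices"]), role=d.get("role", "core"))


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames x particles x 3 coordinates with times and species labels.

    ``orientations`` optionally carries per-frame rotation matrices
    (n_frames, n_bodies, 3, 3) for rigid-body tracking.
    """

    times: np.ndarray                  # (F,) ps, strictly increasing
    positions: np.ndarray              # (F, N, 3) A
    labels: np.ndarray                 # (N,) species names
    box: SimulationBox
    wrapped: bool = False
    orientations: np.ndarray | None = None  # (F, B, 3, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(f"positions must be (F, N, 3), got {self.positions.shape}")
        if self.n_frames < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.times.shape != (self.n_frames,):
            raise ValueError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.labels.shape != (self.n_particles,):
            raise ValueError("every particle needs a species label")
        if self.wrapped:
            L = self.box.edge_length
            if np.any(self.positions < 0) or np.any(self.positions >= L):
                raise ValueError("wrapped trajectory has coordinates outside [0, L)")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            if (self.orientations.ndim != 4
                    or self.orientations.shape[0] != self.n_frames
                    or self.orientations.shape[2:] != (3, 3)):
                raise ValueError("orientations must be (F, B, 3, 3)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def frame_interval(self) -> float:
        """Uniform frame spacing in ps (error if non-uniform)."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a frame interval")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-9):
            raise ValueError("frame times are not uniformly spaced")
        return float(dts[0])

    def species_index(self, table: SpeciesTable) -> np.ndarray:
        """Map each particle to its row index in ``table``."""
        lut = {name: i for i, name in enumerate(table.names)}
        try:
            return np.array([lut[l] for l in self.labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"particle label {exc} not present in species table") from exc

    def indices_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def copy(self) -> "Trajectory":
        return Trajectory(
            times=self.times.copy(),
            positions=self.positions.copy(),
            labels=self.labels.copy(),
            box=self.box,
            wrapped=self.wrapped,
            orientations=None if self.orientations is None else self.orientations.copy(),
        )


@dataclass
class ParticleSystem:
    """A single configuration of spheres: the input to the BD engine."""

    positions: np.ndarray          # (N, 3) A
    radii: np.ndarray              # (N,) A
    labels: np.ndarray             # (N,) species names
    box: SimulationBox
    charges: np.ndarray | None = None   # (N,) e
    table: SpeciesTable | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if self.radii.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("radii and labels must match particle count")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if self.charges is None:
            self.charges = np.zeros(n)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise ValueError("charges must match particle count")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def volume_fraction(self) -> float:
        return float(((4.0 / 3.0) * np.pi * self.radii ** 3).sum() / self.box.volume)

    def min_surface_gap(self) -> float:
        """min over pairs of (rij - ai - aj); >= 0 means no hard overlap."""
        n = self.n_particles
        if n < 2:
            return np.inf
        best = np.inf
        L = self.box.edge_length
        for i in range(n - 1):
            d = minimum_image(self.positions[i + 1:] - self.positions[i], L)
            rij = np.sqrt((d * d).sum(axis=1))
            gap = rij - self.radii[i + 1:] - self.radii[i]
            best = min(best, float(gap.min()))
        return best


# ---------------------------------------------------------------------------
# wrapping / unwrapping
# ---------------------------------------------------------------------------

def wrap_trajectory(traj: Trajectory) -> Trajectory:
    """Wrap all coordinates into [0, L)."""
    out = traj.copy()
    out.positions = traj.box.wrap(out.positions)
    out.wrapped = True
    return out


def unwrap_trajectory(traj: Trajectory, max_step: float | None = None) -> Trajectory:
    """Remove periodic jumps so particle paths are continuous.

    ``max_step`` guards against undersampled trajectories: any
    minimum-imaged per-frame step >= max_step raises
    :class:`UnwrapAmbiguityError` (default L/4; a true displacement of
    L/2 or more is fundamentally unrecoverable, and steps approaching it
    indicate the frame rate is too low).
    """
    if not traj.wrapped:
        raise ValueError("trajectory is already unwrapped")
    L = traj.box.edge_length
    if max_step is None:
        max_step = L / 4.0
    pos = traj.positions
    steps = minimum_image(np.diff(pos, axis=0), L)
    if steps.size and np.abs(steps).max() >= max_step:
        f, p, _ = np.unravel_index(np.abs(steps).argmax(), steps.shape)
        raise UnwrapAmbiguityError(
            f"particle {p} moves {np.abs(steps).max():.3g} A between frames "
            f"{f} and {f + 1} (>= max_step {max_step:.3g} A); frame rate too low"
        )
    out = traj.copy()
    out.positions = np.concatenate(
        [pos[:1], pos[:1] + np.cumsum(steps, axis=0)], axis=0
    ) if traj.n_frames > 1 else pos.copy()
    out.wrapped = False
    return out


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _write_extxyz(traj: Trajectory, path: Path) -> None:
    L = traj.box.edge_length
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(
                f'Lattice="{L:.10g} 0 0 0 {L:.10g} 0 0 0 {L:.10g}" '
                f'Properties=species:S:1:pos:R:3 Time={traj.times[f]:.10g} '
                f'pbc="T T T" wrapped={"T" if traj.wrapped else "F"}\n'
            )
            for lab, (x, y, z) in zip(traj.labels, traj.positions[f]):
                fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-\d.eE+]+)")
_WRAPPED_RE = re.compile(r"wrapped=([TF])")


def _read_extxyz(path: Path) -> Trajectory:
    frames: list[np.ndarray] = []
    times: list[float] = []
    labels: list[str] | None = None
    L = None
    wrapped = False
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_total = len(lines)
    while i < n_total:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: expected atom count at line {i + 1}, got {lines[i]!r}"
            ) from exc
        if i + 1 + natoms >= n_total + 1:
            raise TrajectoryFormatError(f"{path}: truncated frame at line {i + 1}")
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if m:
            vals = [float(v) for v in m.group(1).split()]
            L_frame = vals[0]
            if L is None:
                L = L_frame
            elif not np.isclose(L, L_frame):
                raise TrajectoryFormatError(f"{path}: box changes between frames")
        mt = _TIME_RE.search(comment)
        times.append(float(mt.group(1)) if mt else float(len(times)))
        mw = _WRAPPED_RE.search(comment)
        if mw:
            wrapped = mw.group(1) == "T"
        frame_labels: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(f"{path}: bad atom line {i + 3 + a}")
            frame_labels.append(parts[0])
            coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise TrajectoryFormatError(f"{path}: particle ordering changes between frames")
        frames.append(coords)
        i += 2 + natoms
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    if L is None:
        raise TrajectoryFormatError(f"{path}: no Lattice entry found")
    return Trajectory(
        times=np.array(times),
        positions=np.stack(frames),
        labels=np.array(labels, dtype=object),
        box=SimulationBox(L),
        wrapped=wrapped,
    )


# ---------------------------------------------------------------------------
# DCD (via MDAnalysis) with JSON sidecar for labels/times
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_dcd(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_particles, trajectory=True)
    L = traj.box.edge_length
    with mda.Writer(str(path), n_atoms=traj.n_particles) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[f].astype(np.float32)
            u.dimensions = [L, L, L, 90.0, 90.0, 90.0]
            w.write(u.atoms)
    meta = {
        "labels": [str(l) for l in traj.labels],
        "times": traj.times.tolist(),
        "edge_length": L,
        "wrapped": traj.wrapped,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def _read_dcd(path: Path) -> Trajectory:
    import MDAnalysis as mda

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TrajectoryFormatError(
            f"{path}: missing sidecar {sidecar.name} with species labels and times"
        )
    meta = json.loads(sidecar.read_text())
    n = len(meta["labels"])
    u = mda.Universe.empty(n, trajectory=True)
    try:
        u.load_new(str(path), format="DCD")
    except Exception as exc:
        raise TrajectoryFormatError(f"{path}: not readable as DCD: {exc}") from exc
    frames = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    return Trajectory(
        times=np.array(meta["times"], dtype=float),
        positions=frames,
        labels=np.array(meta["labels"], dtype=object),
        box=SimulationBox(float(meta["edge_length"])),
        wrapped=bool(meta["wrapped"]),
    )


# ---------------------------------------------------------------------------
# public trajectory I/O
# ---------------------------------------------------------------------------

_FORMATS = ("extxyz", "dcd")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise TrajectoryFormatError(f"unknown format tag '{fmt}'; allowed: {_FORMATS}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xyz", ".extxyz"):
        return "extxyz"
    if suffix == ".dcd":
        return "dcd"
    raise TrajectoryFormatError(f"cannot infer format from suffix '{suffix}'")


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "extxyz":
        _write_extxyz(traj, path)
    else:
        _write_dcd(traj, path)


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "extxyz":
        # guard against binary files handed to the text reader
        with open(path, "rb") as fh:
            head = fh.read(512)
        if b"\x00" in head:
            raise TrajectoryFormatError(f"{path}: binary content; not extended XYZ")
        return _read_extxyz(path)
    return _read_dcd(path)


def trajectory_roundtrip(traj: Trajectory, path: str | Path, format: str = "extxyz") -> Trajectory:
    """Write then read back a trajectory (testing/plumbing helper)."""
    write_trajectory(traj, path, format=format)
    return read_trajectory(path, format=format)
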