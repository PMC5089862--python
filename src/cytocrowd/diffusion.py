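"""Translational diffusion: windowed MSD, D_tr fits, size scaling, surface diffusion.

Mean-square displacements are computed with sliding time windows: window
origins advance by a configurable interval dt_origin (10 ps for
macromolecules, 1 ns for metabolites, 500 ps when correlating with
coordination numbers) and each window contributes a squared-displacement
profile up to tau_max (10 ns default); profiles are averaged over origins
and copies.  The translational diffusion coefficient follows from the
Einstein relation D_tr = slope/6 of a straight-line fit, by default over
the last 80% of the MSD curve (small-tau transients degrade the fit); the
full-range variant is used when resolving D against local crowding.
Surface-bound metabolites move in two dimensions, so their slope is
divided by 4 instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import SpeciesTable, Trajectory, minimum_image
from .units import stokes_einstein_d

__all__ = [
    "MSDCurve",
    "DiffusionResult",
    "compute_msd",
    "msd_brute_force",
    "fit_dtr",
    "fit_size_scaling",
    "FitResult",
    "classify_surface_diffusion",
    "SurfaceDiffusionResult",
]


@dataclass
class MSDCurve:
    """Time- (and copy-) averaged mean-square displacement."""

    tau: np.ndarray            # ps, tau[0] = 0
    msd: np.ndarray            # A^2, msd[0] = 0
    n_windows: int
    tau_max: float
    dt_origin: float
    t_end: float
    per_particle: np.ndarray | None = None   # (N, len(tau)) optional

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float)
        self.msd = np.asarray(self.msd, float)
        if self.tau[0] != 0 or self.msd[0] != 0:
            raise ValueError("curve must start at (0, 0)")
        if not np.all(np.diff(self.tau) > 0):
            raise ValueError("tau grid must be strictly increasing")


@dataclass
class DiffusionResult:
    """Fitted translational diffusion constant."""

    d_tr: float                # A^2/ps
    fit_fraction: float
    r_squared: float
    intercept: float
    d0: float | None = None    # dilute-limit reference
    d0_source: str | None = None
    negative_slope: bool = False
    per_copy: np.ndarray | None = None

    @property
    def ratio(self) -> float | None:
        if self.d0 is None or self.d0 == 0:
            return None
        return self.d_tr / self.d0


def compute_msd(traj: Trajectory, selection: np.ndarray | None = None,
                tau_max: float = 10_000.0, dt_origin: float | None = None,
                com_groups: list[np.ndarray] | None = None,
                keep_per_particle: bool = False) -> MSDCurve:
    """Windowed MSD of selected particles (or centres of mass of groups).

    The trajectory must be unwrapped.  Window origins run from t=0 to
    t_end - tau_max in steps of dt_origin (default: one frame interval);
    lags cover one frame interval up to tau_max.
    """
    if traj.wrapped:
        raise ValueError("MSD requires an unwrapped trajectory (see unwrap_trajectory)")
    dt_frame = traj.frame_interval()
    t_end = float(traj.times[-1] - traj.times[0])
    if tau_max >= t_end:
        raise ValueError(f"tau_max ({tau_max} ps) must be < trajectory span ({t_end} ps)")
    if com_groups is not None:
        pos = np.stack([traj.positions[:, g, :].mean(axis=1) for g in com_groups],
                       axis=1)
    elif selection is not None:
        pos = traj.positions[:, np.asarray(selection, int), :]
    else:
        pos = traj.positions

    n_lag = int(round(tau_max / dt_frame))
    n_lag = min(n_lag, traj.n_frames - 1)
    stride = max(1, int(round((dt_origin or dt_frame) / dt_frame)))
    origins = np.arange(0, traj.n_frames - n_lag, stride)
    if origins.size == 0:
        raise ValueError("no valid window origins; trajectory too short")

    n_particles = pos.shape[1]
    per = np.zeros((n_particles, n_lag + 1))
    for lag in range(1, n_lag + 1):
        disp = pos[origins + lag] - pos[origins]
        per[:, lag] = (disp ** 2).sum(axis=2).mean(axis=0)
    tau = np.arange(n_lag + 1) * dt_frame
    return MSDCurve(tau=tau, msd=per.mean(axis=0), n_windows=int(origins.size),
                    tau_max=tau_max, dt_origin=stride * dt_frame, t_end=t_end,
                    per_particle=per if keep_per_particle else None)


def msd_brute_force(positions: np.ndarray, times: np.ndarray, tau_max: float,
                    dt_origin: float) -> tuple[np.ndarray, np.ndarray]:
    """Reference all-origins double loop (oracle for compute_msd)."""
    dt_frame = float(times[1] - times[0])
    n_lag = min(int(round(tau_max / dt_frame)), len(times) - 1)
    stride = max(1, int(round(dt_origin / dt_frame)))
    msd = np.zeros(n_lag + 1)
    for lag in range(1, n_lag + 1):
        acc = 0.0
        cnt = 0
        for origin in range(0, len(times) - n_lag, stride):
            d = positions[origin + lag] - positions[origin]
            acc += float((d ** 2).sum(axis=-1).mean())
            cnt += 1
        msd[lag] = acc / cnt
    return np.arange(n_lag + 1) * dt_frame, msd


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_dtr(curve: MSDCurve, fit_fraction: float = 0.8,
            d0: float | None = None, d0_source: str | None = None,
            dimensions: int = 3) -> DiffusionResult:
    """D_tr from the Einstein relation, slope/(2*dimensions).

    By default only the last ``fit_fraction`` of the curve enters the
    straight-line fit; pass ``fit_fraction=1.0`` for the full-range variant.
    A negative fitted slope is reported as-is with a warning flag.
    """
    if not 0 < fit_fraction <= 1:
        raise ValueError("fit_fraction must be in (0, 1]")
    tau_lo = (1.0 - fit_fraction) * curve.tau[-1]
    mask = curve.tau >= tau_lo
    if mask.sum() < 10:
        raise ValueError(f"need >= 10 points in the fit range, have {int(mask.sum())}")
    denom = 2.0 * dimensions
    slope, intercept, r2 = _line_fit(curve.tau[mask], curve.msd[mask])
    per_copy = None
    if curve.per_particle is not None:
        per_copy = np.array([
            _line_fit(curve.tau[mask], row[mask])[0] / denom
            for row in curve.per_particle
        ])
    return DiffusionResult(d_tr=slope / denom, fit_fraction=fit_fraction,
                           r_squared=r2, intercept=intercept, d0=d0,
                           d0_source=d0_source, negative_slope=slope < 0,
                           per_copy=per_copy)


def species_diffusion(traj: Trajectory, table: SpeciesTable,
                      tau_max: float = 10_000.0, dt_origin: float | None = None,
                      fit_fraction: float = 0.8,
                      d0_table: dict[str, float] | None = None) -> dict[str, DiffusionResult]:
    """Per-species D_tr for a coarse-grained sphere trajectory.

    D0 comes from ``d0_table`` (externally computed dilute values) when
    given, else from Stokes-Einstein on the species radius (flagged in the
    result's ``d0_source``).
    """
    out: dict[str, DiffusionResult] = {}
    for name in table.names:
        idx = traj.indices_of(name)
        if idx.size == 0:
            continue
        curve = compute_msd(traj, selection=idx, tau_max=tau_max,
                            dt_origin=dt_origin, keep_per_particle=True)
        if d0_table and name in d0_table:
            d0, src = float(d0_table[name]), "table"
        else:
            d0, src = stokes_einstein_d(table.radius_of(name)), "stokes_einstein"
        out[name] = fit_dtr(curve, fit_fraction=fit_fraction, d0=d0, d0_source=src)
    return out


# ---------------------------------------------------------------------------
# size-scaling fits
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: str
    coefficients: dict[str, float]
    residual_ss: float
    r_squared: float
    n: int


_MODELS = ("A_over_Rs2", "B_over_Rs", "powerlaw_Rs_of_Mw", "linear_norm")


def fit_size_scaling(x: np.ndarray, y: np.ndarray, model: str) -> FitResult:
    """Least-squares fits of the size-scaling forms.

    * ``A_over_Rs2``:  y = A / x^2   (x = Rs; one-parameter, through origin)
    * ``B_over_Rs``:   y = B / x     (x = Rs)
    * ``powerlaw_Rs_of_Mw``: y = c * x^beta  (x = Mw, y = Rs; log-log fit,
      free exponent -- the printed relation is implemented generically)
    * ``linear_norm``: y = m x + n  (normalized D vs normalized Nc)
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if model not in _MODELS:
        raise ValueError(f"unknown model '{model}'; allowed {_MODELS}")
    if model in ("A_over_Rs2", "B_over_Rs"):
        if np.any(x <= 0):
            raise ValueError("Rs values must be positive")
        if x.size < 2:
            raise ValueError("need >= 2 species")
        basis = 1.0 / x ** 2 if model == "A_over_Rs2" else 1.0 / x
        coef = float((basis * y).sum() / (basis * basis).sum())
        pred = coef * basis
        name = "A" if model == "A_over_Rs2" else "B"
        coeffs = {name: coef}
    elif model == "powerlaw_Rs_of_Mw":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power-law fit needs positive data")
        beta, logc = np.polyfit(np.log(x), np.log(y), 1)
        coeffs = {"prefactor": float(np.exp(logc)), "exponent": float(beta)}
        pred = coeffs["prefactor"] * x ** coeffs["exponent"]
    else:
        m, n_ = np.polyfit(x, y, 1)
        coeffs = {"m": float(m), "n": float(n_)}
        pred = m * x + n_
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(model=model, coefficients=coeffs, residual_ss=ss_res,
                     r_squared=r2, n=int(x.size))


# ---------------------------------------------------------------------------
# two-dimensional surface diffusion of metabolites
# ---------------------------------------------------------------------------

@dataclass
class ResidencySegment:
    metabolite: int
    partner: int          # macromolecule index
    start_frame: int
    end_frame: int        # inclusive
    duration: float       # ps


@dataclass
class SurfaceDiffusionResult:
    segments: list[ResidencySegment]
    d_surface: float | None     # slope/4
    d_bulk: float | None        # slope/6
    surface_fraction: float
    msd_surface: MSDCurve | None = None
    msd_bulk: MSDCurve | None = None


def _nearest_partner(met_pos: np.ndarray, macro_pos: np.ndarray,
                     macro_radii: np.ndarray, L: float) -> tuple[np.ndarray, np.ndarray]:
    """Per metabolite: nearest macromolecule index and surface distance."""
    d = minimum_image(met_pos[:, None, :] - macro_pos[None, :, :], L)
    dist = np.sqrt((d * d).sum(axis=2)) - macro_radii[None, :]
    part = dist.argmin(axis=1)
    return part, dist[np.arange(dist.shape[0]), part]


def classify_surface_diffusion(metabolite_traj: Trajectory,
                               macromolecule_traj: Trajectory,
                               cutoffs: float | dict[str, float] = 8.0,
                               min_residence: float = 5000.0,
                               macro_radii: np.ndarray | None = None,
                               tau_max: float | None = None) -> SurfaceDiffusionResult:
    """Separate surface-bound (2D) from bulk (3D) metabolite diffusion.

    A metabolite frame is *interacting* when its centre is within the
    per-species cutoff of the nearest macromolecule surface (bead centre
    minus bead radius; pass ``macro_radii`` of zeros for point/atom
    references).  Contiguous same-partner runs longer than
    ``min_residence`` are surface segments; MSD windows are evaluated
    inside segments only, with the Einstein slope divided by 4 (surface)
    or 6 (bulk).
    """
    if (metabolite_traj.times.shape != macromolecule_traj.times.shape
            or not np.allclose(metabolite_traj.times, macromolecule_traj.times)):
        raise ValueError("metabolite and macromolecule trajectories must share times")
    if metabolite_traj.box.edge_length != macromolecule_traj.box.edge_length:
        raise ValueError("trajectories must share the simulation box")
    L = metabolite_traj.box.edge_length
    n_frames = metabolite_traj.n_frames
    n_met = metabolite_traj.n_particles
    n_mac = macromolecule_traj.n_particles
    if macro_radii is None:
        macro_radii = np.zeros(n_mac)
    macro_radii = np.asarray(macro_radii, float)
    if isinstance(cutoffs, dict):
        cut = np.array([cutoffs[l] for l in metabolite_traj.labels], float)
    else:
        cut = np.full(n_met, float(cutoffs))

    partner = np.empty((n_frames, n_met), dtype=int)
    bound = np.empty((n_frames, n_met), dtype=bool)
    for f in range(n_frames):
        p, dist = _nearest_partner(metabolite_traj.positions[f],
                                   macromolecule_traj.positions[f],
                                   macro_radii, L)
        partner[f] = p
        bound[f] = dist < cut

    dt_frame = metabolite_traj.frame_interval()
    segments: list[ResidencySegment] = []
    surface_mask = np.zeros((n_frames, n_met), dtype=bool)
    for m in range(n_met):
        f = 0
        while f < n_frames:
            if not bound[f, m]:
                f += 1
                continue
            p = partner[f, m]
            g = f
            while g + 1 < n_frames and bound[g + 1, m] and partner[g + 1, m] == p:
                g += 1
            duration = (g - f) * dt_frame
            if duration > min_residence:
                segments.append(ResidencySegment(m, int(p), f, g, duration))
                surface_mask[f:g + 1, m] = True
            f = g + 1

    met_unwrapped = metabolite_traj
    if metabolite_traj.wrapped:
        from .io_core import unwrap_trajectory
        met_unwrapped = unwrap_trajectory(metabolite_traj)

    if tau_max is None:
        tau_max = min(1000.0, (n_frames - 2) * dt_frame)

    msd_surf = _population_msd(met_unwrapped.positions, surface_mask, dt_frame, tau_max)
    msd_bulk = _population_msd(met_unwrapped.positions, ~bound, dt_frame, tau_max)

    def _fit(curve: MSDCurve | None, dim: int) -> float | None:
        if curve is None:
            return None
        try:
            return fit_dtr(curve, fit_fraction=0.8, dimensions=dim).d_tr
        except ValueError:
            return None

    return SurfaceDiffusionResult(
        segments=segments,
        d_surface=_fit(msd_surf, 2),
        d_bulk=_fit(msd_bulk, 3),
        surface_fraction=float(surface_mask.mean()),
        msd_surface=msd_surf,
        msd_bulk=msd_bulk,
    )


def _population_msd(positions: np.ndarray, mask: np.ndarray, dt_frame: float,
                    tau_max: float) -> MSDCurve | None:
    """MSD restricted to (origin, origin+lag) windows fully inside ``mask``."""
    n_frames, n_met = mask.shape
    n_lag = min(int(round(tau_max / dt_frame)), n_frames - 1)
    if n_lag < 1:
        return None
    msd = np.zeros(n_lag + 1)
    counts = np.zeros(n_lag + 1, dtype=int)
    # run-length encode contiguous True stretches per metabolite
    for m in range(n_met):
        col = mask[:, m]
        f = 0
        while f < n_frames:
            if not col[f]:
                f += 1
                continue
            g = f
            while g + 1 < n_frames and col[g + 1]:
                g += 1
            seg = positions[f:g + 1, m]
            seg_len = g - f + 1
            for lag in range(1, min(n_lag, seg_len - 1) + 1):
                d = seg[lag:] - seg[:-lag]
                msd[lag] += float((d ** 2).sum())
                counts[lag] += d.shape[0]
            f = g + 1
    if counts[1:].sum() == 0 or counts[min(10, n_lag)] == 0:
        return None
    valid = counts > 0
    valid[0] = True
    top = int(np.flatnonzero(valid).max())
    msd_out = np.zeros(top + 1)
    msd_out[1:] = msd[1:top + 1] / np.maximum(counts[1:top + 1], 1)
    if top < 2:
        return None
    return MSDCurve(tau=np.arange(top + 1) * dt_frame, msd=msd_out,
                    n_windows=int(counts[1]), tau_max=top * dt_frame,
                    dt_origin=dt_frame, t_end=n_frames * dt_frame)
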