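"""Rotational motion of rigid bodies and atom groups.

The overall tumbling of a body is tracked through the proper rotation
matrix that best superposes it onto a reference structure (least-RMSD,
Kabsch construction with reflection guard).  The rotational correlation

    theta(tau) = < (1/3) Tr[ R(t)^T R(t+tau) ] >

is the first-rank orientation autocorrelation averaged over the three
body-frame unit vectors (the columns of R); for isotropic rotational
diffusion it decays as exp(-2 Drot tau).  A single-exponential fit over
the decade theta in [0.1, 1] yields the relaxation time tau_rel and
Drot = 1/(2 tau_rel).  The mean angular velocity is reported from the
window-averaged inner products of rotated unit vectors as
omega = (180/pi) arccos(<Delta e(tau_max)>), in degrees per tau_max
window by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_core import Trajectory

__all__ = [
    "kabsch_rotation",
    "rotational_correlation",
    "fit_rotational_relaxation",
    "mean_angular_velocity",
    "RotationalResult",
    "orientations_from_positions",
]


def kabsch_rotation(moving: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising RMSD of R @ (moving-centred).

    Both inputs are (n, 3) with n >= 3 non-collinear points; centroids are
    removed before the fit.
    """
    p = np.asarray(moving, float)
    q = np.asarray(reference, float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) coordinate sets")
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) atom group; superposition undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def orientations_from_positions(positions: np.ndarray,
                                reference: np.ndarray) -> np.ndarray:
    """Best-fit rotation per frame for one atom group, (F, 3, 3).

    R(t) maps the centred reference onto the centred frame coordinates.
    """
    return np.stack([kabsch_rotation(reference, frame) for frame in positions])


@dataclass
class RotationalResult:
    tau: np.ndarray
    theta: np.ndarray            # dimensionless, theta[0] = 1
    tau_rel: float | None = None # ps (None until fitted)
    d_rot: float | None = None   # 1/ps
    omega_mean: float | None = None  # degrees per tau_max window
    fitted: bool = False


def _orientation_tracks(traj: Trajectory,
                        groups: list[np.ndarray] | None,
                        reference: np.ndarray | None) -> np.ndarray:
    """(F, B, 3, 3) orientation operators from a trajectory."""
    if traj.orientations is not None and groups is None:
        return traj.orientations
    if groups is None:
        raise ValueError("trajectory carries no orientations; pass atom groups")
    tracks = []
    for g in groups:
        g = np.asarray(g, int)
        ref = reference if reference is not None else traj.positions[0, g]
        tracks.append(orientations_from_positions(traj.positions[:, g, :], ref))
    return np.stack(tracks, axis=1)


def rotational_correlation(traj: Trajectory, tau_max: float = 10_000.0,
                           dt_origin: float | None = None,
                           groups: list[np.ndarray] | None = None,
                           reference: np.ndarray | None = None) -> RotationalResult:
    """Window- and copy-averaged rotational correlation theta(tau)."""
    mats = _orientation_tracks(traj, groups, reference)
    dt_frame = traj.frame_interval()
    n_frames = mats.shape[0]
    n_lag = min(int(round(tau_max / dt_frame)), n_frames - 1)
    if n_lag < 1:
        raise ValueError("tau_max shorter than one frame interval")
    stride = max(1, int(round((dt_origin or dt_frame) / dt_frame)))
    origins = np.arange(0, n_frames - n_lag, stride)
    if origins.size == 0:
        raise ValueError("no valid window origins")
    theta = np.empty(n_lag + 1)
    theta[0] = 1.0
    for lag in range(1, n_lag + 1):
        # (1/3) Tr(R(t)^T R(t+lag)) per body per origin
        prod = np.einsum("obij,obij->ob", mats[origins], mats[origins + lag])
        theta[lag] = float(prod.mean()) / 3.0
    return RotationalResult(tau=np.arange(n_lag + 1) * dt_frame, theta=theta)


def fit_rotational_relaxation(result: RotationalResult) -> RotationalResult:
    """Single-exponential fit theta = exp(-tau/tau_rel); Drot = 1/(2 tau_rel).

    Only points with theta in [0.1, 1] are fitted.  A curve that never
    decays below 0.9 in range is flagged no-fit with tau_rel infinite.
    """
    tau, theta = result.tau, result.theta
    if theta.min() > 0.9:
        result.tau_rel = np.inf
        result.d_rot = 0.0
        result.fitted = False
        return result
    mask = (theta >= 0.1) & (theta <= 1.0)
    mask[0] = True
    t_fit, y_fit = tau[mask], np.clip(theta[mask], 1e-12, None)
    # log-linear start, refined by nonlinear least squares
    slope = np.polyfit(t_fit[1:], np.log(y_fit[1:]), 1)[0]
    p0 = -1.0 / slope if slope < 0 else tau[-1]
    try:
        popt, _ = curve_fit(lambda t, tr: np.exp(-t / tr), t_fit, y_fit,
                            p0=[max(p0, tau[1])], maxfev=10000)
        tau_rel = float(popt[0])
    except RuntimeError:
        tau_rel = float(p0)
    result.tau_rel = tau_rel
    result.d_rot = 1.0 / (2.0 * tau_rel)
    result.fitted = True
    return result


def mean_angular_velocity(traj: Trajectory, tau_max: float = 10_000.0,
                          dt_origin: float | None = None,
                          groups: list[np.ndarray] | None = None,
                          reference: np.ndarray | None = None,
                          units: str = "per_window") -> float:
    """Mean angular displacement over tau_max windows, in degrees.

    <Delta e(tau_max)> averages e_j(t) . e_j(t+tau_max) over the three
    body axes, window origins and bodies; the result is
    (180/pi) arccos(<Delta e>), per tau_max window (``units='per_window'``)
    or divided by tau_max in ns (``units='per_ns'``).
    """
    mats = _orientation_tracks(traj, groups, reference)
    dt_frame = traj.frame_interval()
    n_frames = mats.shape[0]
    n_lag = min(int(round(tau_max / dt_frame)), n_frames - 1)
    if n_lag < 1:
        raise ValueError("tau_max shorter than one frame interval")
    stride = max(1, int(round((dt_origin or dt_frame) / dt_frame)))
    origins = np.arange(0, n_frames - n_lag, stride)
    if origins.size == 0:
        raise ValueError("no valid window origins")
    prod = np.einsum("obij,obij->ob", mats[origins], mats[origins + n_lag]) / 3.0
    mean_de = float(prod.mean())
    if not -1.0 <= mean_de <= 1.0:
        warnings.warn(f"<Delta e> = {mean_de} outside [-1, 1]; clamped", RuntimeWarning)
        mean_de = float(np.clip(mean_de, -1.0, 1.0))
    angle_deg = np.degrees(np.arccos(mean_de))
    if units == "per_window":
        return float(angle_deg)
    if units == "per_ns":
        return float(angle_deg / ((n_lag * dt_frame) / 1000.0))
    raise ValueError("units must be 'per_window' or 'per_ns'")
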