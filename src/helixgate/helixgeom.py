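"""Local helical twist, deviation maps and backbone RMSF.

The local twist θ of a sliding 4-Cα window (p1..p4) is the angle between the
two internal angle-bisector vectors b2 = (p1-p2)+(p3-p2) and
b3 = (p2-p3)+(p4-p3).  On an exact circular helix the bisectors are radial,
so θ equals the per-residue helical rotation — 100°/residue for an ideal
α-helix.  The signed deviation Δθ = θ - reference (wrapped to (-180, 180])
localises departures from helicity along a helix and over time, and its
per-residue time integral ∫|Δθ|dt (°·μs) summarises the magnitude of
unwinding over a simulation.

By default the window (i, i+1, i+2, i+3) is assigned to residue i+1, the
residue whose bisector opens the angle; assignment to i+2 is available via
``assign_to``.  Whether Δθ is wrapped matters only for distortions beyond
±180°, which do not occur for physical helices; wrapping is applied for
robustness and windows are never masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .errors import GeometryError, SpecValidationError, TrajectoryError

__all__ = [
    "TwistMap",
    "IntegratedDeviation",
    "RMSFProfile",
    "local_twist",
    "twist_map",
    "integrate_deviation",
    "rmsf",
    "wrap_angle",
]

#: Bisector norms below this (Å) are treated as degenerate geometry.
DEGENERACY_TOL = 1e-6

#: Ideal α-helix local twist (degrees per residue), the deviation reference.
IDEAL_ALPHA_TWIST = 100.0


def wrap_angle(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) to the interval (-180, 180]."""
    wrapped = -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)
    return wrapped


@dataclass
class TwistMap:
    """Residues × frames local twist and deviation (degrees)."""

    residue_ids: np.ndarray
    frame_times: np.ndarray
    theta: np.ndarray
    delta_theta: np.ndarray
    reference_twist: float = IDEAL_ALPHA_TWIST


@dataclass
class IntegratedDeviation:
    """Per-residue ∫|Δθ|dt in degree·microseconds."""

    residue_ids: np.ndarray
    value: np.ndarray
    total_time: float  # μs

    def argmax_residue(self) -> int:
        return int(self.residue_ids[int(np.argmax(self.value))])


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Å) about the mean structure."""

    residue_ids: np.ndarray
    rmsf: np.ndarray
    superposition_selection: str


def _bisectors(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit bisector vectors for stacked windows p of shape (..., 4, 3)."""
    b2 = (p[..., 0, :] - p[..., 1, :]) + (p[..., 2, :] - p[..., 1, :])
    b3 = (p[..., 1, :] - p[..., 2, :]) + (p[..., 3, :] - p[..., 2, :])
    n2 = np.linalg.norm(b2, axis=-1)
    n3 = np.linalg.norm(b3, axis=-1)
    if np.any(n2 < DEGENERACY_TOL) or np.any(n3 < DEGENERACY_TOL):
        raise GeometryError(
            "degenerate 4-Cα window: an angle-bisector vector has near-zero norm "
            "(collinear or coincident points)"
        )
    return b2 / n2[..., None], b3 / n3[..., None]


def local_twist(p1, p2, p3, p4) -> float:
    """Local twist (degrees, in [0, 180]) of one 4-Cα window."""
    window = np.stack([np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4)])
    u2, u3 = _bisectors(window[None, :, :])
    cosang = np.clip(np.einsum("...i,...i", u2, u3), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang))[0])


def twist_map(
    traj: Trajectory,
    helix_selection: str = "name CA",
    reference: float = IDEAL_ALPHA_TWIST,
    assign_to: int = 1,
) -> TwistMap:
    """Local twist per residue per frame over a sliding 4-Cα window.

    ``helix_selection`` must resolve to >= 4 Cα atoms, one per consecutive
    residue, present in every frame.  ``assign_to`` maps window (i..i+3) to
    residue i+1 (default) or i+2.
    """
    if assign_to not in (1, 2):
        raise SpecValidationError(f"assign_to must be 1 or 2, got {assign_to}")
    idx = traj.select(helix_selection)
    names = traj.topology.atom_name[idx]
    if not all(str(n).upper() == "CA" for n in names):
        raise TrajectoryError(
            f"selection {helix_selection!r} includes non-Cα atoms; "
            "twist analysis runs on Cα atoms only"
        )
    resids = traj.topology.resid[idx]
    order = np.argsort(resids, kind="stable")
    idx, resids = idx[order], resids[order]
    if len(idx) < 4:
        raise TrajectoryError(
            f"selection {helix_selection!r} has {len(idx)} Cα atoms; need >= 4"
        )
    if len(np.unique(resids)) != len(resids):
        missing = [int(r) for r in resids[np.r_[False, np.diff(resids) == 0]]]
        raise TrajectoryError(f"duplicate Cα atoms for residues {missing}")
    if not np.all(np.isfinite(traj.coords[:, idx, :])):
        bad_f, bad_a, _ = np.where(~np.isfinite(traj.coords[:, idx, :]))
        raise TrajectoryError(
            f"non-finite Cα coordinates, first at frame {int(bad_f[0])}, "
            f"residue {int(resids[bad_a[0]])}"
        )

    ca = traj.coords[:, idx, :]  # (F, R, 3)
    n_res = ca.shape[1]
    windows = np.stack([ca[:, i : n_res - 3 + i, :] for i in range(4)], axis=2)
    # windows: (F, n_windows, 4, 3)
    u2, u3 = _bisectors(windows)
    cosang = np.clip(np.einsum("fwi,fwi->fw", u2, u3), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang)).T  # (n_windows, F)
    assigned = resids[assign_to : assign_to + theta.shape[0]]
    delta = wrap_angle(theta - reference)
    return TwistMap(
        residue_ids=assigned.astype(np.int64),
        frame_times=traj.frame_times.copy(),
        theta=theta,
        delta_theta=delta,
        reference_twist=float(reference),
    )


def integrate_deviation(
    tmap: TwistMap, spacing_rtol: float = 1e-6
) -> IntegratedDeviation:
    """Per-residue ∫|Δθ|dt in °·μs by the rectangle rule (|Δθ| × Δt).

    Frame times must be uniformly spaced within ``spacing_rtol`` (relative to
    the mean spacing); the MD analyses this mirrors use fixed 50 ps snapshots.
    """
    times = np.asarray(tmap.frame_times, dtype=np.float64)
    if len(times) < 2:
        raise SpecValidationError("integration requires at least 2 frames")
    dts = np.diff(times)
    dt = float(np.mean(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > spacing_rtol * abs(dt)):
        raise SpecValidationError(
            f"frame times are not uniformly spaced (spacings {dts.min():g}..{dts.max():g} ps)"
        )
    dt_us = dt * 1e-6  # ps → μs
    value = np.sum(np.abs(tmap.delta_theta), axis=1) * dt_us
    return IntegratedDeviation(
        residue_ids=tmap.residue_ids.copy(),
        value=value,
        total_time=len(times) * dt_us,
    )


def rmsf(
    traj: Trajectory,
    analysis_selection: str = "name CA",
    superposition_selection: str | None = None,
) -> RMSFProfile:
    """Per-residue RMSF (Å) after least-squares superposition.

    Frames are superposed on ``superposition_selection`` (default: the
    analysis selection) onto the iteratively refined mean structure, then the
    per-atom RMS deviation from the mean is averaged per residue.
    """
    from .ensembles import superpose_trajectory

    if traj.n_frames < 2:
        raise SpecValidationError("RMSF requires at least 2 frames")
    sup_sel = superposition_selection or analysis_selection
    fitted = superpose_trajectory(traj, sup_sel)
    idx = traj.select(analysis_selection)
    x = fitted[:, idx, :]
    mean = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))

    resids = traj.topology.resid[idx]
    chains = traj.topology.chain[idx]
    keys: list[tuple[str, int]] = []
    seen: dict[tuple[str, int], list[int]] = {}
    for i, key in enumerate(zip(chains, resids)):
        key = (key[0], int(key[1]))
        if key not in seen:
            seen[key] = []
            keys.append(key)
        seen[key].append(i)
    values = np.array([per_atom[seen[k]].mean() for k in keys])
    return RMSFProfile(
        residue_ids=np.array([k[1] for k in keys], dtype=np.int64),
        rmsf=values,
        superposition_selection=sup_sel,
    )
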