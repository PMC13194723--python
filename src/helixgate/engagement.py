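"""Per-frame ligand-helix engagement metrics and binding-fate calls.

Engagement of a ligand with a helix motif is tracked as (i) the number of
hydrogen bonds per frame between ligand donors and motif acceptors, (ii) the
minimum heavy-atom distance between ligand and motif, and (iii) an overall
H-bond occupancy (percent of frames with at least one bond).  Each replica is
then assigned one of three binding fates from its end-state behaviour:
'bound' (still engaged), 'disengaged_in_site' (lost the motif but stayed in
the binding site) or 'diffused_out' (left the site) — the taxonomy used to
describe replicate unbiased MD of ligand-bound transporters.

Hydrogen bonds use a geometric criterion: donor-acceptor distance <= 3.5 Å
and, when donor hydrogens are available, D-H···A angle >= 130°.  Coarse
models without explicit hydrogens fall back to the distance-only criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory
from .errors import SelectionError, SpecValidationError, TrajectoryError

__all__ = [
    "HBondCriteria",
    "FateThresholds",
    "EngagementSeries",
    "detect_hbonds_frame",
    "engagement_series",
    "classify_binding_fate",
    "water_bridge_occupancy",
]

FATES = ("bound", "disengaged_in_site", "diffused_out")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion (donor-acceptor distance, DHA angle)."""

    max_donor_acceptor_distance: float = 3.5
    min_dha_angle: float = 130.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise SpecValidationError(
                f"max_donor_acceptor_distance must be > 0, got {self.max_donor_acceptor_distance}"
            )
        if not 0 <= self.min_dha_angle <= 180:
            raise SpecValidationError(
                f"min_dha_angle must lie in [0, 180], got {self.min_dha_angle}"
            )


@dataclass(frozen=True)
class FateThresholds:
    """Thresholds for end-state fate calls.

    The fate is judged over the trailing ``terminal_fraction`` of frames:
    'bound' if terminal H-bond occupancy >= ``bound_occupancy`` percent, else
    'diffused_out' if the ligand centre of mass sits more than
    ``escape_distance`` Å from the site centre (median over the terminal
    window), else 'disengaged_in_site'.
    """

    terminal_fraction: float = 0.2
    bound_occupancy: float = 50.0
    escape_distance: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.terminal_fraction <= 1:
            raise SpecValidationError(
                f"terminal_fraction must lie in (0, 1], got {self.terminal_fraction}"
            )
        if not 0 <= self.bound_occupancy <= 100:
            raise SpecValidationError(
                f"bound_occupancy must lie in [0, 100], got {self.bound_occupancy}"
            )
        if self.escape_distance <= 0:
            raise SpecValidationError(
                f"escape_distance must be > 0, got {self.escape_distance}"
            )


@dataclass
class EngagementSeries:
    """Per-frame engagement metrics; ``fate`` is set by classify_binding_fate."""

    frame_times: np.ndarray
    hbond_count: np.ndarray
    min_distance: np.ndarray
    occupancy_percent: float
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    fate: str | None = None


def detect_hbonds_frame(
    frame_coords: np.ndarray,
    donors: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria | None = None,
    donor_hydrogens: dict[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Hydrogen-bonded (donor, acceptor) atom-index pairs in one frame.

    ``donor_hydrogens`` maps donor atom index -> hydrogen atom index; donors
    without an entry are evaluated by the distance-only criterion.
    """
    criteria = criteria or HBondCriteria()
    donors = np.asarray(donors, dtype=np.int64)
    acceptors = np.asarray(acceptors, dtype=np.int64)
    if donors.size == 0:
        raise SelectionError("donor set is empty")
    if acceptors.size == 0:
        raise SelectionError("acceptor set is empty")
    x = np.asarray(frame_coords, dtype=np.float64)
    d = np.linalg.norm(x[donors][:, None, :] - x[acceptors][None, :, :], axis=2)
    pairs: list[tuple[int, int]] = []
    for i, dn in enumerate(donors):
        for j, ac in enumerate(acceptors):
            if d[i, j] > criteria.max_donor_acceptor_distance:
                continue
            if donor_hydrogens and int(dn) in donor_hydrogens:
                h = x[donor_hydrogens[int(dn)]]
                v1 = x[dn] - h
                v2 = x[ac] - h
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 == 0 or n2 == 0:
                    continue
                ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))
                if ang < criteria.min_dha_angle:
                    continue
            pairs.append((int(dn), int(ac)))
    return pairs


def _heavy(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    el = np.char.upper(traj.topology.element[idx].astype(str))
    return idx[el != "H"]


def engagement_series(
    traj: Trajectory,
    ligand_selection: str = "entity ligand",
    motif_selection: str = "name CA",
    criteria: HBondCriteria | None = None,
) -> EngagementSeries:
    """Per-frame H-bond count and minimum heavy-atom ligand-motif distance.

    Donors are the ligand's nitrogen/oxygen atoms (distance-only criterion
    when the topology carries no hydrogens); acceptors are the motif's
    heavy atoms.  Occupancy is the percentage of frames with >= 1 bond.
    """
    criteria = criteria or HBondCriteria()
    lig = traj.select(ligand_selection)
    motif = traj.select(motif_selection)
    lig = _heavy(traj, lig)
    motif = _heavy(traj, motif)
    if lig.size == 0:
        raise SelectionError(f"ligand selection {ligand_selection!r} has no heavy atoms")
    if motif.size == 0:
        raise SelectionError(f"motif selection {motif_selection!r} has no heavy atoms")
    el = np.char.upper(traj.topology.element[lig].astype(str))
    donors = lig[np.isin(el, ["N", "O"])]
    if donors.size == 0:
        donors = lig  # coarse models: every heavy ligand atom may donate

    diff = traj.coords[:, lig, None, :] - traj.coords[:, None, motif, :]
    dmat = np.linalg.norm(diff, axis=3)  # (F, n_lig, n_motif)
    min_distance = dmat.min(axis=(1, 2))
    donor_mask = np.isin(lig, donors)
    hbond_count = (dmat[:, donor_mask, :] <= criteria.max_donor_acceptor_distance).sum(
        axis=(1, 2)
    )
    occupancy = 100.0 * float(np.mean(hbond_count >= 1))
    return EngagementSeries(
        frame_times=traj.frame_times.copy(),
        hbond_count=hbond_count.astype(np.int64),
        min_distance=min_distance,
        occupancy_percent=occupancy,
        criteria=criteria,
    )


def classify_binding_fate(
    series: EngagementSeries,
    site_center: np.ndarray,
    ligand_com_series: np.ndarray,
    thresholds: FateThresholds | None = None,
) -> str:
    """End-state fate of a replica: bound / disengaged_in_site / diffused_out.

    Sets ``series.fate`` and returns the label.
    """
    thresholds = thresholds or FateThresholds()
    com = np.asarray(ligand_com_series, dtype=np.float64)
    n = len(series.hbond_count)
    if com.shape != (n, 3):
        raise TrajectoryError(
            f"ligand_com_series has shape {com.shape}, expected ({n}, 3)"
        )
    n_term = max(1, int(round(thresholds.terminal_fraction * n)))
    window = slice(n - n_term, n)
    occ_term = 100.0 * float(np.mean(series.hbond_count[window] >= 1))
    if occ_term >= thresholds.bound_occupancy:
        fate = "bound"
    else:
        dist = np.linalg.norm(com[window] - np.asarray(site_center), axis=1)
        fate = (
            "diffused_out"
            if float(np.median(dist)) > thresholds.escape_distance
            else "disengaged_in_site"
        )
    series.fate = fate
    return fate


def ligand_com_series(traj: Trajectory, ligand_selection: str = "entity ligand") -> np.ndarray:
    """Per-frame centre of geometry (heavy atoms) of the ligand, (F, 3) Å."""
    lig = _heavy(traj, traj.select(ligand_selection))
    if lig.size == 0:
        raise SelectionError(f"ligand selection {ligand_selection!r} has no heavy atoms")
    return traj.coords[:, lig, :].mean(axis=1)


def water_bridge_occupancy(
    trajs: Trajectory | list[Trajectory],
    ligand_atom: str,
    partner_atom: str,
    water_selection: str = "entity water",
    criteria: HBondCriteria | None = None,
) -> float:
    """Percent of pooled frames with a shared water within H-bond geometry of
    both the ligand atom and the partner atom.

    Multiple replicas are pooled by concatenation ('gross simulation time').
    """
    criteria = criteria or HBondCriteria()
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    total = 0
    bridged = 0
    for t in trajs:
        waters = _heavy(t, t.select(water_selection, required=False))
        if waters.size == 0:
            raise SelectionError(
                f"water selection {water_selection!r} has no atoms in topology"
            )
        la = t.select(ligand_atom)
        pa = t.select(partner_atom)
        d_lw = np.linalg.norm(
            t.coords[:, waters, :] - t.coords[:, la, :].mean(axis=1, keepdims=True),
            axis=2,
        )
        d_pw = np.linalg.norm(
            t.coords[:, waters, :] - t.coords[:, pa, :].mean(axis=1, keepdims=True),
            axis=2,
        )
        cut = criteria.max_donor_acceptor_distance
        bridged += int(np.sum(np.any((d_lw <= cut) & (d_pw <= cut), axis=1)))
        total += t.n_frames
    return 100.0 * bridged / total
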