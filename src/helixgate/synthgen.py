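"""Synthetic trajectory generators with known ground truth.

The generators emulate the statistical structure of unbiased MD of a gated
transporter at desk scale, without any physics: a transmembrane-like helix
whose local twist departs from ideal α-helical geometry over a seeded residue
span and time window (helix unwinding at a flexible di-glycine motif and its
reversal on ligand disengagement), a two-state flipping loop on a rigid core
(an extracellular-loop flip-out/flip-in equilibrium), and a small rigid
pseudo-ligand whose hydrogen bonding to a helix motif follows a prescribed
schedule, including escape from the binding site.

Each generator is deterministic given its spec and seed, returns the exact
generative schedule in ``Trajectory.ground_truth``, and with ``noise_sigma=0``
reproduces the analytic geometry to machine precision.  Defaults follow the
study conditions the analyses are designed for: helix radius 2.3 Å, rise
1.5 Å per residue, 100°/residue twist, 50 ps frame spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, Trajectory
from .errors import SpecValidationError

__all__ = [
    "HelixSpec",
    "UnwindEvent",
    "LoopFlipSpec",
    "EngagementSpec",
    "build_ideal_helix",
    "build_alpha_backbone",
    "generate_helix_trajectory",
    "generate_loop_flip_ensemble",
    "generate_engagement_trajectory",
    "random_engagement_schedule",
]

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class HelixSpec:
    """Geometry and sampling parameters of a synthetic Cα helix.

    ``base_twist`` is the per-residue rotation in degrees (100°/residue for an
    ideal α-helix); ``noise_sigma`` is isotropic Gaussian positional noise per
    atom per frame in Å, applied after exact placement.
    """

    n_residues: int = 30
    radius: float = 2.3
    rise_per_residue: float = 1.5
    base_twist: float = 100.0
    noise_sigma: float = 0.0
    n_frames: int = 1
    frame_spacing: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise SpecValidationError(f"n_residues must be >= 4, got {self.n_residues}")
        if self.radius <= 0:
            raise SpecValidationError(f"radius must be > 0, got {self.radius}")
        if self.rise_per_residue <= 0:
            raise SpecValidationError(
                f"rise_per_residue must be > 0, got {self.rise_per_residue}"
            )
        if not 0 < self.base_twist < 180:
            raise SpecValidationError(
                f"base_twist must lie in (0, 180) degrees, got {self.base_twist}"
            )
        if self.noise_sigma < 0:
            raise SpecValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.n_frames < 1:
            raise SpecValidationError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_spacing <= 0:
            raise SpecValidationError(f"frame_spacing must be > 0, got {self.frame_spacing}")


@dataclass(frozen=True)
class UnwindEvent:
    """A square-pulse change of local twist over a residue span and time window.

    ``residue_span`` is an inclusive pair of 0-based residue indices into the
    helix; the twist of every helical turn starting at a residue inside the
    span is set to ``event_twist`` while the event is active (frames
    ``start_frame..end_frame`` inclusive).  Transitions are instantaneous so
    the time-integrated deviation is analytically predictable.
    """

    residue_span: tuple[int, int]
    event_twist: float
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        lo, hi = self.residue_span
        if lo > hi or lo < 0:
            raise SpecValidationError(f"residue_span must be a valid interval, got {self.residue_span}")
        if not 0 < self.event_twist < 180:
            raise SpecValidationError(
                f"event_twist must lie in (0, 180) degrees, got {self.event_twist}"
            )
        if self.start_frame > self.end_frame or self.start_frame < 0:
            raise SpecValidationError(
                f"start_frame must be <= end_frame and >= 0, got {self.start_frame}..{self.end_frame}"
            )


@dataclass(frozen=True)
class LoopFlipSpec:
    """A rigid core plus a loop toggling between two positions.

    In state-1 frames the loop atoms are displaced ``flip_displacement`` Å
    along a fixed direction; state labels come from ``state_schedule`` (0/1
    per frame).  All atoms carry isotropic Gaussian noise ``noise_sigma``.
    """

    core_size: int = 50
    loop_size: int = 10
    flip_displacement: float = 8.0
    state_schedule: tuple[int, ...] = ()
    noise_sigma: float = 0.3
    frame_spacing: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size < 4:
            raise SpecValidationError(f"core_size must be >= 4, got {self.core_size}")
        if self.loop_size < 1:
            raise SpecValidationError(f"loop_size must be >= 1, got {self.loop_size}")
        if self.flip_displacement < 0:
            raise SpecValidationError(
                f"flip_displacement must be >= 0, got {self.flip_displacement}"
            )
        if self.noise_sigma < 0:
            raise SpecValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if len(self.state_schedule) < 1:
            raise SpecValidationError("state_schedule must contain at least one frame")
        if any(s not in (0, 1) for s in self.state_schedule):
            raise SpecValidationError("state_schedule entries must be 0 or 1")


#: Per-frame engagement labels understood by the engagement generator.
ENGAGEMENT_LABELS = ("engaged", "disengaged_in_site", "escaped")


@dataclass(frozen=True)
class EngagementSpec:
    """Schedule-driven placement of a pseudo-ligand relative to a helix motif.

    ``motif_residues`` are 0-based helix residue indices acting as hydrogen
    bond acceptors.  Per frame, the ligand donor sits within H-bond geometry
    of a motif acceptor ('engaged'), more than 5 Å from every motif atom but
    inside the site shell ('disengaged_in_site'), or beyond
    ``escape_distance`` from the site centre ('escaped').  An optional
    bridging-water particle sits between the ligand donor and a designated
    motif partner whenever ``water_schedule`` says so (default: whenever
    engaged).
    """

    motif_residues: tuple[int, ...]
    engagement_schedule: tuple[str, ...]
    site_center: tuple[float, float, float] | None = None
    escape_distance: float = 10.0
    hbond_distance: float = 2.9
    water_schedule: tuple[bool, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif_residues) == 0:
            raise SpecValidationError("motif_residues must not be empty")
        if self.escape_distance <= 0:
            raise SpecValidationError(
                f"escape_distance must be > 0, got {self.escape_distance}"
            )
        if len(self.engagement_schedule) < 1:
            raise SpecValidationError("engagement_schedule must contain at least one frame")
        bad = set(self.engagement_schedule) - set(ENGAGEMENT_LABELS)
        if bad:
            raise SpecValidationError(
                f"engagement_schedule contains unknown labels {sorted(bad)}"
            )
        if self.water_schedule is not None and len(self.water_schedule) != len(
            self.engagement_schedule
        ):
            raise SpecValidationError(
                "water_schedule length must match engagement_schedule length"
            )


# ---------------------------------------------------------------------------
# geometry helpers


def build_ideal_helix(spec: HelixSpec) -> np.ndarray:
    """Exact Cα positions of a circular helix: residue k at
    (R cos kτ, R sin kτ, k·h).  Right-handed for positive twist.  Noise and
    frame structure are excluded here; this is the single-frame reference
    geometry."""
    turns = np.full(spec.n_residues - 1, spec.base_twist)
    return _helix_from_turns(spec, turns)


def _helix_from_turns(spec: HelixSpec, turn_angles: np.ndarray) -> np.ndarray:
    """Cα positions with per-turn angles (degrees, length n_residues-1)."""
    angles = np.concatenate([[0.0], np.cumsum(np.deg2rad(turn_angles))])
    z = np.arange(spec.n_residues) * spec.rise_per_residue
    return np.column_stack(
        [spec.radius * np.cos(angles), spec.radius * np.sin(angles), z]
    )


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given atoms a-b-c, bond |cd|, angle b-c-d, torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_alpha_backbone(
    n_residues: int,
    phi: float = -57.8,
    psi: float = -47.0,
    omega: float = 180.0,
) -> dict[str, np.ndarray]:
    """Backbone N/CA/C coordinates from canonical covalent geometry and the
    stated dihedrals, built by sequential internal-coordinate placement.

    Bond lengths and angles are the standard protein values (N-CA 1.458 Å,
    CA-C 1.525 Å, C-N 1.329 Å; N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°).
    The defaults are the canonical α-helical dihedrals, which yield a helix of
    ~3.6 residues per turn; its Cα local twist is the 100°/residue reference
    used throughout the twist analyses.
    """
    if n_residues < 2:
        raise SpecValidationError(f"n_residues must be >= 2, got {n_residues}")
    b_nca, b_cac, b_cn = 1.458, 1.525, 1.329
    a_ncac, a_cacn, a_cnca = 111.2, 116.2, 121.7

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([b_nca, 0.0, 0.0])]
    ang = np.deg2rad(a_ncac)
    C = [CA[0] + b_cac * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for _ in range(1, n_residues):
        N.append(_place_nerf(N[-1], CA[-1], C[-1], b_cn, a_cacn, psi))
        CA.append(_place_nerf(CA[-1], C[-1], N[-1], b_nca, a_cnca, omega))
        C.append(_place_nerf(C[-1], N[-1], CA[-1], b_cac, a_ncac, phi))
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C)}


def _helix_topology(n_residues: int) -> Topology:
    n = n_residues
    return Topology(
        chain=np.full(n, "A", dtype=object),
        resid=np.arange(1, n + 1),
        resname=np.full(n, "ALA", dtype=object),
        atom_name=np.full(n, "CA", dtype=object),
        element=np.full(n, "C", dtype=object),
        entity=np.full(n, "protein", dtype=object),
    )


# ---------------------------------------------------------------------------
# generators


def generate_helix_trajectory(
    spec: HelixSpec, events: list[UnwindEvent] | tuple[UnwindEvent, ...] = ()
) -> Trajectory:
    """Helix trajectory whose generative twist is ``base_twist`` everywhere
    except inside active unwinding events.

    Events must be pairwise non-overlapping in (residue, frame) space.  The
    exact per-frame per-turn twist schedule is returned in
    ``ground_truth["twist_schedule"]`` (shape n_frames × (n_residues-1),
    degrees).
    """
    events = list(events)
    for ev in events:
        if ev.residue_span[1] >= spec.n_residues:
            raise SpecValidationError(
                f"residue_span {ev.residue_span} exceeds helix of {spec.n_residues} residues"
            )
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            res_overlap = a.residue_span[0] <= b.residue_span[1] and b.residue_span[0] <= a.residue_span[1]
            frm_overlap = a.start_frame <= b.end_frame and b.start_frame <= a.end_frame
            if res_overlap and frm_overlap:
                raise SpecValidationError(
                    f"events overlap in (residue, frame) space: {a} vs {b}"
                )

    n_turns = spec.n_residues - 1
    schedule = np.full((spec.n_frames, n_turns), spec.base_twist, dtype=np.float64)
    for ev in events:
        lo, hi = ev.residue_span
        f1 = min(ev.end_frame, spec.n_frames - 1)
        schedule[ev.start_frame : f1 + 1, lo : min(hi, n_turns - 1) + 1] = ev.event_twist

    rng = np.random.default_rng(spec.seed)
    coords = np.empty((spec.n_frames, spec.n_residues, 3))
    for f in range(spec.n_frames):
        coords[f] = _helix_from_turns(spec, schedule[f])
    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    return Trajectory(
        topology=_helix_topology(spec.n_residues),
        coords=coords,
        frame_times=np.arange(spec.n_frames) * spec.frame_spacing,
        ground_truth={"twist_schedule": schedule},
    )


def generate_loop_flip_ensemble(spec: LoopFlipSpec, n_replicas: int = 1) -> list[Trajectory]:
    """Replicas of a rigid core with a two-state flipping loop.

    The base structure is an ideal helix of ``core_size + loop_size`` Cα
    atoms; the last ``loop_size`` residues form the loop, displaced along +x
    in state-1 frames.  Replica r uses a seed derived from ``spec.seed`` so
    replicas share topology and schedule but not noise.  Ground-truth state
    labels are in ``ground_truth["state_labels"]``.
    """
    if n_replicas < 1:
        raise SpecValidationError(f"n_replicas must be >= 1, got {n_replicas}")
    n_res = spec.core_size + spec.loop_size
    base = build_ideal_helix(
        HelixSpec(n_residues=n_res, n_frames=1, seed=0)
    )
    states = np.asarray(spec.state_schedule, dtype=np.int64)
    n_frames = len(states)
    direction = np.array([1.0, 0.0, 0.0])
    loop_idx = np.arange(spec.core_size, n_res)

    out: list[Trajectory] = []
    for r in range(n_replicas):
        seed_r = int((spec.seed + 1_000_003 * r) % (2**31 - 1))
        rng = np.random.default_rng(seed_r)
        coords = np.broadcast_to(base, (n_frames, n_res, 3)).copy()
        coords[np.flatnonzero(states == 1)[:, None], loop_idx[None, :], :] += (
            spec.flip_displacement * direction
        )
        if spec.noise_sigma > 0:
            coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        out.append(
            Trajectory(
                topology=_helix_topology(n_res),
                coords=coords,
                frame_times=np.arange(n_frames) * spec.frame_spacing,
                ground_truth={
                    "state_labels": states.copy(),
                    "loop_residues": loop_idx.copy(),
                    "replica_seed": seed_r,
                },
            )
        )
    return out


def _ligand_positions(anchor: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rigid 3-atom pseudo-ligand (donor N, central C, carboxylate-like O)
    laid out along *direction* starting at *anchor* (the donor position)."""
    d = direction / np.linalg.norm(direction)
    return np.stack([anchor, anchor + 1.47 * d, anchor + 2.71 * d])


def generate_engagement_trajectory(spec: EngagementSpec, helix: HelixSpec) -> Trajectory:
    """Helix + 3-atom pseudo-ligand + bridging-water particle.

    Placement per frame follows ``spec.engagement_schedule``; the exact labels
    and water-bridge booleans are returned in ``ground_truth``.  The helix
    carries the spec's positional noise; ligand and water are placed exactly
    so the engagement geometry holds by construction.
    """
    n_frames = len(spec.engagement_schedule)
    helix_traj = generate_helix_trajectory(
        HelixSpec(
            n_residues=helix.n_residues,
            radius=helix.radius,
            rise_per_residue=helix.rise_per_residue,
            base_twist=helix.base_twist,
            noise_sigma=helix.noise_sigma,
            n_frames=n_frames,
            frame_spacing=helix.frame_spacing,
            seed=spec.seed,
        )
    )
    motif = np.asarray(spec.motif_residues, dtype=np.int64)
    if motif.max() >= helix.n_residues or motif.min() < 0:
        raise SpecValidationError(
            f"motif_residues {spec.motif_residues} outside helix of {helix.n_residues} residues"
        )
    ideal = build_ideal_helix(
        HelixSpec(n_residues=helix.n_residues, radius=helix.radius,
                  rise_per_residue=helix.rise_per_residue, base_twist=helix.base_twist)
    )
    anchor_res = int(motif[0])
    partner_res = int(motif[1]) if len(motif) > 1 else int(motif[0])
    # radial outward unit vector at the anchor residue
    tau = np.deg2rad(helix.base_twist)
    outward = np.array([np.cos(anchor_res * tau), np.sin(anchor_res * tau), 0.0])
    site_center = (
        np.asarray(spec.site_center, dtype=np.float64)
        if spec.site_center is not None
        else ideal[motif].mean(axis=0) + 6.0 * outward
    )

    water_sched = (
        np.array([lab == "engaged" for lab in spec.engagement_schedule])
        if spec.water_schedule is None
        else np.asarray(spec.water_schedule, dtype=bool)
    )

    n_helix = helix.n_residues
    coords = np.empty((n_frames, n_helix + 4, 3))
    coords[:, :n_helix, :] = helix_traj.coords
    far_water = site_center + outward * (spec.escape_distance + 20.0)

    for f, label in enumerate(spec.engagement_schedule):
        if label == "engaged":
            donor = ideal[anchor_res] + spec.hbond_distance * outward
        elif label == "disengaged_in_site":
            donor = site_center + min(3.0, spec.escape_distance / 3.0) * outward
        else:  # escaped
            donor = site_center + (spec.escape_distance + 5.0) * outward
        coords[f, n_helix : n_helix + 3, :] = _ligand_positions(donor, outward)
        if water_sched[f]:
            partner = ideal[partner_res]
            mid = 0.5 * (donor + partner)
            coords[f, n_helix + 3, :] = mid
        else:
            coords[f, n_helix + 3, :] = far_water

    top = _helix_topology(n_helix)
    lig_water = Topology(
        chain=np.array(["L", "L", "L", "W"], dtype=object),
        resid=np.array([1, 1, 1, 1]),
        resname=np.array(["ORN", "ORN", "ORN", "HOH"], dtype=object),
        atom_name=np.array(["NE", "CD", "OXT", "O"], dtype=object),
        element=np.array(["N", "C", "O", "O"], dtype=object),
        entity=np.array(["ligand", "ligand", "ligand", "water"], dtype=object),
        formal_charge=np.array([1, 0, -1, 0]),
    )
    full_top = Topology(
        chain=np.concatenate([top.chain, lig_water.chain]),
        resid=np.concatenate([top.resid, lig_water.resid]),
        resname=np.concatenate([top.resname, lig_water.resname]),
        atom_name=np.concatenate([top.atom_name, lig_water.atom_name]),
        element=np.concatenate([top.element, lig_water.element]),
        entity=np.concatenate([top.entity, lig_water.entity]),
        formal_charge=np.concatenate([top.formal_charge, lig_water.formal_charge]),
    )
    return Trajectory(
        topology=full_top,
        coords=coords,
        frame_times=np.arange(n_frames) * helix.frame_spacing,
        ground_truth={
            "engagement_labels": np.array(spec.engagement_schedule, dtype=object),
            "water_bridge": water_sched,
            "site_center": site_center,
            "motif_residues": motif,
        },
    )


def random_engagement_schedule(
    rng: np.random.Generator, n_frames: int
) -> tuple[tuple[str, ...], str]:
    """Draw a random engagement schedule and its expected end-state fate.

    The replica stays engaged for a random initial stretch and then either
    remains bound, disengages but stays in the site, or escapes — the
    three-fate taxonomy of replicate MD.  Returns (schedule, expected fate in
    {'bound', 'disengaged_in_site', 'diffused_out'}).
    """
    fate = rng.choice(["bound", "disengaged_in_site", "diffused_out"])
    if fate == "bound":
        # mostly engaged throughout, occasional brief flicker
        labels = np.array(["engaged"] * n_frames, dtype=object)
        n_flicker = int(rng.integers(0, max(1, n_frames // 20)))
        flicker = rng.choice(n_frames, size=n_flicker, replace=False)
        labels[flicker] = "disengaged_in_site"
    else:
        t_leave = int(rng.integers(n_frames // 4, (3 * n_frames) // 4))
        end_label = "escaped" if fate == "diffused_out" else "disengaged_in_site"
        labels = np.array(
            ["engaged"] * t_leave + [end_label] * (n_frames - t_leave), dtype=object
        )
    return tuple(labels.tolist()), str(fate)
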