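"""Protein-ligand interaction fingerprints and replicate-averaged profiles.

Each frame is typed into per-residue interactions drawn from a small
vocabulary — hydrogen bond, salt bridge, π-cation, hydrophobic contact and
water bridge — using geometric rules with configurable cutoffs (defaults in
the range used by standard interaction-fingerprinting tools).  Per replicate,
each (residue, type) row is summarised as the fraction of frames in which the
interaction is present; across replicates the mean and sample standard
deviation are reported, mirroring how per-residue interaction profiles of
replicate MD simulations are presented.

Formal charges and aromatic-ring membership come from a built-in residue
template table covering the standard amino acids plus ornithine; topologies
may also carry explicit formal charges, which take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Topology, Trajectory
from .engagement import HBondCriteria
from .errors import SpecValidationError, TrajectoryError

__all__ = [
    "InteractionRuleSet",
    "FingerprintTable",
    "frame_fingerprint",
    "trajectory_fingerprints",
    "aggregate_fingerprints",
    "RESIDUE_TEMPLATES",
]

INTERACTION_TYPES = (
    "hydrogen_bond",
    "salt_bridge",
    "pi_cation",
    "hydrophobic",
    "water_bridge",
)

#: name -> (positive atoms, negative atoms, aromatic rings, apolar carbons)
RESIDUE_TEMPLATES: dict[str, dict] = {
    "ARG": {"positive": {"NH1", "NH2", "NE", "CZ"}, "negative": set(),
            "rings": [], "apolar": {"CB", "CG", "CD"}},
    "LYS": {"positive": {"NZ"}, "negative": set(), "rings": [],
            "apolar": {"CB", "CG", "CD", "CE"}},
    "HIS": {"positive": set(), "negative": set(),
            "rings": [("CG", "ND1", "CD2", "CE1", "NE2")], "apolar": {"CB"}},
    "ASP": {"positive": set(), "negative": {"OD1", "OD2"}, "rings": [], "apolar": {"CB"}},
    "GLU": {"positive": set(), "negative": {"OE1", "OE2"}, "rings": [], "apolar": {"CB", "CG"}},
    "PHE": {"positive": set(), "negative": set(),
            "rings": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
            "apolar": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}},
    "TYR": {"positive": set(), "negative": set(),
            "rings": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
            "apolar": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"}},
    "TRP": {"positive": set(), "negative": set(),
            "rings": [("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
            "apolar": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}},
    "ALA": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB"}},
    "VAL": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB", "CG1", "CG2"}},
    "LEU": {"positive": set(), "negative": set(), "rings": [],
            "apolar": {"CB", "CG", "CD1", "CD2"}},
    "ILE": {"positive": set(), "negative": set(), "rings": [],
            "apolar": {"CB", "CG1", "CG2", "CD1"}},
    "MET": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB", "CG", "CE"}},
    "PRO": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB", "CG", "CD"}},
    "GLY": {"positive": set(), "negative": set(), "rings": [], "apolar": set()},
    "SER": {"positive": set(), "negative": set(), "rings": [], "apolar": set()},
    "THR": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CG2"}},
    "CYS": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB"}},
    "ASN": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB"}},
    "GLN": {"positive": set(), "negative": set(), "rings": [], "apolar": {"CB", "CG"}},
    # ornithine as a free-ligand entity: protonated α- and δ-amino groups,
    # deprotonated carboxylate
    "ORN": {"positive": {"N", "NE"}, "negative": {"O", "OXT"}, "rings": [],
            "apolar": {"CB", "CG", "CD"}},
}


@dataclass(frozen=True)
class InteractionRuleSet:
    """Geometric thresholds per interaction type (Å / degrees)."""

    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    salt_bridge_cutoff: float = 4.5
    pi_cation_cutoff: float = 4.5
    pi_cation_max_offset: float = 30.0
    hydrophobic_cutoff: float = 4.5
    enabled: tuple[str, ...] = INTERACTION_TYPES

    def __post_init__(self) -> None:
        for name in ("salt_bridge_cutoff", "pi_cation_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.pi_cation_max_offset <= 180:
            raise SpecValidationError(
                f"pi_cation_max_offset must lie in [0, 180], got {self.pi_cation_max_offset}"
            )
        bad = set(self.enabled) - set(INTERACTION_TYPES)
        if bad:
            raise SpecValidationError(f"unknown interaction types {sorted(bad)}")


@dataclass
class FingerprintTable:
    """Tidy per-(residue, type) frequencies with across-replicate statistics.

    ``table`` columns: residue (chain:resid:resname), interaction, one
    ``rep<i>`` column per replicate (fraction of frames), mean, sd, n.
    """

    table: pd.DataFrame
    rules: InteractionRuleSet


def _annotations(top: Topology, idx: np.ndarray, rule: str, kind: str):
    """Per-atom annotation masks/structures for the given atoms."""
    out = []
    for a in idx:
        resname = str(top.resname[a]).upper()
        tmpl = RESIDUE_TEMPLATES.get(resname)
        if tmpl is None:
            raise TrajectoryError(
                f"rule '{rule}' requires template annotations but residue "
                f"{resname} is not in the template table"
            )
        out.append(tmpl)
    return out


def _charged_atoms(top: Topology, idx: np.ndarray, sign: int, rule: str) -> np.ndarray:
    """Atoms among idx with the requested formal-charge sign.

    Explicit topology charges win; otherwise the template table is consulted.
    """
    explicit = top.formal_charge[idx]
    if np.any(explicit != 0):
        return idx[np.sign(explicit) == sign]
    keep = []
    for a in idx:
        resname = str(top.resname[a]).upper()
        tmpl = RESIDUE_TEMPLATES.get(resname)
        if tmpl is None:
            raise TrajectoryError(
                f"rule '{rule}' requires charge annotations but residue "
                f"{resname} is not in the template table"
            )
        bucket = tmpl["positive"] if sign > 0 else tmpl["negative"]
        if str(top.atom_name[a]).upper() in bucket:
            keep.append(a)
    return np.asarray(keep, dtype=np.int64)


def _residue_key(top: Topology, a: int) -> tuple:
    return (str(top.chain[a]), int(top.resid[a]), str(top.resname[a]))


def frame_fingerprint(
    frame_coords: np.ndarray,
    topology: Topology,
    ligand_idx: np.ndarray,
    residue_idx: np.ndarray,
    rules: InteractionRuleSet | None = None,
    water_idx: np.ndarray | None = None,
) -> set[tuple[tuple, str]]:
    """Set of (residue key, interaction type) present in one frame.

    ``residue_idx`` are the protein atoms considered; ``water_idx`` enables
    the water-bridge rule.  Hydrogens are ignored throughout (heavy-atom
    geometry only).
    """
    rules = rules or InteractionRuleSet()
    x = np.asarray(frame_coords, dtype=np.float64)
    top = topology
    el = np.char.upper(top.element.astype(str))
    ligand_idx = np.asarray(ligand_idx)[el[np.asarray(ligand_idx)] != "H"]
    residue_idx = np.asarray(residue_idx)[el[np.asarray(residue_idx)] != "H"]
    if ligand_idx.size == 0 or residue_idx.size == 0:
        raise TrajectoryError("ligand or residue atom set is empty after removing hydrogens")

    found: set[tuple[tuple, str]] = set()
    dmat = np.linalg.norm(x[ligand_idx][:, None, :] - x[residue_idx][None, :, :], axis=2)

    if "hydrogen_bond" in rules.enabled:
        lig_polar = np.isin(el[ligand_idx], ["N", "O"])
        res_polar = np.isin(el[residue_idx], ["N", "O"])
        hits = np.argwhere(
            (dmat <= rules.hbond.max_donor_acceptor_distance)
            & lig_polar[:, None]
            & res_polar[None, :]
        )
        for _, j in hits:
            found.add((_residue_key(top, int(residue_idx[j])), "hydrogen_bond"))

    if "salt_bridge" in rules.enabled:
        for lig_sign in (+1, -1):
            lq = _charged_atoms(top, ligand_idx, lig_sign, "salt_bridge")
            rq = _charged_atoms(top, residue_idx, -lig_sign, "salt_bridge")
            if lq.size and rq.size:
                d = np.linalg.norm(x[lq][:, None, :] - x[rq][None, :, :], axis=2)
                for _, j in np.argwhere(d <= rules.salt_bridge_cutoff):
                    found.add((_residue_key(top, int(rq[j])), "salt_bridge"))

    if "pi_cation" in rules.enabled:
        cations = _charged_atoms(top, ligand_idx, +1, "pi_cation")
        cations = cations[el[cations] == "N"]
        if cations.size:
            # aromatic rings among the considered residues
            by_res: dict[tuple, list[int]] = {}
            for a in residue_idx:
                by_res.setdefault(_residue_key(top, int(a)), []).append(int(a))
            for key, atoms in by_res.items():
                tmpl = RESIDUE_TEMPLATES.get(key[2].upper())
                if tmpl is None:
                    raise TrajectoryError(
                        f"rule 'pi_cation' requires ring annotations but residue "
                        f"{key[2]} is not in the template table"
                    )
                names = {str(top.atom_name[a]).upper(): a for a in atoms}
                for ring in tmpl["rings"]:
                    if not all(n in names for n in ring):
                        continue
                    ring_xyz = x[[names[n] for n in ring]]
                    centroid = ring_xyz.mean(axis=0)
                    # ring normal from SVD of centred ring atoms
                    _, _, vt = np.linalg.svd(ring_xyz - centroid)
                    normal = vt[2]
                    for c in cations:
                        v = x[c] - centroid
                        dist = np.linalg.norm(v)
                        if dist > rules.pi_cation_cutoff or dist == 0:
                            continue
                        cosang = abs(v @ normal) / dist
                        offset = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if offset <= rules.pi_cation_max_offset:
                            found.add((key, "pi_cation"))

    if "hydrophobic" in rules.enabled:
        lig_c = [a for a, t in zip(ligand_idx, _annotations(top, ligand_idx, "hydrophobic", "apolar"))
                 if str(top.atom_name[a]).upper() in t["apolar"]]
        res_c = [a for a, t in zip(residue_idx, _annotations(top, residue_idx, "hydrophobic", "apolar"))
                 if str(top.atom_name[a]).upper() in t["apolar"]]
        if lig_c and res_c:
            d = np.linalg.norm(
                x[np.asarray(lig_c)][:, None, :] - x[np.asarray(res_c)][None, :, :], axis=2
            )
            for _, j in np.argwhere(d <= rules.hydrophobic_cutoff):
                found.add((_residue_key(top, int(res_c[j])), "hydrophobic"))

    if "water_bridge" in rules.enabled and water_idx is not None and len(water_idx):
        water_idx = np.asarray(water_idx)[el[np.asarray(water_idx)] != "H"]
        cut = rules.hbond.max_donor_acceptor_distance
        lig_polar = ligand_idx[np.isin(el[ligand_idx], ["N", "O"])]
        res_polar = residue_idx[np.isin(el[residue_idx], ["N", "O"])]
        if lig_polar.size and res_polar.size and water_idx.size:
            d_lw = np.linalg.norm(x[water_idx][:, None, :] - x[lig_polar][None, :, :], axis=2)
            d_rw = np.linalg.norm(x[water_idx][:, None, :] - x[res_polar][None, :, :], axis=2)
            near_lig = np.any(d_lw <= cut, axis=1)
            for w in np.flatnonzero(near_lig):
                for j in np.flatnonzero(d_rw[w] <= cut):
                    found.add((_residue_key(top, int(res_polar[j])), "water_bridge"))

    return found


def trajectory_fingerprints(
    traj: Trajectory,
    ligand_selection: str = "entity ligand",
    residue_selection: str = "entity protein",
    rules: InteractionRuleSet | None = None,
    water_selection: str = "entity water",
) -> list[set[tuple[tuple, str]]]:
    """Per-frame fingerprint sets for a whole trajectory."""
    rules = rules or InteractionRuleSet()
    lig = traj.select(ligand_selection)
    res = traj.select(residue_selection)
    wat = traj.select(water_selection, required=False)
    return [
        frame_fingerprint(traj.coords[f], traj.topology, lig, res, rules, water_idx=wat)
        for f in range(traj.n_frames)
    ]


def aggregate_fingerprints(
    replicate_fingerprints: list[list[set[tuple[tuple, str]]]],
    rules: InteractionRuleSet | None = None,
    residue_universes: list[set] | None = None,
) -> FingerprintTable:
    """Across-replicate mean and sample s.d. of per-(residue, type) frequencies.

    Each replicate is a list of per-frame fingerprint sets.  Every (residue,
    type) row observed in any replicate is scored in all replicates (absent =
    frequency 0).  ``residue_universes``, when given (one residue-key set per
    replicate, from the topologies), must be identical across replicates.
    With a single replicate the s.d. column is 0 by convention.
    """
    if not replicate_fingerprints:
        raise SpecValidationError("at least one replicate is required")
    if residue_universes is not None:
        if len(residue_universes) != len(replicate_fingerprints):
            raise SpecValidationError("one residue universe per replicate is required")
        first = residue_universes[0]
        for r, uni in enumerate(residue_universes[1:], start=2):
            if uni != first:
                raise SpecValidationError(
                    f"replicate {r} has a different residue universe than replicate 1"
                )
    rows = sorted({pair for frames in replicate_fingerprints for frame in frames for pair in frame})
    n_rep = len(replicate_fingerprints)
    freq = np.zeros((len(rows), n_rep))
    for r, frames in enumerate(replicate_fingerprints):
        if not frames:
            raise SpecValidationError(f"replicate {r} contains no frames")
        for i, pair in enumerate(rows):
            freq[i, r] = sum(pair in frame for frame in frames) / len(frames)
    mean = freq.mean(axis=1)
    sd = freq.std(axis=1, ddof=1) if n_rep > 1 else np.zeros(len(rows))
    sd[np.ptp(freq, axis=1) == 0] = 0.0  # identical replicates: exactly zero
    data = {
        "residue": [f"{k[0]}:{k[1]}:{k[2]}" for k, _ in rows],
        "interaction": [t for _, t in rows],
    }
    for r in range(n_rep):
        data[f"rep{r + 1}"] = freq[:, r]
    data["mean"] = mean
    data["sd"] = sd
    data["n"] = n_rep
    return FingerprintTable(table=pd.DataFrame(data), rules=rules or InteractionRuleSet())
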