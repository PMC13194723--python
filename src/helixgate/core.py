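"""In-memory containers: Topology and Trajectory.

A Trajectory is the package's canonical trajectory object: an ordered stack of
frames of labelled coordinates (Å) with per-frame time stamps (ps) and a
Topology describing chain/residue/atom naming, elements, formal charges and a
coarse entity classification (protein / ligand / water).  Synthetic generators
attach their ground truth (twist schedules, state labels, engagement labels)
in ``Trajectory.ground_truth`` so downstream analyses can be validated against
what was actually generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError, TrajectoryError

#: Residue names treated as water when classifying entities.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"})

#: The 20 standard amino acids plus common variants seen in PDB files.
PROTEIN_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
    }
)


def classify_entity(resname: str) -> str:
    """Classify a residue name as 'protein', 'water' or 'ligand'."""
    rn = resname.upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in PROTEIN_RESNAMES:
        return "protein"
    return "ligand"


@dataclass
class Topology:
    """Per-atom annotation arrays, all of equal length.

    Atom indices are dense 0..n_atoms-1; residue numbering follows the input
    (author numbering, 1-based for generated systems) and is never silently
    renumbered.
    """

    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    entity: np.ndarray
    formal_charge: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=object)
        self.resid = np.asarray(self.resid, dtype=np.int64)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.entity = np.asarray(self.entity, dtype=object)
        if self.formal_charge is None:
            self.formal_charge = np.zeros(len(self.chain), dtype=np.int64)
        self.formal_charge = np.asarray(self.formal_charge, dtype=np.int64)
        n = len(self.chain)
        for name in ("resid", "resname", "atom_name", "element", "entity", "formal_charge"):
            if len(getattr(self, name)) != n:
                raise TrajectoryError(
                    f"topology field '{name}' has length {len(getattr(self, name))}, expected {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resid) keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain, self.resid):
            seen.setdefault((c, int(r)), None)
        return list(seen)

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression to sorted atom indices.

        See :mod:`helixgate.select` for the grammar.
        """
        from .select import select_atoms

        return select_atoms(self, expression)


@dataclass
class Trajectory:
    """Coordinates (n_frames, n_atoms, 3) in Å plus topology and times (ps)."""

    topology: Topology
    coords: np.ndarray
    frame_times: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.frame_times) != self.coords.shape[0]:
            raise TrajectoryError(
                f"{len(self.frame_times)} frame times for {self.coords.shape[0]} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_spacing(self) -> float:
        """Frame spacing in ps (nan for single-frame trajectories)."""
        if self.n_frames < 2:
            return float("nan")
        return float(self.frame_times[1] - self.frame_times[0])

    def select(self, expression: str, required: bool = True) -> np.ndarray:
        idx = self.topology.select(expression)
        if required and idx.size == 0:
            raise SelectionError(f"selection {expression!r} resolves to zero atoms")
        return idx
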