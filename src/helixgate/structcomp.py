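"""Static-structure comparisons: Cα RMSD, binding-site shells, contact
distances, apo-vs-bound displacements and sequence identity/similarity.

Structures are read from PDB/mmCIF via :func:`helixgate.io.read_structure`
into a :class:`StructureModel`.  All distance and RMSD quantities are
heavy-atom only and rigid-motion invariant; cross-conformation RMSD pairs
residues by (chain, residue number) intersection by default.

Sequence identity/similarity uses global alignment with affine gaps
(Needleman-Wunsch as implemented by Biopython's PairwiseAligner) and a
substitution matrix (BLOSUM62 by default): identity is the fraction of
alignment columns with identical residues, similarity the fraction with a
positive substitution score (identities included).  The alternative
denominator (shorter sequence length) is reported in the result metadata
since conventions differ between alignment tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, classify_entity
from .errors import GeometryError, SelectionError, SpecValidationError

__all__ = [
    "StructureModel",
    "AlignmentResult",
    "ca_rmsd_pair",
    "shell_residues",
    "contact_distance",
    "state_displacement",
    "pairwise_identity_similarity",
]

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "HSD": "H", "HSE": "H", "HSP": "H",
}


@dataclass
class StructureModel:
    """A static structure: per-atom arrays plus coordinates (Å).

    ``icode`` is the PDB insertion code ('' when absent).  Entities are
    classified as protein / ligand / water by residue name.
    """

    chain: np.ndarray
    resid: np.ndarray
    icode: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    entity: np.ndarray = None  # type: ignore[assignment]
    source: str = ""

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=object)
        self.resid = np.asarray(self.resid, dtype=np.int64)
        self.icode = np.asarray(self.icode, dtype=object)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.entity is None:
            self.entity = np.array(
                [classify_entity(str(r)) for r in self.resname], dtype=object
            )
        if not np.all(np.isfinite(self.coords)):
            raise SpecValidationError("structure contains non-finite coordinates")
        keys = list(zip(self.chain, self.resid, self.icode, self.atom_name))
        if len(set(keys)) != len(keys):
            raise SpecValidationError(
                "duplicate (chain, resid, icode, atom name) keys in structure"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def as_topology(self) -> Topology:
        return Topology(
            chain=self.chain,
            resid=self.resid,
            resname=self.resname,
            atom_name=self.atom_name,
            element=self.element,
            entity=self.entity,
        )

    def select(self, expression: str, required: bool = True) -> np.ndarray:
        idx = self.as_topology().select(expression)
        if required and idx.size == 0:
            raise SelectionError(f"selection {expression!r} resolves to zero atoms")
        return idx

    def heavy(self, idx: np.ndarray) -> np.ndarray:
        el = np.char.upper(self.element[idx].astype(str))
        return idx[el != "H"]

    def sequence(self, chain: str) -> str:
        """One-letter protein sequence of a chain, in residue order."""
        mask = (self.chain.astype(str) == chain) & (self.entity.astype(str) == "protein")
        seen: dict[tuple, str] = {}
        for r, ic, rn in zip(self.resid[mask], self.icode[mask], self.resname[mask]):
            key = (int(r), str(ic))
            if key not in seen:
                seen[key] = _THREE_TO_ONE.get(str(rn).upper(), "X")
        return "".join(seen[k] for k in sorted(seen))

    def ca_map(self, chain: str | None = None) -> dict[tuple, np.ndarray]:
        """(chain, resid, icode) -> Cα coordinate."""
        out: dict[tuple, np.ndarray] = {}
        for i in range(self.n_atoms):
            if str(self.atom_name[i]).upper() != "CA" or str(self.entity[i]) != "protein":
                continue
            if chain is not None and str(self.chain[i]) != chain:
                continue
            out[(str(self.chain[i]), int(self.resid[i]), str(self.icode[i]))] = self.coords[i]
        return out


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    percent_identity: float
    percent_similarity: float
    scoring: dict = field(default_factory=dict)


def ca_rmsd_pair(
    a: StructureModel,
    b: StructureModel,
    pairing: list[tuple[tuple, tuple]] | None = None,
    chains: tuple[str, str] | None = None,
) -> tuple[float, int]:
    """Cα RMSD (Å) after Kabsch superposition over matched residues.

    The default correspondence is the (chain, resid, icode) intersection of
    both structures' Cα atoms; an explicit ``pairing`` (list of key pairs) or
    a chain restriction may be supplied.  Returns (rmsd, n_matched).
    """
    from .ensembles import kabsch_superpose

    ca_a = a.ca_map(chains[0] if chains else None)
    ca_b = b.ca_map(chains[1] if chains else None)
    if pairing is None:
        if chains and chains[0] != chains[1]:
            keys_a = {(k[1], k[2]): k for k in ca_a}
            keys_b = {(k[1], k[2]): k for k in ca_b}
            shared = sorted(set(keys_a) & set(keys_b))
            pairing = [(keys_a[s], keys_b[s]) for s in shared]
        else:
            shared = sorted(set(ca_a) & set(ca_b))
            pairing = [(s, s) for s in shared]
    if len(pairing) < 3:
        raise GeometryError(
            f"residue correspondence yields {len(pairing)} Cα pairs; need >= 3"
        )
    P = np.array([ca_a[ka] for ka, _ in pairing])
    Q = np.array([ca_b[kb] for _, kb in pairing])
    _, _, rmsd = kabsch_superpose(P, Q)
    return rmsd, len(pairing)


def shell_residues(
    s: StructureModel, center_selection: str, cutoff: float
) -> set[tuple[str, int, str]]:
    """Residues with any heavy atom within *cutoff* Å of the centre entity.

    The centre entity's own residues are excluded.  Monotone in cutoff;
    cutoff 0 gives the empty set.
    """
    center = s.heavy(s.select(center_selection))
    if center.size == 0:
        raise SelectionError(f"centre selection {center_selection!r} has no heavy atoms")
    if cutoff < 0:
        raise SpecValidationError(f"cutoff must be >= 0, got {cutoff}")
    center_res = {
        (str(s.chain[i]), int(s.resid[i]), str(s.icode[i])) for i in center
    }
    all_heavy = s.heavy(np.arange(s.n_atoms))
    d = np.linalg.norm(
        s.coords[all_heavy][:, None, :] - s.coords[center][None, :, :], axis=2
    )
    near = all_heavy[np.any(d <= cutoff, axis=1)] if cutoff > 0 else np.array([], dtype=int)
    out = set()
    for i in near:
        key = (str(s.chain[i]), int(s.resid[i]), str(s.icode[i]))
        if key not in center_res:
            out.add(key)
    return out


def contact_distance(s: StructureModel, selection_a: str, selection_b: str) -> float:
    """Minimum heavy-atom distance (Å) between two selections."""
    ia = s.heavy(s.select(selection_a))
    ib = s.heavy(s.select(selection_b))
    if ia.size == 0:
        raise SelectionError(f"selection {selection_a!r} resolves to no heavy atoms")
    if ib.size == 0:
        raise SelectionError(f"selection {selection_b!r} resolves to no heavy atoms")
    d = np.linalg.norm(s.coords[ia][:, None, :] - s.coords[ib][None, :, :], axis=2)
    return float(d.min())


def state_displacement(
    a: StructureModel,
    b: StructureModel,
    superpose_selection: str,
    report_atoms: list[tuple[str, int, str]],
) -> dict[tuple[str, int, str], float]:
    """Per-atom displacement (Å) of *report_atoms* between two conformations.

    Structure *b* is superposed onto *a* over the Cα atoms of
    ``superpose_selection`` (matched by (chain, resid, icode)); each reported
    atom (chain, resid, atom name) must exist in both structures.
    """
    from .ensembles import kabsch_superpose

    sel_a = a.select(superpose_selection)
    sel_b = b.select(superpose_selection)

    def keyed(s: StructureModel, idx: np.ndarray) -> dict[tuple, np.ndarray]:
        out = {}
        for i in idx:
            if str(s.atom_name[i]).upper() == "CA":
                out[(str(s.chain[i]), int(s.resid[i]), str(s.icode[i]))] = s.coords[i]
        return out

    ka, kb = keyed(a, sel_a), keyed(b, sel_b)
    shared = sorted(set(ka) & set(kb))
    if len(shared) < 3:
        raise GeometryError(
            f"superposition selection shares only {len(shared)} Cα pairs; need >= 3"
        )
    P = np.array([kb[k] for k in shared])
    Q = np.array([ka[k] for k in shared])
    R, t, _ = kabsch_superpose(P, Q)

    def atom_xyz(s: StructureModel, key: tuple[str, int, str]) -> np.ndarray:
        chain, resid, name = key
        mask = (
            (s.chain.astype(str) == chain)
            & (s.resid == resid)
            & (np.char.upper(s.atom_name.astype(str)) == name.upper())
        )
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise SelectionError(f"atom {key} missing from structure {s.source or '<b>'}")
        return s.coords[hits[0]]

    out = {}
    for key in report_atoms:
        xa = atom_xyz(a, key)
        xb = atom_xyz(b, key) @ R.T + t
        out[key] = float(np.linalg.norm(xb - xa))
    return out


def pairwise_identity_similarity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Global identity/similarity of two protein sequences (percent).

    Denominator: alignment length including gap columns (the alternative,
    shorter-sequence denominator, is recorded in ``scoring``).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise SpecValidationError(f"{name} is empty")
        bad = set(seq.upper()) - _AA_LETTERS
        if bad:
            raise SpecValidationError(f"{name} contains invalid residue letters {sorted(bad)}")

    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = Align.PairwiseAligner()
    sub = substitution_matrices.load(matrix)
    aligner.substitution_matrix = sub
    aligner.mode = "global"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    sa, sb = str(aln[0]), str(aln[1])

    length = len(sa)
    ident = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    simil = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        if x == y or sub[x, y] > 0:
            simil += 1
    shorter = min(len(seq_a), len(seq_b))
    return AlignmentResult(
        aligned_a=sa,
        aligned_b=sb,
        percent_identity=100.0 * ident / length,
        percent_similarity=100.0 * simil / length,
        scoring={
            "matrix": matrix,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
            "alignment_length": length,
            "identity_over_shorter": 100.0 * ident / shorter,
            "similarity_over_shorter": 100.0 * simil / shorter,
        },
    )
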