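"""Superposition, pooled PCA and gromos-style RMSD clustering.

Superposition uses the Kabsch algorithm (least-squares optimal proper
rotation; reflections disallowed).  Pooled PCA decomposes the coordinate
covariance of all frames of all supplied replicas about the pooled mean and
reports per-component variance fractions — the diagnostic used to decide
whether a single conformational mode (e.g. a loop flip) dominates an
ensemble.  Clustering follows the gromos algorithm: repeatedly take the frame
with the most neighbours within an RMSD cutoff as a cluster centre and remove
its neighbourhood; the representative of the most populated cluster is the
cluster median, the member with minimal mean RMSD to the other members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .core import Trajectory
from .errors import GeometryError, SpecValidationError

__all__ = [
    "EnsembleDecomposition",
    "ClusterResult",
    "kabsch_superpose",
    "superpose_trajectory",
    "pooled_pca",
    "classify_loop_state",
    "cluster_gromos",
    "pairwise_rmsd_matrix",
]


@dataclass
class EnsembleDecomposition:
    eigenvalues: np.ndarray          # descending, Å²
    variance_fraction: np.ndarray    # sums to 1
    projections: np.ndarray          # frames × components, Å
    components: np.ndarray           # components × 3N
    mean_structure: np.ndarray       # (N, 3) Å
    selection: str
    frame_origin: np.ndarray         # replica index per pooled frame


@dataclass
class ClusterResult:
    assignments: np.ndarray          # per-frame cluster id (0 = largest-first order of discovery)
    sizes: np.ndarray                # per-cluster frame counts
    centers: np.ndarray              # per-cluster centre frame index
    representative_frame: int        # cluster median of the most populated cluster
    cutoff: float


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t mapping mobile onto reference.

    Returns (R, t, rmsd) with ``mobile @ R.T + t`` the fitted coordinates.
    Raises GeometryError for < 3 points or a rank-deficient (collinear)
    configuration, where the rotation is not unique.
    """
    P = np.asarray(mobile, dtype=np.float64)
    Q = np.asarray(reference, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"point sets must both be (n, 3); got {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"superposition requires >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise GeometryError("rank-deficient point spread (collinear points); rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt((w * np.sum((fitted - Q) ** 2, axis=1)).sum()))
    return R, t, rmsd


def superpose_trajectory(
    traj: Trajectory, selection: str, n_iterations: int = 2
) -> np.ndarray:
    """All-atom coordinates after fitting every frame on *selection*.

    Frames are first fitted to frame 0, then refitted to the mean structure
    ``n_iterations`` times (the usual iterative-mean refinement).
    """
    idx = traj.select(selection)
    coords = traj.coords.copy()
    ref = coords[0, idx, :]
    for _ in range(n_iterations + 1):
        for f in range(traj.n_frames):
            R, t, _ = kabsch_superpose(coords[f, idx, :], ref)
            coords[f] = coords[f] @ R.T + t
        ref = coords[:, idx, :].mean(axis=0)
    return coords


def pooled_pca(
    trajs: list[Trajectory] | Trajectory,
    selection: str = "name CA",
    superpose_selection: str | None = None,
    superpose: bool = True,
) -> EnsembleDecomposition:
    """PCA of pooled frame coordinates over *selection*.

    All replicas are concatenated and superposed on ``superpose_selection``
    (default: the analysis selection; for a mobile loop on a rigid core, pass
    the core here so loop motion is not absorbed by the fit), unless
    ``superpose=False`` for pre-aligned input.  The coordinate covariance of
    the analysis selection about the pooled mean is then decomposed; variance
    fractions are eigenvalue / trace and sum to 1.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise SpecValidationError("pooled_pca needs at least one trajectory")
    sup_sel = superpose_selection or selection
    idx = trajs[0].select(selection)
    frames = []
    origin = []
    for r, t in enumerate(trajs):
        jdx = t.select(selection)
        if len(jdx) != len(idx):
            raise SpecValidationError(
                f"selection {selection!r} resolves to {len(jdx)} atoms in replica {r}, "
                f"expected {len(idx)}"
            )
        x = superpose_trajectory(t, sup_sel)[:, jdx, :] if superpose else t.coords[:, jdx, :]
        frames.append(x)
        origin.extend([r] * t.n_frames)
    X = np.concatenate(frames, axis=0)
    n_frames = X.shape[0]
    if n_frames < 2:
        raise SpecValidationError("pooled PCA requires at least 2 pooled frames")
    if superpose and len(trajs) > 1:
        # refit on the pooled mean of the superpose selection so replicas share
        # one frame of reference
        sup_idx_in_sel = None
        kdx = trajs[0].select(sup_sel)
        lookup = {int(a): i for i, a in enumerate(idx)}
        if all(int(a) in lookup for a in kdx):
            sup_idx_in_sel = np.array([lookup[int(a)] for a in kdx])
        fit_cols = sup_idx_in_sel if sup_idx_in_sel is not None else np.arange(X.shape[1])
        ref = X[:, fit_cols, :].mean(axis=0)
        for f in range(n_frames):
            R, tr, _ = kabsch_superpose(X[f, fit_cols, :], ref)
            X[f] = X[f] @ R.T + tr
    flat = X.reshape(n_frames, -1)
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(flat)
    eig = pca.explained_variance_
    frac = pca.explained_variance_ratio_
    return EnsembleDecomposition(
        eigenvalues=eig,
        variance_fraction=frac,
        projections=proj,
        components=pca.components_,
        mean_structure=flat.mean(axis=0).reshape(-1, 3),
        selection=selection,
        frame_origin=np.asarray(origin, dtype=np.int64),
    )


def classify_loop_state(
    decomposition: EnsembleDecomposition,
    component: int = 0,
    threshold: float | None = None,
    n_bins: int = 64,
) -> np.ndarray:
    """Per-frame labels {'flipped_in', 'flipped_out'} from a PC projection.

    With no explicit threshold, the projection histogram is scanned for its
    two largest modes and the midpoint of their bin centres is used.  If the
    distribution is unimodal a warning is emitted and all frames get one
    label.  Frames below the threshold are labelled 'flipped_in'.
    """
    if component >= decomposition.projections.shape[1] or component < 0:
        raise SpecValidationError(
            f"component {component} out of range (have "
            f"{decomposition.projections.shape[1]} components)"
        )
    p = decomposition.projections[:, component]
    if threshold is None:
        # kernel-density mode finding: a smooth density estimate avoids the
        # spurious local maxima of a raw histogram
        from scipy.stats import gaussian_kde

        spread = np.ptp(p)
        if spread == 0:
            warnings.warn(
                "projection distribution is unimodal; all frames assigned one state",
                stacklevel=2,
            )
            return np.full(len(p), "flipped_in", dtype=object)
        grid = np.linspace(p.min() - 0.05 * spread, p.max() + 0.05 * spread, 4 * n_bins)
        density = gaussian_kde(p)(grid)
        peaks, props = find_peaks(density, prominence=0.05 * density.max())
        if len(peaks) < 2:
            warnings.warn(
                "projection distribution is unimodal; all frames assigned one state",
                stacklevel=2,
            )
            return np.full(len(p), "flipped_in", dtype=object)
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        threshold = float(grid[top2].mean())
    labels = np.where(p <= threshold, "flipped_in", "flipped_out")
    return labels.astype(object)


def pairwise_rmsd_matrix(
    coords: np.ndarray, fit: bool = True
) -> np.ndarray:
    """Symmetric all-vs-all RMSD (Å) over frames of shape (F, N, 3).

    With ``fit=True`` each pair is Kabsch-superposed first (the behaviour of
    standard trajectory-clustering tools); otherwise raw coordinate RMSD.
    """
    F = coords.shape[0]
    mat = np.zeros((F, F))
    if fit:
        for i in range(F):
            for j in range(i + 1, F):
                _, _, r = kabsch_superpose(coords[i], coords[j])
                mat[i, j] = mat[j, i] = r
    else:
        for i in range(F):
            d = coords[i + 1 :] - coords[i]
            if len(d):
                mat[i, i + 1 :] = mat[i + 1 :, i] = np.sqrt(
                    np.mean(np.sum(d**2, axis=2), axis=1)
                )
    if not np.all(np.isfinite(mat)):
        raise GeometryError("non-finite pairwise RMSD encountered")
    return mat


def cluster_gromos(
    frames: Trajectory | np.ndarray,
    selection: str | None = None,
    cutoff: float = 1.0,
    fit: bool = True,
) -> ClusterResult:
    """Gromos clustering at an RMSD *cutoff* (Å, default 1.0).

    Greedily extracts the frame with the most neighbours within the cutoff
    (ties broken by lowest frame index), assigns its neighbourhood to a
    cluster, removes it and repeats.  The representative frame is the cluster
    median of the most populated cluster: the member with minimal mean RMSD
    to the other members (size ties broken by earliest-discovered cluster;
    median ties by lowest frame index).
    """
    if isinstance(frames, Trajectory):
        idx = frames.select(selection) if selection else np.arange(frames.n_atoms)
        coords = frames.coords[:, idx, :]
    else:
        coords = np.asarray(frames, dtype=np.float64)
    F = coords.shape[0]
    if F < 1:
        raise SpecValidationError("clustering requires at least one frame")
    mat = pairwise_rmsd_matrix(coords, fit=fit)
    neighbour = mat <= cutoff

    assignments = np.full(F, -1, dtype=np.int64)
    remaining = np.ones(F, dtype=bool)
    sizes: list[int] = []
    centers: list[int] = []
    cid = 0
    while remaining.any():
        counts = (neighbour & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbour[center] & remaining)
        assignments[members] = cid
        sizes.append(len(members))
        centers.append(center)
        remaining[members] = False
        cid += 1

    sizes_arr = np.asarray(sizes, dtype=np.int64)
    largest = int(np.argmax(sizes_arr))
    members = np.flatnonzero(assignments == largest)
    if len(members) == 1:
        rep = int(members[0])
    else:
        sub = mat[np.ix_(members, members)]
        mean_rmsd = sub.sum(axis=1) / (len(members) - 1)
        rep = int(members[int(np.argmin(mean_rmsd))])
    return ClusterResult(
        assignments=assignments,
        sizes=sizes_arr,
        centers=np.asarray(centers, dtype=np.int64),
        representative_frame=rep,
        cutoff=float(cutoff),
    )
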