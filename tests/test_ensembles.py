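"""Kabsch superposition, pooled PCA, loop-state calls, gromos clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixgate.ensembles import (
    classify_loop_state,
    cluster_gromos,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    pooled_pca,
)
from helixgate.errors import GeometryError, SpecValidationError
from helixgate.synthgen import HelixSpec, generate_helix_trajectory


@pytest.fixture(scope="module")
def chiral_points():
    rng = np.random.default_rng(0)
    return rng.normal(size=(12, 3))


class TestKabsch:
    def test_pure_translation_recovered(self, chiral_points):
        R, t, rmsd = kabsch_superpose(chiral_points + [5, -2, 7], chiral_points)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, [-5, 2, -7], atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_recovered(self, chiral_points):
        R_true = Rotation.from_rotvec(np.deg2rad(30) * np.array([0, 0, 1.0])).as_matrix()
        mobile = chiral_points @ R_true.T
        R, _, rmsd = kabsch_superpose(mobile, chiral_points)
        np.testing.assert_allclose(R @ R_true, np.eye(3), atol=1e-6)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_cannot_fit_exactly(self, chiral_points):
        mirror = chiral_points * np.array([1, 1, -1])
        R, _, rmsd = kabsch_superpose(mirror, chiral_points)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_rmsd_symmetric(self, chiral_points):
        rng = np.random.default_rng(1)
        other = chiral_points + rng.normal(0, 0.5, size=chiral_points.shape)
        _, _, ab = kabsch_superpose(chiral_points, other)
        _, _, ba = kabsch_superpose(other, chiral_points)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


class TestPooledPCA:
    def test_loop_flip_mode_dominates(self, loop_flip_ensemble):
        dec = pooled_pca(loop_flip_ensemble, "name CA", superpose_selection="resid 1:50")
        assert dec.variance_fraction[0] >= 0.8
        assert dec.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_orthonormal(self, loop_flip_ensemble):
        dec = pooled_pca(loop_flip_ensemble, "name CA", superpose_selection="resid 1:50")
        k = min(10, dec.components.shape[0])
        gram = dec.components[:k] @ dec.components[:k].T
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-8)

    def test_isotropic_noise_has_no_dominant_component(self):
        traj = generate_helix_trajectory(
            HelixSpec(n_residues=20, n_frames=500, noise_sigma=0.3, seed=17)
        )
        dec = pooled_pca(traj, "name CA")
        mean_frac = dec.variance_fraction.mean()
        assert dec.variance_fraction[0] < 3 * mean_frac

    def test_single_frame_rejected(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=1))
        with pytest.raises(SpecValidationError):
            pooled_pca(traj)


class TestLoopStateClassification:
    def test_two_state_labels_match_ground_truth(self, loop_flip_ensemble):
        dec = pooled_pca(loop_flip_ensemble, "name CA", superpose_selection="resid 1:50")
        labels = classify_loop_state(dec)
        truth = np.concatenate(
            [t.ground_truth["state_labels"] for t in loop_flip_ensemble]
        )
        as_label = np.where(truth == 0, "flipped_in", "flipped_out")
        acc = np.mean(labels == as_label)
        assert max(acc, 1 - acc) >= 0.99  # sign of a PC is arbitrary

    def test_unimodal_projection_warns_and_yields_single_state(self):
        traj = generate_helix_trajectory(
            HelixSpec(n_residues=10, n_frames=300, noise_sigma=0.2, seed=3)
        )
        dec = pooled_pca(traj, "name CA")
        with pytest.warns(UserWarning, match="unimodal"):
            labels = classify_loop_state(dec)
        assert len(set(labels)) == 1

    def test_infinite_threshold_gives_one_label(self, loop_flip_ensemble):
        dec = pooled_pca(loop_flip_ensemble, "name CA", superpose_selection="resid 1:50")
        labels = classify_loop_state(dec, threshold=np.inf)
        assert set(labels) == {"flipped_in"}


def brute_force_gromos(mat: np.ndarray, cutoff: float):
    """Independent reference implementation by exhaustive neighbour counting."""
    n = mat.shape[0]
    remaining = set(range(n))
    assignments = {}
    sizes = []
    cid = 0
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if mat[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in remaining if mat[best, j] <= cutoff)
        for j in members:
            assignments[j] = cid
        sizes.append(len(members))
        remaining -= set(members)
        cid += 1
    largest = int(np.argmax(sizes))
    members = sorted(j for j, c in assignments.items() if c == largest)
    if len(members) == 1:
        rep = members[0]
    else:
        means = [sum(mat[i, j] for j in members if j != i) / (len(members) - 1) for i in members]
        rep = members[int(np.argmin(means))]
    return [assignments[i] for i in range(n)], sizes, rep


class TestGromosClustering:
    def _two_groups(self, n_big=7, n_small=3, sep=50.0, jitter=0.3, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(5, 3)) * 4
        frames = [base + rng.normal(0, jitter, size=base.shape) for _ in range(n_big)]
        far = base + np.array([sep, 0, 0]) + 2.0 * rng.normal(size=base.shape)
        frames += [far + rng.normal(0, jitter, size=base.shape) for _ in range(n_small)]
        return np.array(frames)

    def test_two_tight_groups_recovered(self):
        coords = self._two_groups()
        res = cluster_gromos(coords, cutoff=1.0)
        assert sorted(res.sizes.tolist(), reverse=True) == [7, 3]
        assert res.representative_frame < 7  # from the big group

    def test_matches_bruteforce_on_random_fixtures(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 13))
            coords = rng.normal(size=(n, 4, 3)) * rng.uniform(0.3, 2.0)
            mat = pairwise_rmsd_matrix(coords, fit=True)
            res = cluster_gromos(coords, cutoff=1.0)
            bf_assign, bf_sizes, bf_rep = brute_force_gromos(mat, 1.0)
            assert res.assignments.tolist() == bf_assign
            assert res.sizes.tolist() == bf_sizes
            assert res.representative_frame == bf_rep

    def test_identical_frames_single_cluster_lowest_index_rep(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 6, 3)), (5, 1, 1))
        res = cluster_gromos(coords, cutoff=1.0)
        assert len(res.sizes) == 1 and res.sizes[0] == 5
        assert res.representative_frame == 0

    def test_tiny_cutoff_singleton_clusters(self):
        coords = self._two_groups()
        res = cluster_gromos(coords, cutoff=1e-9)
        assert len(res.sizes) == len(coords)
        assert np.all(res.sizes == 1)

    def test_trajectory_input_with_selection(self, loop_flip_ensemble):
        traj = loop_flip_ensemble[0]
        sub = type(traj)(
            topology=traj.topology,
            coords=traj.coords[:10],
            frame_times=traj.frame_times[:10],
        )
        res = cluster_gromos(sub, "resid 51:60", cutoff=2.0)
        assert res.assignments.shape == (10,)
        assert res.sizes.sum() == 10
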