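"""Interaction typing rules and replicate aggregation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixgate.core import Topology
from helixgate.errors import SpecValidationError, TrajectoryError
from helixgate.fingerprints import (
    InteractionRuleSet,
    aggregate_fingerprints,
    frame_fingerprint,
)


def _toy_system():
    """Ornithine-like ligand near an ASP / TYR / LEU / SER pocket.

    Returns (topology, coords, ligand_idx, residue_idx).
    """
    names = []
    # ligand ORN: cationic NE, apolar CD, anionic OXT
    atoms = [
        ("L", 1, "ORN", "NE", "N"),
        ("L", 1, "ORN", "CD", "C"),
        ("L", 1, "ORN", "OXT", "O"),
        # ASP 10: carboxylate oxygen
        ("A", 10, "ASP", "OD1", "O"),
        ("A", 10, "ASP", "CB", "C"),
        # TYR 20: aromatic ring
        ("A", 20, "TYR", "CG", "C"),
        ("A", 20, "TYR", "CD1", "C"),
        ("A", 20, "TYR", "CD2", "C"),
        ("A", 20, "TYR", "CE1", "C"),
        ("A", 20, "TYR", "CE2", "C"),
        ("A", 20, "TYR", "CZ", "C"),
        # LEU 30: apolar side-chain carbon
        ("A", 30, "LEU", "CD1", "C"),
        # SER 40: polar hydroxyl oxygen
        ("A", 40, "SER", "OG", "O"),
    ]
    top = Topology(
        chain=[a[0] for a in atoms],
        resid=[a[1] for a in atoms],
        resname=[a[2] for a in atoms],
        atom_name=[a[3] for a in atoms],
        element=[a[4] for a in atoms],
        entity=["ligand"] * 3 + ["protein"] * 10,
    )
    ring = 1.4 * np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    )
    coords = np.array(
        [
            [0.0, 0.0, 4.0],     # NE: 4 Å above the TYR ring centroid (origin)
            [20.0, 0.0, 0.0],    # CD: repositioned per test
            [30.0, 0.0, 0.0],    # OXT
            [0.0, 0.0, 7.5],     # ASP OD1: 3.5 Å from NE
            [0.0, 2.0, 7.5],     # ASP CB
            *ring,               # TYR ring in z=0 plane
            [24.0, 0.0, 0.0],    # LEU CD1: 4.0 Å from ligand CD
            [40.0, 0.0, 0.0],    # SER OG
        ]
    )
    return top, coords, np.arange(3), np.arange(3, 13)


class TestFrameRules:
    def setup_method(self):
        self.top, self.coords, self.lig, self.res = _toy_system()

    def fp(self, coords=None, rules=None):
        return frame_fingerprint(
            coords if coords is not None else self.coords,
            self.top, self.lig, self.res, rules,
        )

    def test_salt_bridge_inside_cutoff(self):
        assert (("A", 10, "ASP"), "salt_bridge") in self.fp()

    def test_salt_bridge_outside_cutoff(self):
        coords = self.coords.copy()
        coords[3] = [0.0, 0.0, 12.0]  # OD1 8 Å from NE
        assert (("A", 10, "ASP"), "salt_bridge") not in self.fp(coords)

    def test_pi_cation_above_ring(self):
        assert (("A", 20, "TYR"), "pi_cation") in self.fp()

    def test_pi_cation_too_far(self):
        coords = self.coords.copy()
        coords[0] = [0.0, 0.0, 8.0]
        assert (("A", 20, "TYR"), "pi_cation") not in self.fp(coords)

    def test_pi_cation_lateral_offset_rejected(self):
        coords = self.coords.copy()
        coords[0] = [4.0, 0.0, 0.5]  # within 4.5 Å but ~83° off the ring axis
        assert (("A", 20, "TYR"), "pi_cation") not in self.fp(coords)

    def test_hydrophobic_contact(self):
        assert (("A", 30, "LEU"), "hydrophobic") in self.fp()

    def test_hydrogen_bond_to_polar_oxygen(self):
        coords = self.coords.copy()
        coords[12] = [0.0, 2.9, 4.0]  # SER OG 2.9 Å from NE
        assert (("A", 40, "SER"), "hydrogen_bond") in self.fp(coords)

    def test_rigid_motion_invariance(self):
        R = Rotation.from_euler("xyz", [31, -17, 59], degrees=True).as_matrix()
        moved = self.coords @ R.T + np.array([3.0, -7.0, 11.0])
        assert self.fp(moved) == self.fp()

    def test_atom_order_invariance(self):
        perm = np.random.default_rng(0).permutation(len(self.coords))
        top = Topology(
            chain=self.top.chain[perm], resid=self.top.resid[perm],
            resname=self.top.resname[perm], atom_name=self.top.atom_name[perm],
            element=self.top.element[perm], entity=self.top.entity[perm],
        )
        inv = np.argsort(perm)
        lig = np.sort(inv[self.lig])
        res = np.sort(inv[self.res])
        assert frame_fingerprint(self.coords[perm], top, lig, res) == self.fp()

    def test_relaxing_thresholds_never_removes_rows(self):
        tight = self.fp()
        for kwargs in (
            {"salt_bridge_cutoff": 6.0},
            {"pi_cation_cutoff": 6.0},
            {"hydrophobic_cutoff": 6.0},
            {"pi_cation_max_offset": 60.0},
        ):
            relaxed = self.fp(rules=InteractionRuleSet(**kwargs))
            assert tight <= relaxed

    def test_unknown_residue_template_raises(self):
        top, coords, lig, res = _toy_system()
        top.resname[3] = "XYZ"
        top.resname[4] = "XYZ"
        with pytest.raises(TrajectoryError, match="salt_bridge|hydrophobic"):
            frame_fingerprint(coords, top, lig, res)


class TestAggregation:
    KEY = (("A", 10, "ASP"), "salt_bridge")

    def _frames(self, n_present, n_total):
        return [{self.KEY} for _ in range(n_present)] + [set() for _ in range(n_total - n_present)]

    def test_two_replicate_mean_and_sd(self):
        table = aggregate_fingerprints([self._frames(4, 10), self._frames(6, 10)]).table
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(np.sqrt(0.02), abs=1e-6)  # ≈ 0.141

    def test_identical_replicates_zero_sd(self):
        reps = [self._frames(7, 10)] * 3
        table = aggregate_fingerprints(reps).table
        assert np.all(table["sd"] == 0.0)

    def test_three_replicates_with_scheduled_contact(self):
        reps = [self._frames(100, 100), self._frames(100, 100), self._frames(97, 100)]
        row = aggregate_fingerprints(reps).table.iloc[0]
        assert row["mean"] == pytest.approx(0.99, abs=1e-9)
        assert row["sd"] == pytest.approx(0.0173, abs=0.0005)

    def test_single_replicate_sd_zero_by_convention(self):
        table = aggregate_fingerprints([self._frames(5, 10)]).table
        assert table.iloc[0]["sd"] == 0.0
        assert table.iloc[0]["mean"] == pytest.approx(0.5)

    def test_absent_row_counts_as_zero_frequency(self):
        table = aggregate_fingerprints([self._frames(10, 10), self._frames(0, 10)]).table
        assert table.iloc[0]["mean"] == pytest.approx(0.5)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(SpecValidationError):
            aggregate_fingerprints(
                [self._frames(1, 2), self._frames(1, 2)],
                residue_universes=[{("A", 10, "ASP")}, {("A", 11, "GLU")}],
            )

    def test_empty_input_rejected(self):
        with pytest.raises(SpecValidationError):
            aggregate_fingerprints([])


class TestOracleEquality:
    def test_frequencies_match_bruteforce_recount(self):
        """Aggregate frequencies equal an independent per-frame distance check."""
        top, coords0, lig, res = _toy_system()
        rng = np.random.default_rng(4)
        frames = []
        coords_list = []
        for _ in range(10):
            c = coords0.copy()
            c[0, 2] = rng.uniform(2.0, 9.0)  # NE height above ring varies
            coords_list.append(c)
            frames.append(frame_fingerprint(c, top, lig, res))
        freq = aggregate_fingerprints([frames]).table
        # independent oracle: ASP salt bridge iff |NE - OD1| <= 4.5
        expect = np.mean(
            [np.linalg.norm(c[0] - c[3]) <= 4.5 for c in coords_list]
        )
        got = freq.loc[
            (freq["residue"] == "A:10:ASP") & (freq["interaction"] == "salt_bridge"),
            "mean",
        ]
        assert float(got.iloc[0]) == pytest.approx(expect)
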