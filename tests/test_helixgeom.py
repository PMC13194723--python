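"""Local twist, deviation maps, time integration and RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from helixgate.errors import GeometryError, SpecValidationError, TrajectoryError
from helixgate.helixgeom import (
    IDEAL_ALPHA_TWIST,
    TwistMap,
    integrate_deviation,
    local_twist,
    rmsf,
    twist_map,
    wrap_angle,
)
from helixgate.synthgen import (
    HelixSpec,
    LoopFlipSpec,
    UnwindEvent,
    build_ideal_helix,
    generate_helix_trajectory,
    generate_loop_flip_ensemble,
)


class TestLocalTwist:
    @pytest.mark.parametrize("tau", [100.0, 87.0, 50.0, 140.0])
    def test_circular_helix_twist_equals_rotation(self, tau):
        xyz = build_ideal_helix(HelixSpec(n_residues=8, base_twist=tau))
        for i in range(4):
            assert local_twist(*xyz[i : i + 4]) == pytest.approx(tau, abs=1e-9)

    def test_collinear_points_raise(self):
        pts = [np.array([0.0, 0.0, z]) for z in range(4)]
        with pytest.raises(GeometryError):
            local_twist(*pts)

    def test_coincident_points_raise(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            local_twist(p, p, p, p)

    @given(
        angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
        shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    @settings(max_examples=50, deadline=None)
    def test_rigid_motion_invariance(self, angles, shift):
        xyz = build_ideal_helix(HelixSpec(n_residues=4, base_twist=87.0))
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        moved = xyz @ R.T + np.asarray(shift)
        assert local_twist(*moved) == pytest.approx(local_twist(*xyz), abs=1e-9)


class TestTwistMap:
    def test_ideal_helix_has_zero_deviation(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=3))
        tm = twist_map(traj)
        assert np.all(np.abs(tm.delta_theta) < 1e-6)
        assert tm.reference_twist == IDEAL_ALPHA_TWIST

    def test_event_deviation_localised(self, event_trajectory):
        traj, event = event_trajectory
        tm = twist_map(traj)
        # resid = 0-based index + 1; interior event residue index 11 -> resid 12
        row = np.flatnonzero(tm.residue_ids == 12)[0]
        assert tm.delta_theta[row, 150] == pytest.approx(-13.0, abs=1e-9)
        assert tm.delta_theta[row, 50] == pytest.approx(0.0, abs=1e-9)
        # far from the event: no deviation at any time
        far = np.flatnonzero(tm.residue_ids == 25)[0]
        assert np.all(np.abs(tm.delta_theta[far]) < 1e-6)

    def test_four_residue_selection_yields_single_row(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=2))
        tm = twist_map(traj, "resid 3:6")
        assert len(tm.residue_ids) == 1
        assert tm.residue_ids[0] == 4  # window (3,4,5,6) assigned to resid 4

    def test_assignment_convention_configurable(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=2))
        tm = twist_map(traj, "resid 3:6", assign_to=2)
        assert tm.residue_ids[0] == 5

    def test_too_few_residues_rejected(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=2))
        with pytest.raises(TrajectoryError):
            twist_map(traj, "resid 3:5")

    def test_missing_coordinates_reported_with_frame_and_residue(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=3))
        traj.coords[1, 4, 0] = np.nan
        with pytest.raises(TrajectoryError, match="frame 1.*residue 5"):
            twist_map(traj)

    def test_wrap_angle_range(self):
        vals = wrap_angle(np.array([-500.0, -180.0, 0.0, 180.0, 500.0]))
        assert np.all(vals > -180.0) and np.all(vals <= 180.0)
        assert wrap_angle(180.0) == 180.0
        assert wrap_angle(-180.0) == 180.0


class TestIntegrateDeviation:
    def _map(self, delta, dt_ps=50.0):
        delta = np.asarray(delta, dtype=float)
        n_res, n_frames = delta.shape
        return TwistMap(
            residue_ids=np.arange(1, n_res + 1),
            frame_times=np.arange(n_frames) * dt_ps,
            theta=delta + 100.0,
            delta_theta=delta,
        )

    def test_constant_deviation_closed_form(self):
        # -13° held for 0.5 μs (10000 frames × 50 ps) -> 6.5 °·μs
        tm = self._map(np.full((1, 10000), -13.0))
        integ = integrate_deviation(tm)
        assert integ.value[0] == pytest.approx(6.5, rel=1e-9)
        assert integ.total_time == pytest.approx(0.5, rel=1e-9)

    def test_zero_deviation_integrates_to_zero(self):
        integ = integrate_deviation(self._map(np.zeros((3, 100))))
        np.testing.assert_array_equal(integ.value, 0.0)

    def test_seeded_event_integral_and_argmax(self):
        # 0.2 μs event (4000 frames) at -13° on an otherwise ideal helix
        spec = HelixSpec(n_residues=20, n_frames=5000)
        event = UnwindEvent((8, 10), 87.0, 500, 4499)
        traj = generate_helix_trajectory(spec, [event])
        integ = integrate_deviation(twist_map(traj))
        assert integ.argmax_residue() == 10  # interior event residue (index 9)
        assert integ.value.max() == pytest.approx(13.0 * 0.2, rel=1e-6)

    @pytest.mark.parametrize("n_event_frames", [1000, 2000, 4000])
    def test_integral_scales_linearly_with_duration(self, n_event_frames):
        spec = HelixSpec(n_residues=20, n_frames=5000)
        event = UnwindEvent((8, 10), 87.0, 0, n_event_frames - 1)
        traj = generate_helix_trajectory(spec, [event])
        integ = integrate_deviation(twist_map(traj))
        expected = 13.0 * n_event_frames * 50e-6
        assert integ.value.max() == pytest.approx(expected, rel=1e-6)

    def test_additive_over_disjoint_intervals(self):
        rng = np.random.default_rng(1)
        delta = rng.normal(0, 5, size=(2, 200))
        whole = integrate_deviation(self._map(delta)).value
        first = np.sum(np.abs(delta[:, :120]), axis=1) * 50e-6
        second = np.sum(np.abs(delta[:, 120:]), axis=1) * 50e-6
        np.testing.assert_allclose(whole, first + second, rtol=1e-12)

    def test_non_uniform_spacing_rejected(self):
        tm = self._map(np.zeros((1, 5)))
        tm.frame_times = np.array([0.0, 50.0, 100.0, 200.0, 250.0])
        with pytest.raises(SpecValidationError):
            integrate_deviation(tm)


class TestRMSF:
    def test_static_trajectory_zero(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=5))
        prof = rmsf(traj)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_isotropic_noise_gives_sigma_sqrt3(self):
        sigma = 0.3
        traj = generate_helix_trajectory(
            HelixSpec(n_residues=30, n_frames=2000, noise_sigma=sigma, seed=9)
        )
        prof = rmsf(traj)
        assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_loop_more_mobile_than_core(self, loop_flip_ensemble):
        traj = loop_flip_ensemble[0]
        prof = rmsf(traj, "name CA", "resid 1:50")
        core = prof.rmsf[prof.residue_ids <= 50]
        loop = prof.rmsf[prof.residue_ids > 50]
        assert loop.mean() > core.mean()

    def test_single_frame_rejected(self):
        traj = generate_helix_trajectory(HelixSpec(n_residues=10, n_frames=1))
        with pytest.raises(SpecValidationError):
            rmsf(traj)
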