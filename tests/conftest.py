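"""Shared fixtures: small synthetic systems with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from helixgate.synthgen import (
    EngagementSpec,
    HelixSpec,
    LoopFlipSpec,
    UnwindEvent,
    generate_engagement_trajectory,
    generate_helix_trajectory,
    generate_loop_flip_ensemble,
)


@pytest.fixture(scope="session")
def ideal_helix_spec() -> HelixSpec:
    return HelixSpec(n_residues=30, n_frames=1)


@pytest.fixture(scope="session")
def event_trajectory():
    """400-frame noiseless helix with one unwinding event (87° at residues
    10-12, frames 100-299)."""
    spec = HelixSpec(n_residues=30, n_frames=400, noise_sigma=0.0, seed=11)
    event = UnwindEvent(residue_span=(10, 12), event_twist=87.0, start_frame=100, end_frame=299)
    return generate_helix_trajectory(spec, [event]), event


@pytest.fixture(scope="session")
def loop_flip_ensemble():
    """Three replicas, 50-residue rigid core + 10-residue loop flipped 8 Å in
    half the frames, σ = 0.3 Å."""
    spec = LoopFlipSpec(
        core_size=50,
        loop_size=10,
        flip_displacement=8.0,
        state_schedule=tuple([0, 1] * 150),
        noise_sigma=0.3,
        seed=5,
    )
    return generate_loop_flip_ensemble(spec, n_replicas=3)


@pytest.fixture(scope="session")
def engagement_trajectory():
    """Half-engaged schedule (500 engaged / 500 disengaged-in-site frames)."""
    schedule = tuple(["engaged"] * 500 + ["disengaged_in_site"] * 500)
    spec = EngagementSpec(motif_residues=(11, 12, 13), engagement_schedule=schedule, seed=3)
    return generate_engagement_trajectory(spec, HelixSpec(n_residues=30))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
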