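"""Shared fixtures: small synthetic stimulus sets and epoch configurations."""

import numpy as np
import pytest

from facesim.similarity import category_model_matrix
from facesim.simulate import FaceSetSpec, MegSimSpec, generate_face_set


@pytest.fixture()
def rng():
    """Fresh deterministic stream per test: results never depend on test
    execution order."""
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale face set: 2 identities x 3 expressions, 30 landmarks."""
    return FaceSetSpec(
        n_identities=2,
        n_expressions=3,
        n_landmarks=30,
        n_interior=23,
        n_features=4,
        n_frames=12,
        frame_rate=6.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_faceset(small_spec):
    return generate_face_set(small_spec)


@pytest.fixture(scope="session")
def full_size_faceset():
    """Full-scale counts (36 videos, 179 landmarks, 56 frames)."""
    return generate_face_set(FaceSetSpec(seed=11))


@pytest.fixture(scope="session")
def grid_ids():
    """12 stimuli on a 3-identity x 4-expression grid with labels."""
    ids = tuple(sorted(f"id{i}_e{j}" for i in range(3) for j in range(4)))
    identities = tuple(s.split("_")[0] for s in ids)
    expressions = tuple(s.split("_")[1] for s in ids)
    return ids, identities, expressions


@pytest.fixture(scope="session")
def identity_model(grid_ids):
    ids, identities, expressions = grid_ids
    return category_model_matrix(ids, identities, identities, expressions)


@pytest.fixture(scope="session")
def tiny_meg_spec(identity_model):
    """Fast epoch simulation with a strongly planted identity geometry."""
    return MegSimSpec(
        n_participants=4,
        n_channels=24,
        presentations_per_run=2,
        n_runs=2,
        sfreq=100.0,
        tmin_ms=-500.0,
        tmax_ms=1500.0,
        planted_model=identity_model,
        planted_window_ms=(400.0, 1200.0),
        planted_freqs_hz=(6.0, 20.0),
        effect_size=3.0,
        noise_sd=0.5,
        seed=3,
    )
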