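import numpy as np
import pytest

from mousemal import (
    CohortConfig,
    build_stimulus_set,
    default_profiles,
    generate_cohort,
)
from mousemal.cli import extract_cohort_features
from mousemal.kinematics import N_FRAMES, StandardTrajectory
from mousemal.synthgen import GROUP_LABELS


def make_standard(waypoints, frame_indices=None, it_ms=0.0, rt_ms=1000.0, mirrored=False):
    """Build a 101-frame StandardTrajectory through waypoints.

    Waypoints are placed at the given frame indices (default: spread
    evenly) and intermediate frames are linearly interpolated, so polyline
    vertices are exactly represented.
    """
    pts = np.asarray(waypoints, dtype=float)
    if frame_indices is None:
        frame_indices = np.linspace(0, N_FRAMES - 1, len(pts))
    frame_indices = np.asarray(frame_indices, dtype=float)
    grid = np.arange(N_FRAMES, dtype=float)
    fx = np.interp(grid, frame_indices, pts[:, 0])
    fy = np.interp(grid, frame_indices, pts[:, 1])
    return StandardTrajectory(fx, fy, it_ms=it_ms, rt_ms=rt_ms, mirrored=mirrored)


@pytest.fixture(scope="session")
def stimulus_set():
    return build_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohort(stimulus_set, profiles):
    """8 participants per group, shared across tests."""
    cfg = CohortConfig(n_per_group={g: 8 for g in GROUP_LABELS}, seed=11)
    return generate_cohort(cfg, profiles, stimulus_set)


@pytest.fixture(scope="session")
def small_features(small_cohort, stimulus_set):
    return extract_cohort_features(small_cohort, stimulus_set)
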