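"""Kinematics tests: standardization, time normalization and the metric
oracles (analytic point-to-line distance, shoelace area, flip enumeration)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mousemal.kinematics import (
    DEFAULT_GEOMETRY,
    N_FRAMES,
    RawTrajectory,
    StandardTrajectory,
    area_under_curve,
    average_trajectory,
    flips,
    frame_kinematics,
    initiation_time,
    max_deviation,
    remap,
    standardize,
    time_normalize,
    trial_features,
)

from conftest import make_standard


def _raw_to_box_center(side="left", idle_ms=0.0):
    geo = DEFAULT_GEOMETRY
    sx, sy = geo.start
    cx, cy = geo.box_left_center if side == "left" else geo.box_right_center
    t, x, y = [0.0], [sx], [sy]
    if idle_ms > 0:
        t, x, y = [0.0, idle_ms], [sx, sx], [sy, sy]
    t = t + [t[-1] + 500.0, t[-1] + 1000.0]
    x = x + [(sx + cx) / 2.0, cx]
    y = y + [(sy + cy) / 2.0, cy]
    return RawTrajectory("q", np.array(t), np.array(x), np.array(y), True, side)


def test_remap_box_center_maps_to_minus1_15():
    st_ = standardize(_raw_to_box_center("left"))
    assert st_.frames_x[-1] == pytest.approx(-1.0)
    assert st_.frames_y[-1] == pytest.approx(1.5)


def test_remap_straight_segment():
    xn, yn, mirrored = remap(_raw_to_box_center("left"))
    assert not mirrored
    assert xn[0] == pytest.approx(0.0) and yn[0] == pytest.approx(0.0)
    assert xn[-1] == pytest.approx(-1.0) and yn[-1] == pytest.approx(1.5)


def test_mirror_invariance_of_features():
    """A right-box trial that mirrors a left-box twin yields identical features."""
    geo = DEFAULT_GEOMETRY
    left = _raw_to_box_center("left")
    sx = geo.start[0]
    right = RawTrajectory(
        "q", left.t_ms.copy(), 2 * sx - left.x_px, left.y_px.copy(), False, "right"
    )
    fl = trial_features(left)
    fr = trial_features(right)
    for attr in ("md", "auc", "x_flip", "y_flip", "v_x", "v_y", "rt_ms", "it_ms"):
        assert getattr(fl, attr) == pytest.approx(getattr(fr, attr), abs=1e-9)


def test_time_normalize_identity_on_uniform_101():
    t = np.linspace(0, 2000, N_FRAMES)
    x = np.linspace(0, -1, N_FRAMES)
    y = np.linspace(0, 1.5, N_FRAMES)
    out = time_normalize(t, x, y, it_ms=0.0, rt_ms=2000.0)
    np.testing.assert_allclose(out.frames_x, x, atol=1e-12)
    np.testing.assert_allclose(out.frames_y, y, atol=1e-12)


def test_time_normalize_linear_interpolation_closed_form():
    t = np.array([0.0, 100.0, 200.0])
    x = np.array([0.0, -0.5, -1.0])
    y = np.array([0.0, 0.75, 1.5])
    out = time_normalize(t, x, y, 0.0, 200.0)
    assert len(out.frames_x) == N_FRAMES
    assert out.frames_x[50] == pytest.approx(-0.5)
    assert out.frames_y[50] == pytest.approx(0.75)


def test_time_normalize_rejects_single_sample():
    with pytest.raises(ValueError):
        time_normalize(np.array([0.0]), np.array([0.0]), np.array([0.0]), 0, 0)


@settings(deadline=None, max_examples=30)
@given(st.data())
def test_time_normalize_always_101_frames_and_endpoints(data):
    n = data.draw(st.integers(2, 40))
    dt = data.draw(st.lists(st.floats(1.0, 100.0), min_size=n - 1, max_size=n - 1))
    t = np.concatenate([[0.0], np.cumsum(dt)])
    x = np.array(data.draw(st.lists(st.floats(-2, 2), min_size=n, max_size=n)))
    y = np.array(data.draw(st.lists(st.floats(-2, 2), min_size=n, max_size=n)))
    out = time_normalize(t, x, y, 0.0, float(t[-1]))
    assert len(out.frames_x) == N_FRAMES
    assert out.frames_x[0] == pytest.approx(x[0])
    assert out.frames_x[-1] == pytest.approx(x[-1])
    assert out.frames_y[-1] == pytest.approx(y[-1])


def test_initiation_time_immediate_and_delayed():
    moving = _raw_to_box_center("left")
    it, moved = initiation_time(moving)
    assert moved and it == 0.0
    idle = _raw_to_box_center("left", idle_ms=500.0)
    it, moved = initiation_time(idle)
    assert moved and it == 500.0


def test_initiation_time_no_movement_flag():
    r = RawTrajectory(
        "q",
        np.array([0.0, 100.0, 200.0]),
        np.array([960.0, 960.0, 960.0]),
        np.array([150.0, 150.0, 150.0]),
        True,
        "left",
    )
    it, moved = initiation_time(r)
    assert not moved and it == 200.0


def test_max_deviation_straight_path_zero():
    st_ = make_standard([(0, 0), (-1, 1.5)])
    md, _ = max_deviation(st_)
    assert md == pytest.approx(0.0, abs=1e-12)


def test_max_deviation_analytic_oracle():
    """Deviation of (0,1) from the line through (0,0),(-1,1.5) is 1/sqrt(3.25)."""
    st_ = make_standard([(0, 0), (0, 1), (-1, 1.5)], frame_indices=[0, 50, 100])
    md, _ = max_deviation(st_)
    assert md == pytest.approx(1.0 / np.sqrt(3.25), abs=1e-10)


def test_md_time_frame_to_clock_mapping():
    """Peak at frame 50 of a 4000 ms movement starting at question onset -> 2000 ms."""
    st_ = make_standard(
        [(0, 0), (0, 1), (-1, 1.5)], frame_indices=[0, 50, 100], it_ms=0.0, rt_ms=4000.0
    )
    _, md_time = max_deviation(st_)
    assert md_time == pytest.approx(2000.0)


def test_md_time_includes_initiation_time():
    st_ = make_standard(
        [(0, 0), (0, 1), (-1, 1.5)], frame_indices=[0, 50, 100], it_ms=500.0, rt_ms=4500.0
    )
    _, md_time = max_deviation(st_)
    assert md_time == pytest.approx(2500.0)


def test_max_deviation_rejects_degenerate_line():
    frames = np.zeros(N_FRAMES)
    st_ = StandardTrajectory(frames, frames.copy(), 0.0, 1000.0, False)
    with pytest.raises(ValueError):
        max_deviation(st_)


def _brute_force_signed_dev(st_):
    x, y = st_.frames_x, st_.frames_y
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    e = p1 - p0
    out = []
    for xi, yi in zip(x, y):
        v = np.array([xi, yi]) - p0
        out.append((v[0] * e[1] - v[1] * e[0]) / np.linalg.norm(e))
    return np.array(out)


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_max_deviation_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    x = np.concatenate([[0.0], rng.normal(0, 0.5, N_FRAMES - 2), [-1.0]])
    y = np.concatenate([[0.0], rng.normal(0.7, 0.5, N_FRAMES - 2), [1.5]])
    st_ = StandardTrajectory(x, y, 0.0, 1000.0, False)
    md, _ = max_deviation(st_)
    dev = _brute_force_signed_dev(st_)
    assert abs(md) == pytest.approx(np.max(np.abs(dev)), abs=1e-10)


def test_auc_straight_zero_and_triangle():
    assert area_under_curve(make_standard([(0, 0), (-1, 1.5)])) == pytest.approx(0.0, abs=1e-12)
    tri = make_standard([(0, 0), (0, 1.5), (-1, 1.5)], frame_indices=[0, 50, 100])
    assert area_under_curve(tri) == pytest.approx(0.75, abs=1e-10)


def test_auc_mirror_and_translation_invariance():
    rng = np.random.default_rng(4)
    x = np.concatenate([[0.0], np.sort(rng.uniform(-1, 0, N_FRAMES - 2))[::-1], [-1.0]])
    y = np.linspace(0, 1.5, N_FRAMES) + np.concatenate([[0], rng.normal(0, 0.05, 99), [0]])
    st_a = StandardTrajectory(x, y, 0, 1000, False)
    st_shift = StandardTrajectory(x + 3.0, y - 2.0, 0, 1000, False)
    assert area_under_curve(st_a) == pytest.approx(area_under_curve(st_shift), abs=1e-10)
    md_a, _ = max_deviation(st_a)
    md_s, _ = max_deviation(st_shift)
    assert md_a == pytest.approx(md_s, abs=1e-10)
    # mirroring about x=0 flips the sign of both metrics
    st_m = StandardTrajectory(-x, y, 0, 1000, False)
    assert area_under_curve(st_m) == pytest.approx(-area_under_curve(st_a), abs=1e-10)
    md_m, _ = max_deviation(st_m)
    assert md_m == pytest.approx(-md_a, abs=1e-10)


def _path_from_increments(incs):
    coords = np.concatenate([[0.0], np.cumsum(incs)])
    pad = np.full(N_FRAMES - len(coords), coords[-1])
    x = np.concatenate([coords, pad])
    y = np.linspace(0, 1.5, N_FRAMES)
    return StandardTrajectory(x, y, 0, 1000, False)


def test_flips_enumeration_cases():
    assert flips(make_standard([(0, 0), (-1, 1.5)]), "x") == 0
    assert flips(_path_from_increments([-1, 1, -1, 1, -1]), "x") == 4
    assert flips(_path_from_increments([-1, 0, 1]), "x") == 1  # zeros skipped


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_flips_match_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.choice([-1.0, 0.0, 1.0], size=N_FRAMES).cumsum()
    st_ = StandardTrajectory(x, np.linspace(0, 1.5, N_FRAMES), 0, 1000, False)
    inc = np.diff(x)
    signs = [s for s in np.sign(inc) if s != 0]
    expected = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    assert flips(st_, "x") == expected


def test_frame_kinematics_closed_forms():
    st_ = make_standard([(0, 0), (-1, 1.5)])
    vx, vy, ax, ay = frame_kinematics(st_)
    assert vy == pytest.approx(1.5 / 100)
    assert vx == pytest.approx(-1.0 / 100)
    assert ax == pytest.approx(0.0, abs=1e-12)
    assert ay == pytest.approx(0.0, abs=1e-12)


def test_average_trajectory_properties():
    a = make_standard([(0, 0), (-1, 1.5)])
    b = make_standard([(0, 0), (1, 1.5)])
    mx, my = average_trajectory([a])
    np.testing.assert_allclose(mx, a.frames_x)
    mx, _ = average_trajectory([a, b])
    np.testing.assert_allclose(mx, 0.0, atol=1e-12)
    mx, my = average_trajectory([a, a, a])
    np.testing.assert_allclose(mx, a.frames_x)
    with pytest.raises(ValueError):
        average_trajectory([])
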