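"""Trajectory standardization and per-trial kinematic metrics.

Raw mouse paths (time in ms, pixel coordinates) are mapped into the
standard tracker space — start button at the origin, response-box centers
at (−1, 1.5) and (1, 1.5), y increasing toward the boxes — mirrored so
every standardized trial moves leftward, and resampled to 101 time frames
by linear interpolation over the movement interval.

From the standardized path the classic trajectory metrics are computed:
initiation time (IT), reaction time (RT), maximum deviation (MD) and its
time (MD-time), geometric area between path and ideal line (AUC),
direction reversals per axis (x-flip / y-flip), and mean per-frame
velocity/acceleration per axis. MD and AUC are signed, positive toward the
non-chosen response side, so a net attraction toward the rejected
alternative shows up as a positive group mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "DEFAULT_GEOMETRY",
    "RawTrajectory",
    "StandardTrajectory",
    "TrialFeatures",
    "N_FRAMES",
    "remap",
    "time_normalize",
    "standardize",
    "initiation_time",
    "max_deviation",
    "area_under_curve",
    "flips",
    "frame_kinematics",
    "trial_features",
    "average_trajectory",
]

#: number of time-normalized frames per trial
N_FRAMES = 101

#: normalized coordinates of the response-box centers (left box; right is mirrored)
BOX_CENTER_NORM = (-1.0, 1.5)


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel layout of the task screen (y increases upward).

    ``box_left``/``box_right`` are (x_min, y_min, x_max, y_max) rectangles.
    """

    width: float = 1920.0
    height: float = 1080.0
    start: tuple[float, float] = (960.0, 150.0)
    box_left: tuple[float, float, float, float] = (100.0, 540.0, 420.0, 760.0)
    box_right: tuple[float, float, float, float] = (1500.0, 540.0, 1820.0, 760.0)

    @property
    def box_left_center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box_left
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    @property
    def box_right_center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box_right
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def validate(self) -> None:
        lx, ly = self.box_left_center
        rx, ry = self.box_right_center
        sx, sy = self.start
        if abs(rx - sx) < 1e-9 or abs(lx - sx) < 1e-9 or abs(ly - sy) < 1e-9:
            raise ValueError("response boxes must be offset from the start point")

    def to_normalized(self, x_px, y_px, side: str):
        """Map pixel coordinates to standard space, mirroring right-side trials."""
        sx, sy = self.start
        cx, cy = self.box_left_center if side == "left" else self.box_right_center
        xn = (np.asarray(x_px, dtype=float) - sx) / abs(cx - sx)
        yn = (np.asarray(y_px, dtype=float) - sy) / (cy - sy) * BOX_CENTER_NORM[1]
        if side == "right":
            xn = -xn
        return xn, yn

    def from_normalized(self, x_n, y_n, side: str):
        """Inverse of :meth:`to_normalized` (used by the synthetic generator)."""
        sx, sy = self.start
        cx, cy = self.box_left_center if side == "left" else self.box_right_center
        xn = -np.asarray(x_n, dtype=float) if side == "right" else np.asarray(x_n, dtype=float)
        x_px = sx + xn * abs(cx - sx)
        y_px = sy + np.asarray(y_n, dtype=float) / BOX_CENTER_NORM[1] * (cy - sy)
        return x_px, y_px


DEFAULT_GEOMETRY = ScreenGeometry()


@dataclass
class RawTrajectory:
    """One trial's raw mouse log: strictly increasing times, pixel coords."""

    question_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    response: bool  # True = yes
    response_side: str  # "left" | "right"

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.t_ms) == len(self.x_px) == len(self.y_px)):
            raise ValueError("t/x/y must have equal length")
        if len(self.t_ms) and (np.any(np.diff(self.t_ms) <= 0) or self.t_ms[0] != 0):
            raise ValueError("timestamps must start at 0 and be strictly increasing")


@dataclass
class StandardTrajectory:
    """Time-normalized path: 101 frames in standard space, plus trial timing."""

    frames_x: np.ndarray
    frames_y: np.ndarray
    it_ms: float
    rt_ms: float
    mirrored: bool

    def __post_init__(self):
        if len(self.frames_x) != N_FRAMES or len(self.frames_y) != N_FRAMES:
            raise ValueError(f"standard trajectory must have {N_FRAMES} frames")


@dataclass
class TrialFeatures:
    """The per-trial metric vector."""

    it_ms: float
    rt_ms: float
    md_time_ms: float
    md: float
    auc: float
    x_flip: int
    y_flip: int
    v_x: float
    v_y: float
    a_x: float
    a_y: float


def remap(raw: RawTrajectory, geometry: ScreenGeometry = DEFAULT_GEOMETRY):
    """Map a raw path to standard space (mirrored rightward trials).

    Returns (x_norm, y_norm, mirrored). Samples outside the screen are
    clamped with a warning.
    """
    geometry.validate()
    x, y = raw.x_px, raw.y_px
    if (
        np.any(x < 0)
        or np.any(x > geometry.width)
        or np.any(y < 0)
        or np.any(y > geometry.height)
    ):
        warnings.warn("trajectory samples outside screen bounds were clamped")
        x = np.clip(x, 0, geometry.width)
        y = np.clip(y, 0, geometry.height)
    xn, yn = geometry.to_normalized(x, y, raw.response_side)
    return xn, yn, raw.response_side == "right"


def initiation_time(raw: RawTrajectory, epsilon_px: float = 0.0) -> tuple[float, bool]:
    """Movement onset time in ms.

    Onset is the timestamp of the last sample before cumulative displacement
    from the start first exceeds ``epsilon_px`` (i.e., when the movement
    began). Returns (it_ms, moved); if the path never exceeds the threshold
    the total duration is returned with ``moved=False``.
    """
    dx = raw.x_px - raw.x_px[0]
    dy = raw.y_px - raw.y_px[0]
    disp = np.hypot(dx, dy)
    over = np.nonzero(disp > epsilon_px)[0]
    if len(over) == 0:
        return float(raw.t_ms[-1]), False
    first = over[0]
    return float(raw.t_ms[max(first - 1, 0)]), True


def time_normalize(
    t_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    it_ms: float,
    rt_ms: float,
    mirrored: bool = False,
) -> StandardTrajectory:
    """Resample a path to 101 frames equally spaced over [onset, click]."""
    t_ms = np.asarray(t_ms, dtype=float)
    if len(t_ms) < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    grid = np.linspace(it_ms, rt_ms, N_FRAMES)
    fx = np.interp(grid, t_ms, np.asarray(x, dtype=float))
    fy = np.interp(grid, t_ms, np.asarray(y, dtype=float))
    return StandardTrajectory(fx, fy, it_ms=it_ms, rt_ms=rt_ms, mirrored=mirrored)


def standardize(
    raw: RawTrajectory,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    epsilon_px: float = 0.0,
) -> StandardTrajectory:
    """remap + onset detection + time normalization in one call."""
    xn, yn, mirrored = remap(raw, geometry)
    it, _ = initiation_time(raw, epsilon_px)
    return time_normalize(raw.t_ms, xn, yn, it, float(raw.t_ms[-1]), mirrored)


def _chord_deviation(st: StandardTrajectory) -> np.ndarray:
    """Signed perpendicular distance of every frame from the start→end line.

    Positive toward the non-chosen side (+x half-plane for standardized,
    leftward-moving paths).
    """
    x, y = st.frames_x, st.frames_y
    ex, ey = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(ex, ey)
    if norm < 1e-12:
        raise ValueError("degenerate trajectory: start equals end")
    # cross product (P - P0) x (E - P0); sign fixed so +x deviation is positive
    cross = (x - x[0]) * ey - (y - y[0]) * ex
    return cross / norm


def max_deviation(st: StandardTrajectory) -> tuple[float, float]:
    """Signed maximum deviation and the time (question-onset clock) it occurs.

    The reported md is the signed distance of the frame farthest from the
    ideal line; md_time includes initiation time, consistent with RT's clock.
    """
    d = _chord_deviation(st)
    i = int(np.argmax(np.abs(d)))
    md = float(d[i])
    md_time = st.it_ms + (st.rt_ms - st.it_ms) * i / (N_FRAMES - 1)
    return md, float(md_time)


def area_under_curve(st: StandardTrajectory) -> float:
    """Signed shoelace area between the path and the straight start→end line.

    Equivalent to the polygon area of path + reversed ideal segment; positive
    toward the non-chosen side.
    """
    d = _chord_deviation(st)
    x, y = st.frames_x, st.frames_y
    ex, ey = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(ex, ey)
    # projection of each frame onto the chord
    t = ((x - x[0]) * ex + (y - y[0]) * ey) / norm
    return float(np.trapezoid(d, t))


def flips(st: StandardTrajectory, axis: str) -> int:
    """Direction reversals along an axis: sign changes of successive nonzero
    per-frame increments (zero increments are skipped)."""
    coords = st.frames_x if axis == "x" else st.frames_y
    inc = np.diff(coords)
    signs = np.sign(inc)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def frame_kinematics(st: StandardTrajectory) -> tuple[float, float, float, float]:
    """Signed mean per-frame velocity and acceleration per axis.

    v = X_n − X_{n−1} (100 values per axis), a = v_n − v_{n−1} (99 values);
    returns (v_x, v_y, a_x, a_y) as their means.
    """
    vx = np.diff(st.frames_x)
    vy = np.diff(st.frames_y)
    ax = np.diff(vx)
    ay = np.diff(vy)
    return float(vx.mean()), float(vy.mean()), float(ax.mean()), float(ay.mean())


def trial_features(
    raw: RawTrajectory,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    epsilon_px: float = 0.0,
    absolute_va: bool = False,
) -> TrialFeatures:
    """Compute the full per-trial metric vector from a raw trajectory.

    ``absolute_va`` switches v/a means to absolute values.
    """
    st = standardize(raw, geometry, epsilon_px)
    md, md_time = max_deviation(st)
    auc = area_under_curve(st)
    vx, vy, axm, aym = frame_kinematics(st)
    if absolute_va:
        vx, vy, axm, aym = abs(vx), abs(vy), abs(axm), abs(aym)
    return TrialFeatures(
        it_ms=st.it_ms,
        rt_ms=st.rt_ms,
        md_time_ms=md_time,
        md=md,
        auc=auc,
        x_flip=flips(st, "x"),
        y_flip=flips(st, "y"),
        v_x=vx,
        v_y=vy,
        a_x=axm,
        a_y=aym,
    )


def average_trajectory(paths: list[StandardTrajectory]) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean path of a group of standardized trajectories."""
    if not paths:
        raise ValueError("cannot average an empty group of trajectories")
    mx = np.mean([p.frames_x for p in paths], axis=0)
    my = np.mean([p.frames_y for p in paths], axis=0)
    return mx, my
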