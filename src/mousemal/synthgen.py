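"""Seeded synthetic cohorts: symptom endorsements and raw mouse trajectories.

Three experimental conditions are emulated: honest healthy responders
(truth-tellers), healthy responders instructed to feign depression (liars),
and genuinely depressed patients. Each group is described by a
:class:`GroupProfile` whose kinematic parameters are the published group
means/SDs (reaction time, initiation time, maximum deviation, area under
curve, flip counts, maximum-deviation time as a fraction of movement time)
and whose per-category endorsement probabilities reproduce the published
pairwise endorsement differences: liars over-endorse both typical and
atypical symptoms, depressed patients endorse an intermediate number but
respond slowest, and truth-tellers endorse almost nothing.

Trajectory model
----------------
A trial is built directly in the standardized 101-frame space and then
emitted as a raw pixel log whose linear re-interpolation reproduces those
frames exactly (sample times include the frame breakpoints). In chord
coordinates (t = progress along the straight start→click line, d = signed
perpendicular deviation):

* initiation and reaction times are lognormal with the configured
  mean/SD; the path idles at the start until IT;
* the deviation profile rises to its (drawn) maximum ``A`` at the drawn
  peak frame, giving the MD and MD-time targets exactly;
* the progress profile is a "double swing": an approach sweep at sustained
  deviation, a partial return near the chord, and a second sweep to the
  click. The return length is solved in closed form so the shoelace area
  equals the drawn AUC target (the published AUC/MD ratios exceed what a
  single smooth bump can produce);
* direction reversals are topped up to the drawn per-axis flip targets by
  inserting small, isolated counter-movements away from the deviation peak.

Only the extracted-feature statistics of this construction are
contractual; the shape itself is a stylized stand-in for real movements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import BOX_CENTER_NORM, DEFAULT_GEOMETRY, N_FRAMES, RawTrajectory, ScreenGeometry
from .protocol import (
    CONTROL_CATEGORIES,
    DEFAULT_COUNTS,
    SYMPTOM_CATEGORIES,
    StimulusSet,
    build_stimulus_set,
    truthful_answer,
)

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "SyntheticParticipant",
    "GROUP_LABELS",
    "default_profiles",
    "synth_trajectory",
    "sample_participant",
    "generate_cohort",
    "default_train_config",
    "default_test_config",
]

GROUP_LABELS = ("truth_teller", "depressed", "liar")

#: default stimulus item counts per symptom category (for probability anchors)
_N_ITEMS = DEFAULT_COUNTS


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one experimental condition."""

    label: str
    endorse_prob: dict[str, float]  # category -> P(yes) on symptom items
    rt_mean: float  # ms
    rt_sd: float
    it_mean: float  # ms
    it_sd: float
    mdtime_frac_mean: float  # peak position as fraction of movement time
    mdtime_frac_sd: float
    md_mean: float  # normalized units (signed amplitude)
    md_sd: float
    auc_mean: float  # normalized shoelace area
    auc_ratio_sd: float  # SD of the per-trial AUC/MD ratio draw
    flip_rate_x: float  # expected direction changes per trial
    flip_sd_x: float
    flip_rate_y: float
    flip_sd_y: float
    error_prob_controls: float  # P(wrong answer) per control item
    click_x_mean: float = -0.85  # normalized click point (left-side trials)
    click_x_sd: float = 0.08
    click_y_mean: float = 1.326
    click_y_sd: float = 0.015

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.endorse_prob.values()):
            raise ValueError("endorsement probabilities must lie in [0, 1]")
        if not 0.0 <= self.error_prob_controls <= 1.0:
            raise ValueError("error_prob_controls must lie in [0, 1]")
        if self.rt_mean <= self.it_mean or self.it_mean < 0:
            raise ValueError("require rt_mean > it_mean >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, seed and acquisition parameters."""

    n_per_group: dict[str, int]
    seed: int = 0
    sampling_rate_hz: float = 70.0
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be non-negative")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.geometry.validate()


@dataclass
class SyntheticParticipant:
    participant_id: str
    label: str
    responses: dict[str, bool]
    trajectories: dict[str, RawTrajectory]


def _endorsement_targets() -> dict[str, dict[str, float]]:
    """Mean endorsed-count targets per group and category.

    Truth-teller anchors (DS=1.0, 2DS-c=1.5, VAS=0.5, 2DS-d=6.0,
    DS&EX-c=0.5, DS&EX-d=0.5); the other groups follow from the published
    pairwise differences (liars endorse 7.75 more DS, 11.85 more 2DS-c and
    6.80 more VAS items than truth-tellers; depressed 5.30, 6.85 and 3.95
    more; 2DS-d runs the opposite way: truth-tellers 5.25 and 3.10 above
    liars and depressed).
    """
    tt = {"DS": 1.0, "2DS-c": 1.5, "VAS": 0.5, "2DS-d": 6.0, "DS&EX-c": 0.5, "DS&EX-d": 0.5}
    liar = {
        "DS": tt["DS"] + 7.75,
        "2DS-c": tt["2DS-c"] + 11.85,
        "VAS": tt["VAS"] + 6.80,
        "2DS-d": tt["2DS-d"] - 5.25,
        "DS&EX-c": tt["DS&EX-c"] + 2.40,
        "DS&EX-d": tt["DS&EX-d"],
    }
    dep = {
        "DS": tt["DS"] + 5.30,
        "2DS-c": tt["2DS-c"] + 6.85,
        "VAS": tt["VAS"] + 3.95,
        "2DS-d": tt["2DS-d"] - 3.10,
        "DS&EX-c": tt["DS&EX-c"] + 2.20,
        "DS&EX-d": tt["DS&EX-d"],
    }
    return {"truth_teller": tt, "depressed": dep, "liar": liar}


def _probs(targets: dict[str, float]) -> dict[str, float]:
    return {c: min(max(targets[c] / _N_ITEMS[c], 0.0), 1.0) for c in targets}


def default_profiles() -> dict[str, GroupProfile]:
    """Profiles calibrated to the published group statistics.

    Kinematic targets are the published means/SDs (RT 4018.79 / 6641.81 /
    4030.60 ms for truth-teller / depressed / liar, MD 0.44 / 0.51 / 0.57,
    AUC 1.01 / 1.09 / 1.25, x-flip 7.64 / 8.75 / 9.23, ...). The
    maximum-deviation-time fraction is derived so that IT + frac × (RT −
    IT) equals the published MD-time mean (2392.37 / 4199.85 / 2297.64 ms).
    """
    targets = _endorsement_targets()

    def frac(mdt, it, rt):
        return (mdt - it) / (rt - it)

    common = dict(mdtime_frac_sd=0.05, click_x_sd=0.08, click_y_sd=0.015)
    profiles = {
        "truth_teller": GroupProfile(
            label="truth_teller",
            endorse_prob=_probs(targets["truth_teller"]),
            rt_mean=4018.79, rt_sd=1466.98,
            it_mean=620.35, it_sd=491.94,
            mdtime_frac_mean=frac(2392.37, 620.35, 4018.79),
            md_mean=0.44, md_sd=0.31,
            auc_mean=1.01, auc_ratio_sd=0.15,
            flip_rate_x=7.64, flip_sd_x=2.24,
            flip_rate_y=7.74, flip_sd_y=2.63,
            error_prob_controls=0.13,
            click_x_mean=-0.85, click_y_mean=1.326,
            **common,
        ),
        "depressed": GroupProfile(
            label="depressed",
            endorse_prob=_probs(targets["depressed"]),
            rt_mean=6641.81, rt_sd=3204.22,
            it_mean=408.67, it_sd=332.99,
            mdtime_frac_mean=frac(4199.85, 408.67, 6641.81),
            md_mean=0.51, md_sd=0.30,
            auc_mean=1.09, auc_ratio_sd=0.15,
            flip_rate_x=8.75, flip_sd_x=2.94,
            flip_rate_y=8.05, flip_sd_y=2.88,
            error_prob_controls=0.04,
            click_x_mean=-0.85, click_y_mean=1.315,
            **common,
        ),
        "liar": GroupProfile(
            label="liar",
            endorse_prob=_probs(targets["liar"]),
            rt_mean=4030.60, rt_sd=1203.67,
            it_mean=559.57, it_sd=399.84,
            mdtime_frac_mean=frac(2297.64, 559.57, 4030.60),
            md_mean=0.57, md_sd=0.24,
            auc_mean=1.25, auc_ratio_sd=0.15,
            flip_rate_x=9.23, flip_sd_x=2.72,
            flip_rate_y=9.20, flip_sd_y=2.67,
            error_prob_controls=0.09,
            click_x_mean=-0.85, click_y_mean=1.326,
            **common,
        ),
    }
    return profiles


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

_MIN_MOVEMENT_MS = 200.0


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a lognormal parameterized by its mean and SD."""
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _deviation_shape(i_peak: int, j1: int, j2: int) -> np.ndarray:
    """Relative deviation profile s (s[i_peak] = 1, unique maximum)."""
    i = np.arange(N_FRAMES, dtype=float)
    s = np.zeros(N_FRAMES)
    plateau, valley, h2 = 0.86, 0.02, 0.84

    rise_len = min(8, max(i_peak - 1, 1))
    sel = i <= i_peak
    s[sel] = plateau * _smoothstep(i[sel] / rise_len)
    # fall from plateau to valley over (i_peak, j1]
    sel = (i > i_peak) & (i <= j1)
    s[sel] = valley + (plateau - valley) * (1.0 - _smoothstep((i[sel] - i_peak) / max(j1 - i_peak, 1)))
    sel = (i > j1) & (i <= j2)
    s[sel] = valley
    # second sweep hump: valley -> h2 -> 0 at the final frame
    sel = i > j2
    leg = i[sel] - j2
    leg_len = max(N_FRAMES - 1 - j2, 1)
    tri = np.sin(np.pi * leg / leg_len)  # 0 -> 1 -> 0
    s[sel] = valley * (1.0 - leg / leg_len) + (h2 - valley) * tri
    # narrow dome making the global maximum unique at i_peak
    s += (1.0 - plateau) * np.exp(-(((i - i_peak) / 4.0) ** 2))
    s[0] = 0.0
    s[-1] = 0.0
    s[i_peak] = 1.0
    return s


def _progress_shape(chord_len: float, backtrack: float, j1: int, j2: int) -> np.ndarray:
    """Progress t along the chord: 0 → L, back to L−B, forward to L."""
    i = np.arange(N_FRAMES, dtype=float)
    t = np.empty(N_FRAMES)
    sel = i <= j1
    t[sel] = chord_len * _smoothstep(i[sel] / max(j1, 1))
    sel = (i > j1) & (i <= j2)
    t[sel] = chord_len - backtrack * _smoothstep((i[sel] - j1) / max(j2 - j1, 1))
    sel = i > j2
    t[sel] = chord_len - backtrack + backtrack * _smoothstep((i[sel] - j2) / max(N_FRAMES - 1 - j2, 1))
    return t


def _count_flips(coords: np.ndarray) -> int:
    inc = np.diff(coords)
    signs = np.sign(inc)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def _insert_blips(
    coords: np.ndarray, n_blips: int, forbidden: np.ndarray, rng: np.random.Generator
) -> int:
    """Insert up to ``n_blips`` isolated counter-movements; returns how many.

    Each blip displaces one interior frame against the local direction of
    motion, creating an isolated −/+ increment pattern (two reversals).
    Candidate frames have same-sign nonzero increments on both sides, lie
    outside ``forbidden`` and are spaced so blips do not interact. Blip
    amplitude is kept small so deviation/area targets are not disturbed.
    """
    if n_blips <= 0:
        return 0
    inc = np.diff(coords)
    sg = np.sign(inc)
    candidates = [
        j
        for j in range(2, N_FRAMES - 2)
        if sg[j - 1] != 0 and sg[j - 1] == sg[j] == sg[j + 1] and not forbidden[j]
    ]
    rng.shuffle(candidates)
    used: list[int] = []
    for j in candidates:
        if len(used) >= n_blips:
            break
        if any(abs(j - u) < 3 for u in used):
            continue
        sigma = sg[j]
        delta = float(np.clip(abs(inc[j]) * 0.6, 0.004, 0.012))
        coords[j] = coords[j - 1] - sigma * delta
        used.append(j)
    return len(used)


def _top_up_flips(
    coords: np.ndarray, target: int, forbidden: np.ndarray, rng: np.random.Generator
) -> None:
    """Raise the axis flip count toward ``target`` by inserting blips.

    Blips add two reversals each; an odd residual of one is added with
    probability 1/2 so the expected count is unbiased.
    """
    for _ in range(4):
        need = target - _count_flips(coords)
        if need < 2:
            break
        if _insert_blips(coords, need // 2, forbidden, rng) == 0:
            break
    if target - _count_flips(coords) == 1 and rng.random() < 0.5:
        _insert_blips(coords, 1, forbidden, rng)


def synth_trajectory(
    profile: GroupProfile,
    target_side: str,
    rng: np.random.Generator,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    sampling_rate_hz: float = 70.0,
    question_id: str = "q",
    response: bool = True,
) -> RawTrajectory:
    """Synthesize one raw trial toward the given response box."""
    geometry.validate()
    if target_side not in ("left", "right"):
        raise ValueError("target_side must be 'left' or 'right'")

    it = _lognormal(rng, profile.it_mean, profile.it_sd)
    rt = _lognormal(rng, profile.rt_mean, profile.rt_sd)
    for _ in range(100):
        if rt >= it + _MIN_MOVEMENT_MS:
            break
        rt = _lognormal(rng, profile.rt_mean, profile.rt_sd)
    else:
        rt = it + _MIN_MOVEMENT_MS
    mt = rt - it

    # click point (normalized, left-side convention), clipped into the box
    bw = (geometry.box_left[2] - geometry.box_left[0]) / 2.0
    bh = (geometry.box_left[3] - geometry.box_left[1]) / 2.0
    sx = abs(geometry.box_left_center[0] - geometry.start[0])
    sy = geometry.box_left_center[1] - geometry.start[1]
    half_w = bw / sx  # box half-extent in normalized units
    half_h = bh / sy * BOX_CENTER_NORM[1]
    cx = float(np.clip(rng.normal(profile.click_x_mean, profile.click_x_sd), -1.0 - half_w, -1.0 + half_w))
    cy = float(np.clip(rng.normal(profile.click_y_mean, profile.click_y_sd), 1.5 - half_h, 1.5 + half_h))
    chord = np.array([cx, cy])
    L = float(np.hypot(cx, cy))
    u_hat = chord / L
    n_hat = np.array([u_hat[1], -u_hat[0]])  # +x half-plane: non-chosen side

    # amplitude, area target, peak frame
    amp = float(rng.normal(profile.md_mean, profile.md_sd))
    ratio = profile.auc_mean / profile.md_mean if profile.md_mean > 0 else 0.0
    area_target = amp * float(rng.normal(ratio, profile.auc_ratio_sd)) if ratio else 0.0
    frac = float(np.clip(rng.normal(profile.mdtime_frac_mean, profile.mdtime_frac_sd), 0.1, 0.9))
    i_peak = int(np.clip(round(frac * (N_FRAMES - 1)), 5, 92))
    j1 = i_peak + max(int(round(0.25 * (N_FRAMES - 1 - i_peak))), 2)
    j2 = j1 + max(int(round(0.20 * (N_FRAMES - 1 - i_peak))), 2)
    j2 = min(j2, 97)

    s = _deviation_shape(i_peak, j1, j2)
    d = amp * s

    # solve the backtrack length so the shoelace area hits the target;
    # area(B) is linear in B for fixed shapes
    t0 = _progress_shape(L, 0.0, j1, j2)
    t1 = _progress_shape(L, 1.0, j1, j2)
    area0 = float(np.trapezoid(d, t0))
    slope = float(np.trapezoid(d, t1)) - area0
    if abs(slope) > 1e-9:
        backtrack = float(np.clip((area_target - area0) / slope, 0.0, 0.92 * L))
    else:
        backtrack = 0.0
    t = _progress_shape(L, backtrack, j1, j2)

    x = t * u_hat[0] + d * n_hat[0]
    y = t * u_hat[1] + d * n_hat[1]

    # top up direction reversals to the drawn per-axis targets
    forbidden = np.zeros(N_FRAMES, dtype=bool)
    forbidden[max(i_peak - 6, 0) : i_peak + 7] = True
    for coords, rate, sd in (
        (x, profile.flip_rate_x, profile.flip_sd_x),
        (y, profile.flip_rate_y, profile.flip_sd_y),
    ):
        k = int(np.round(rng.normal(rate, sd)))
        _top_up_flips(coords, k, forbidden, rng)

    # mirror right-side trials and map to pixels
    frame_t = it + np.arange(N_FRAMES) * (mt / (N_FRAMES - 1))
    x_px, y_px = geometry.from_normalized(x, y, target_side)

    # raw sample times: idle grid during IT, then the union of the frame
    # breakpoints and the tracker sampling grid (positions lie on the
    # piecewise-linear frame path, so re-interpolation is exact)
    dt = 1000.0 / sampling_rate_hz
    idle = np.arange(0.0, it, dt)
    move_grid = np.arange(it + dt, rt, dt)
    times = np.concatenate([idle, [it], move_grid, frame_t, [rt]])
    # quantize to 0.01 ms so serialized logs survive any float parser
    times = np.unique(np.round(times, 2))
    times = times[(times >= 0) & (times <= round(rt, 2))]
    xs = np.interp(times, frame_t, x_px, left=x_px[0])
    ys = np.interp(times, frame_t, y_px, left=y_px[0])
    xs = np.round(xs, 1)
    ys = np.round(ys, 1)
    return RawTrajectory(
        question_id=question_id,
        t_ms=times,
        x_px=xs,
        y_px=ys,
        response=response,
        response_side=target_side,
    )


# ---------------------------------------------------------------------------
# participants and cohorts
# ---------------------------------------------------------------------------


def _draw_response(profile: GroupProfile, question, rng: np.random.Generator) -> bool:
    code = question.category.code
    if code in CONTROL_CATEGORIES:
        key = truthful_answer(question, depressed=False)
        return key if rng.random() >= profile.error_prob_controls else not key
    p = profile.endorse_prob.get(code, 0.0)
    return bool(rng.random() < p)


def sample_participant(
    profile: GroupProfile,
    stimulus_set: StimulusSet,
    rng: np.random.Generator,
    participant_id: str = "p0",
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    sampling_rate_hz: float = 70.0,
) -> SyntheticParticipant:
    """Draw one participant: responses per question plus a trajectory each.

    Truth-tellers and depressed patients answer symptom items at their
    (low/intermediate) endorsement rates and controls per the key with
    ``error_prob_controls`` noise; the liar profile's elevated endorsement
    probabilities implement over-endorsement of typical, atypical and
    discordant content. Responses map yes→left box, no→right box.
    """
    responses: dict[str, bool] = {}
    trajectories: dict[str, RawTrajectory] = {}
    for q in stimulus_set:
        resp = _draw_response(profile, q, rng)
        side = "left" if resp else "right"
        responses[q.id] = resp
        trajectories[q.id] = synth_trajectory(
            profile,
            side,
            rng,
            geometry=geometry,
            sampling_rate_hz=sampling_rate_hz,
            question_id=q.id,
            response=resp,
        )
    return SyntheticParticipant(
        participant_id=participant_id,
        label=profile.label,
        responses=responses,
        trajectories=trajectories,
    )


def generate_cohort(
    config: CohortConfig,
    profiles: dict[str, GroupProfile] | None = None,
    stimulus_set: StimulusSet | None = None,
    id_prefix: str = "",
) -> list[SyntheticParticipant]:
    """Generate a seeded cohort; deterministic for a fixed (config, seed).

    ``id_prefix`` namespaces participant ids (e.g. to keep train and test
    cohorts disjoint).
    """
    if profiles is None:
        profiles = default_profiles()
    if stimulus_set is None:
        stimulus_set = build_stimulus_set(seed=config.seed)
    root = np.random.SeedSequence(config.seed)
    participants: list[SyntheticParticipant] = []
    idx = 0
    for label in GROUP_LABELS:
        n = config.n_per_group.get(label, 0)
        for k in range(n):
            rng = np.random.default_rng(root.spawn(1)[0])
            participants.append(
                sample_participant(
                    profiles[label],
                    stimulus_set,
                    rng,
                    participant_id=f"{id_prefix}{label}-{k + 1:03d}",
                    geometry=config.geometry,
                    sampling_rate_hz=config.sampling_rate_hz,
                )
            )
            idx += 1
    return participants


def default_train_config(seed: int = 0) -> CohortConfig:
    """The model-building cohort: 20 per group, 60 participants."""
    return CohortConfig(n_per_group={g: 20 for g in GROUP_LABELS}, seed=seed)


def default_test_config(seed: int = 1) -> CohortConfig:
    """The held-out generalization cohort: 9 per group, 27 participants."""
    return CohortConfig(n_per_group={g: 9 for g in GROUP_LABELS}, seed=seed)


def cohort_manifest(config: CohortConfig, profiles: dict[str, GroupProfile]) -> str:
    """JSON manifest of the generating parameters."""
    return json.dumps(
        {
            "seed": config.seed,
            "sampling_rate_hz": config.sampling_rate_hz,
            "n_per_group": config.n_per_group,
            "profiles": {
                label: {
                    k: (v if not isinstance(v, dict) else dict(v))
                    for k, v in vars(p).items()
                }
                for label, p in profiles.items()
            },
        },
        indent=2,
    )
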