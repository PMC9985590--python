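"""Synthetic sit-to-stand recordings and cohorts with known ground truth.

The trajectory generator drives a 2D linked-segment chain (foot anchored at
the ankle, shank, thigh, trunk, head) through scripted sit-stand cycles
using raised-cosine joint-angle profiles, whose derivatives are available in
closed form; that gives exact oracles for total test time, cycle count,
peak trunk angle and peak trunk angular acceleration.  The chain is
projected to image pixels with a single horizontal foreshortening factor
standing in for the 45-degree recording obliquity (a deliberate
simplification of true perspective), and all 25 pose landmarks are emitted
-- non-modelled ones (eyes, ears, arms, far side) as anatomically plausible
rigid offsets so the format contract holds.

The scripted peak trunk lean is specified *in the camera projection plane*:
the generator inverts the foreshortening when posing the trunk (world lean
= atan(tan(lean) / k)), so the scripted value is exactly the angle a 2D
analysis should measure.

The cohort generator draws survey covariates and target test times from a
Gaussian copula with planted correlations, and maps each participant to a
motion script whose ground-truth parameters realise the plant (e.g. an
osteoarthritis trunk-lean shift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import KeypointSeries
from .landmarks import LEFT_RIGHT_PAIRS, N_LANDMARKS, LandmarkID


@dataclass
class SkeletonSpec:
    """Segment lengths (subject-height units) and camera geometry.

    obliquity_deg is the camera's horizontal angle off the sagittal plane
    (45 by protocol); it enters as a cos(obliquity) foreshortening of
    horizontal world coordinates.  scale_px converts height units to
    pixels; the rendered subject must fit inside image_width_px x
    image_height_px.
    """

    foot: float = 0.15
    shank: float = 0.25
    thigh: float = 0.25
    trunk: float = 0.30
    neck_to_nose: float = 0.10
    ankle_height: float = 0.05
    obliquity_deg: float = 45.0
    scale_px: float = 520.0
    image_width_px: float = 720.0
    image_height_px: float = 1280.0

    def __post_init__(self) -> None:
        for name in ("foot", "shank", "thigh", "trunk", "neck_to_nose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name} must be positive")
        total = self.ankle_height + self.shank + self.thigh + self.trunk + self.neck_to_nose
        if total * self.scale_px > self.image_height_px:
            raise ValueError("subject does not fit inside the image frame")

    @property
    def foreshortening(self) -> float:
        return float(np.cos(np.radians(self.obliquity_deg)))


@dataclass
class MotionScript:
    """Timing and posture targets for one five-repetition test.

    Each cycle is seated dwell -> rise -> standing dwell -> descent; the
    recording ends with a final seated dwell.  peak_trunk_lean_deg is the
    projection-plane trunk lean reached mid-rise (and mid-descent).
    """

    n_cycles: int = 5
    rise_s: float = 0.8
    descent_s: float = 0.8
    dwell_stand_s: float = 0.35
    dwell_sit_s: float = 0.35
    peak_trunk_lean_deg: float = 20.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("rise_s", "descent_s", "dwell_stand_s", "dwell_sit_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.peak_trunk_lean_deg < 90):
            raise ValueError("peak_trunk_lean_deg must lie in [0, 90)")

    @property
    def period_s(self) -> float:
        return self.dwell_sit_s + self.rise_s + self.dwell_stand_s + self.descent_s

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.period_s + self.dwell_sit_s

    @classmethod
    def from_total_time(cls, total_time_s: float, n_cycles: int = 5,
                        peak_trunk_lean_deg: float = 20.0,
                        fps: float = 30.0) -> "MotionScript":
        """Script whose ground-truth (uncorrected) total time hits a target.

        Total time spans the first to last standing positions, i.e.
        (n_cycles - 1) full periods; the period is solved accordingly with
        the default 35/15/35/15% rise/dwell/descent/dwell split.
        """
        if n_cycles < 2:
            raise ValueError("need >= 2 cycles for a defined total time")
        period = total_time_s / (n_cycles - 1)
        return cls(n_cycles=n_cycles, rise_s=0.35 * period,
                   descent_s=0.35 * period, dwell_stand_s=0.15 * period,
                   dwell_sit_s=0.15 * period,
                   peak_trunk_lean_deg=peak_trunk_lean_deg, fps=fps)


@dataclass
class NoiseSpec:
    """Measurement corruption emulating pose-estimator output.

    jitter_px: SD of additive Gaussian keypoint noise; dropout_prob: per
    frame probability of a whole-pose detection failure; runs are capped at
    max_dropout_run frames (failures are isolated single frames in
    practice); facing "left" renders the recording as if the subject's left
    side were nearest the camera (x reflected, bilateral labels swapped).
    """

    jitter_px: float = 0.0
    dropout_prob: float = 0.0
    max_dropout_run: int = 1
    facing: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.facing not in ("left", "right"):
            raise ValueError("facing must be 'left' or 'right'")


@dataclass
class GroundTruth:
    """Analytic truth for one simulated recording."""

    total_time_s: float
    n_cycles: int
    peak_trunk_angle_deg: float
    peak_trunk_acc_deg_s2: float
    standing_times_s: np.ndarray
    sitting_times_s: np.ndarray
    period_s: float


def _pose_phase(t: np.ndarray, script: MotionScript) -> tuple[np.ndarray, np.ndarray]:
    """Sit(0)-to-stand(1) phase s(t) and its rise/descent time-within-phase.

    Returns (s, tau) where tau is NaN outside transitions (dwells).
    """
    P = script.period_s
    tc = np.mod(t, P)
    in_last_tail = t >= script.n_cycles * P  # final seated dwell
    s = np.zeros_like(t)
    tau = np.full_like(t, np.nan)

    t0 = script.dwell_sit_s
    t1 = t0 + script.rise_s
    t2 = t1 + script.dwell_stand_s
    t3 = t2 + script.descent_s  # == P

    rising = (tc >= t0) & (tc < t1) & ~in_last_tail
    standing = (tc >= t1) & (tc < t2) & ~in_last_tail
    descending = (tc >= t2) & (tc < t3) & ~in_last_tail

    s[rising] = 0.5 * (1 - np.cos(np.pi * (tc[rising] - t0) / script.rise_s))
    s[standing] = 1.0
    s[descending] = 0.5 * (1 + np.cos(np.pi * (tc[descending] - t2) / script.descent_s))
    tau[rising] = tc[rising] - t0
    return s, tau


def trunk_lean_profile(s: np.ndarray, peak_deg: float) -> np.ndarray:
    """Projection-plane trunk lean (deg) as a function of pose phase."""
    return peak_deg * np.sin(np.pi * np.asarray(s))


def _trunk_lean_acc(tau: np.ndarray, script: MotionScript) -> np.ndarray:
    """Closed-form second time-derivative of the lean during a rise.

    With s(tau) = (1 - cos(w tau)) / 2, w = pi / rise_s, the lean is
    m = L sin(u), u = pi s; then m'' = L (cos(u) u'' - sin(u) u'^2).
    """
    L = script.peak_trunk_lean_deg
    w = np.pi / script.rise_s
    u = 0.5 * np.pi * (1 - np.cos(w * tau))
    du = 0.5 * np.pi * w * np.sin(w * tau)
    ddu = 0.5 * np.pi * w**2 * np.cos(w * tau)
    return L * (np.cos(u) * ddu - np.sin(u) * du**2)


def simulate_sts(
    skeleton: SkeletonSpec | None = None,
    script: MotionScript | None = None,
) -> tuple[KeypointSeries, GroundTruth]:
    """Render a noiseless rightward-facing recording plus its ground truth."""
    skeleton = skeleton or SkeletonSpec()
    script = script or MotionScript()
    fps = script.fps
    n_frames = int(round(script.duration_s * fps)) + 1
    t = np.arange(n_frames) / fps
    s, _ = _pose_phase(t, script)

    k = skeleton.foreshortening
    lean_proj = np.radians(trunk_lean_profile(s, script.peak_trunk_lean_deg))
    lean_world = np.arctan2(np.tan(lean_proj), k)

    # world chain, y up, facing +x
    ankle = np.column_stack([np.zeros_like(t),
                             np.full_like(t, skeleton.ankle_height)])
    knee = ankle + np.column_stack([np.zeros_like(t),
                                    np.full_like(t, skeleton.shank)])
    phi = np.radians(90.0 * (1.0 - s))  # thigh angle from vertical
    hip = knee + skeleton.thigh * np.column_stack([-np.sin(phi), np.cos(phi)])
    trunk_dir = np.column_stack([np.sin(lean_world), np.cos(lean_world)])
    neck = hip + skeleton.trunk * trunk_dir
    nose = neck + skeleton.neck_to_nose * trunk_dir

    big_toe = np.column_stack([np.full_like(t, skeleton.foot),
                               np.full_like(t, 0.02)])
    small_toe = big_toe + [-0.02, 0.0]
    heel = np.column_stack([np.full_like(t, -0.04), np.full_like(t, 0.02)])

    world = np.zeros((n_frames, N_LANDMARKS, 2))
    lateral = np.array([0.04, 0.01])  # far-side offset after projection

    def put(lm: LandmarkID, pts: np.ndarray) -> None:
        world[:, int(lm), :] = pts

    put(LandmarkID.NOSE, nose)
    put(LandmarkID.NECK, neck)
    put(LandmarkID.MID_HIP, hip + lateral / 2)
    put(LandmarkID.RIGHT_HIP, hip)
    put(LandmarkID.LEFT_HIP, hip + lateral)
    put(LandmarkID.RIGHT_KNEE, knee)
    put(LandmarkID.LEFT_KNEE, knee + lateral)
    put(LandmarkID.RIGHT_ANKLE, ankle)
    put(LandmarkID.LEFT_ANKLE, ankle + lateral)
    put(LandmarkID.RIGHT_BIG_TOE, big_toe)
    put(LandmarkID.LEFT_BIG_TOE, big_toe + lateral)
    put(LandmarkID.RIGHT_SMALL_TOE, small_toe)
    put(LandmarkID.LEFT_SMALL_TOE, small_toe + lateral)
    put(LandmarkID.RIGHT_HEEL, heel)
    put(LandmarkID.LEFT_HEEL, heel + lateral)
    shoulder_off = 0.02 * np.column_stack([trunk_dir[:, 1], -trunk_dir[:, 0]])
    put(LandmarkID.RIGHT_SHOULDER, neck + shoulder_off)
    put(LandmarkID.LEFT_SHOULDER, neck - shoulder_off + lateral)
    # arms folded across the chest
    chest = hip + 0.7 * skeleton.trunk * trunk_dir
    put(LandmarkID.RIGHT_ELBOW, chest + [0.06, 0.0])
    put(LandmarkID.LEFT_ELBOW, chest + [0.06, 0.0] + lateral)
    put(LandmarkID.RIGHT_WRIST, chest + [0.02, 0.02])
    put(LandmarkID.LEFT_WRIST, chest + [0.02, 0.02] + lateral)
    head_up = 0.03 * trunk_dir
    put(LandmarkID.RIGHT_EYE, nose + head_up + [-0.01, 0.0])
    put(LandmarkID.LEFT_EYE, nose + head_up + [-0.01, 0.0] + lateral / 2)
    put(LandmarkID.RIGHT_EAR, nose + head_up + [-0.05, -0.01])
    put(LandmarkID.LEFT_EAR, nose + head_up + [-0.05, -0.01] + lateral / 2)

    cx = skeleton.image_width_px * 0.45
    y0 = skeleton.image_height_px * 0.9
    xy = np.empty_like(world)
    xy[..., 0] = cx + skeleton.scale_px * k * world[..., 0]
    xy[..., 1] = y0 - skeleton.scale_px * world[..., 1]
    if (xy[..., 0].min() < 0 or xy[..., 0].max() > skeleton.image_width_px
            or xy[..., 1].min() < 0 or xy[..., 1].max() > skeleton.image_height_px):
        raise ValueError("rendered motion leaves the image frame; reduce scale_px")

    conf = np.full((n_frames, N_LANDMARKS), 0.9)
    series = KeypointSeries(xy=xy, confidence=conf, fps=fps,
                            source_id="synthetic")

    P = script.period_s
    stand_centers = (script.dwell_sit_s + script.rise_s
                     + script.dwell_stand_s / 2 + P * np.arange(script.n_cycles))
    sit_centers = script.dwell_sit_s / 2 + P * np.arange(script.n_cycles + 1)
    tau_dense = np.linspace(0, script.rise_s, 2001)
    acc_dense = _trunk_lean_acc(tau_dense, script)
    truth = GroundTruth(
        total_time_s=float(stand_centers[-1] - stand_centers[0]),
        n_cycles=script.n_cycles,
        peak_trunk_angle_deg=script.peak_trunk_lean_deg,
        peak_trunk_acc_deg_s2=float(acc_dense.max()),
        standing_times_s=stand_centers,
        sitting_times_s=sit_centers,
        period_s=P,
    )
    return series, truth


def corrupt(series: KeypointSeries, noise: NoiseSpec) -> KeypointSeries:
    """Apply facing, jitter and dropout corruption; reproducible from seed."""
    rng = np.random.default_rng(noise.seed)
    xy = series.xy.copy()
    conf = series.confidence.copy()

    if noise.facing == "left":
        axis = (xy[..., 0].min() + xy[..., 0].max()) / 2.0
        xy[..., 0] = 2.0 * axis - xy[..., 0]
        for right, left in LEFT_RIGHT_PAIRS:
            xy[:, [int(right), int(left)], :] = xy[:, [int(left), int(right)], :]

    if noise.jitter_px > 0:
        xy += rng.normal(0.0, noise.jitter_px, size=xy.shape)

    if noise.dropout_prob > 0:
        T = len(xy)
        i = 0
        while i < T:
            if rng.random() < noise.dropout_prob:
                run = int(rng.integers(1, noise.max_dropout_run + 1))
                stop = min(i + run, T)
                xy[i:stop] = 0.0
                conf[i:stop] = 0.0
                i = stop + 1  # keep dropouts isolated
            else:
                i += 1

    return KeypointSeries(xy=xy, confidence=conf, fps=series.fps,
                          source_id=series.source_id,
                          n_detections=series.n_detections)


def write_openpose_dir(series: KeypointSeries, path: str | Path) -> None:
    """Write a series as per-frame OpenPose-layout JSON files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for frame in series.frames():
        people = []
        if frame.confidence.max() > 0:
            people.append({"pose_keypoints_2d": [round(v, 3) for v in frame.to_flat()]})
        payload = {"version": 1.3, "people": people}
        with open(path / f"frame_{frame.frame_index:06d}_keypoints.json", "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortSpec:
    """Population model for a synthetic study cohort.

    Covariates are drawn from a Gaussian copula whose latent correlation
    matrix carries the planted effects (binary variables by thresholding at
    the target prevalence); marginal locations and scales follow the study
    population (age 37.3 +/- 17.8 truncated to [18, 96], test time
    11.4 +/- 3.4 s in [4.3, 32.9], PROMIS scores on the T-score scale).
    Osteoarthritis adds a trunk-lean shift (default +5.8 deg, the observed
    group difference), and race/ethnicity groups may carry their own lean
    shifts.  A fraction of participants is marked excluded-on-review, with
    a mildly sex-dependent rate so the balance table has signal.
    """

    n: int = 405
    seed: int = 0
    planted_corr: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("age", "time"): 0.35,
        ("bmi", "time"): 0.20,
        ("gph", "time"): -0.20,
        ("age", "oa"): 0.30,
    })
    female_prop: float = 0.53
    oa_prevalence: float = 0.15
    race_props: dict[str, float] = field(default_factory=lambda: {
        "white": 0.60, "asian": 0.25, "black": 0.09, "hispanic": 0.06,
    })
    base_lean_mean_deg: float = 17.0
    base_lean_sd_deg: float = 4.0
    oa_lean_shift_deg: float = 5.8
    race_lean_shift_deg: dict[str, float] = field(default_factory=lambda: {
        "white": 0.0, "asian": 4.0, "black": 1.0, "hispanic": 1.0,
    })
    exclusion_rate_female: float = 0.20
    exclusion_rate_male: float = 0.13
    fps: float = 30.0

    _VARS = ("age", "sex", "bmi", "gph", "gmh", "oa", "time")

    def latent_correlation(self) -> np.ndarray:
        v = self._VARS
        R = np.eye(len(v))
        for (a, b), rho in self.planted_corr.items():
            if a not in v or b not in v:
                raise ValueError(f"unknown variables in planted pair ({a}, {b})")
            i, j = v.index(a), v.index(b)
            R[i, j] = R[j, i] = rho
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ValueError(
                f"planted correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
        return R


def simulate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[pd.DataFrame, dict[str, MotionScript], pd.DataFrame]:
    """Draw a cohort table, per-participant motion scripts, and truth table.

    Returns (cohort, scripts, truth): ``cohort`` follows the cohort CSV
    schema; ``scripts`` maps participant_id to the MotionScript realising
    that participant's target test time and trunk lean; ``truth`` records
    the planted per-participant ground-truth parameters.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    R = spec.latent_correlation()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    z = rng.standard_normal((spec.n, len(R))) @ L.T
    cols = dict(zip(spec._VARS, z.T))

    age = np.clip(37.3 + 17.8 * cols["age"], 18.0, 96.0)
    sex = np.where(cols["sex"] < sps.norm.ppf(spec.female_prop), "female", "male")
    bmi = np.clip(26.6 + 5.5 * cols["bmi"], 16.0, 55.0)
    gph = 50.0 + 10.0 * cols["gph"]
    gmh = 50.0 + 10.0 * cols["gmh"]
    oa = (cols["oa"] < sps.norm.ppf(spec.oa_prevalence)).astype(int)
    time = np.clip(11.4 + 3.4 * cols["time"], 4.3, 32.9)

    races = list(spec.race_props)
    probs = np.array([spec.race_props[r] for r in races], dtype=float)
    probs = probs / probs.sum()
    race = rng.choice(races, size=spec.n, p=probs)

    lean = np.clip(
        rng.normal(spec.base_lean_mean_deg, spec.base_lean_sd_deg, size=spec.n)
        + spec.oa_lean_shift_deg * oa
        + np.array([spec.race_lean_shift_deg.get(r, 0.0) for r in race]),
        3.0, 45.0,
    )

    p_excl = np.where(sex == "female", spec.exclusion_rate_female,
                      spec.exclusion_rate_male)
    excluded = rng.random(spec.n) < p_excl
    flags = np.where(excluded, "manual_review", "")

    ids = [f"P{i:04d}" for i in range(spec.n)]
    cohort = pd.DataFrame({
        "participant_id": ids,
        "age": np.round(age, 1),
        "sex": sex,
        "bmi": np.round(bmi, 1),
        "race_ethnicity": race,
        "gph": np.round(gph, 1),
        "gmh": np.round(gmh, 1),
        "oa_diagnosis": oa,
        "exclusion_flags": flags,
    })

    scripts = {
        pid: MotionScript.from_total_time(
            float(tt), peak_trunk_lean_deg=float(pl), fps=spec.fps)
        for pid, tt, pl in zip(ids, time, lean)
    }
    truth = pd.DataFrame({
        "participant_id": ids,
        "true_total_time_s": time,
        "true_max_trunk_angle_deg": lean,
        "excluded": excluded,
    })
    return cohort, scripts, truth
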