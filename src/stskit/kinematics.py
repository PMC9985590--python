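"""2D joint and trunk kinematics in the camera projection plane.

Joint angles are interior angles at a vertex landmark: knee from
ankle-knee-hip, hip from knee-hip-neck, ankle from first
metatarsal-ankle-knee, computed bilaterally.  The trunk angle is measured
between an upward vertical through the right hip and the right-hip-to-neck
vector, so 0 deg is perfectly upright and larger values mean more forward
or lateral lean in the 2D projection ("right" is the camera-near side after
orientation standardisation).  Angular velocities and accelerations use
first differences scaled by the sampling rate (i.e. divided by the frame
period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkID
from .preprocess import CleanSeries
from .segment import Segmentation


class KinematicsError(ValueError):
    pass


@dataclass
class AngleSeries:
    """Per-frame angle in degrees for one joint (or the trunk)."""

    angle_deg: np.ndarray
    joint: str           # knee | hip | ankle | trunk
    side: str            # left | right | n/a
    fps: float


@dataclass
class DerivativeSeries:
    """Discrete derivative of an angle trace.

    ``value[i]`` is the derivative aligned to source frame
    ``i + order`` (the later frame of each difference); ``frame_offset``
    records that alignment.
    """

    value: np.ndarray
    order: int
    fps: float

    @property
    def frame_offset(self) -> int:
        return self.order


def three_point_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at vertex ``b`` of the 2D triangle a-b-c, degrees.

    Accepts single points (shape (2,)) or stacked frames ((T, 2)).  Frames
    with a zero-length limb vector yield NaN.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cosang = np.where((nu == 0) | (nv == 0), np.nan, cosang)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang[0] if ang.shape == (1,) else ang


_JOINT_TRIPLES = {
    ("knee", "right"): (LandmarkID.RIGHT_ANKLE, LandmarkID.RIGHT_KNEE, LandmarkID.RIGHT_HIP),
    ("knee", "left"): (LandmarkID.LEFT_ANKLE, LandmarkID.LEFT_KNEE, LandmarkID.LEFT_HIP),
    ("hip", "right"): (LandmarkID.RIGHT_KNEE, LandmarkID.RIGHT_HIP, LandmarkID.NECK),
    ("hip", "left"): (LandmarkID.LEFT_KNEE, LandmarkID.LEFT_HIP, LandmarkID.NECK),
    ("ankle", "right"): (LandmarkID.RIGHT_BIG_TOE, LandmarkID.RIGHT_ANKLE, LandmarkID.RIGHT_KNEE),
    ("ankle", "left"): (LandmarkID.LEFT_BIG_TOE, LandmarkID.LEFT_ANKLE, LandmarkID.LEFT_KNEE),
}


def joint_angle_series(series: CleanSeries, joint: str, side: str) -> AngleSeries:
    """Per-frame interior angle of one joint over the recording."""
    try:
        la, lb, lc = _JOINT_TRIPLES[(joint, side)]
    except KeyError:
        raise KinematicsError(f"unknown joint/side {(joint, side)!r}") from None
    ang = three_point_angle(series.trace(la), series.trace(lb), series.trace(lc))
    return AngleSeries(angle_deg=np.atleast_1d(ang), joint=joint, side=side,
                       fps=series.fps)


def trunk_angle(series: CleanSeries) -> AngleSeries:
    """Trunk lean: angle between vertical-up at the right hip and hip->neck."""
    hip = series.trace(LandmarkID.RIGHT_HIP)
    neck = series.trace(LandmarkID.NECK)
    v = neck - hip
    up = np.zeros_like(v)
    up[:, 1] = 1.0
    ang = three_point_angle(hip + up, hip, neck)
    n_bad = int(np.sum(~np.isfinite(ang)))
    if n_bad:
        series.qc.degenerate_angle_frames += n_bad
    return AngleSeries(angle_deg=np.atleast_1d(ang), joint="trunk", side="n/a",
                       fps=series.fps)


def differentiate(values: np.ndarray, fps: float, order: int = 1) -> DerivativeSeries:
    """Discrete derivative of given order, scaled by the sampling rate.

    Each application takes a first difference and divides by the frame
    period (equivalently multiplies by fps); the output shrinks by one
    sample per order and aligns to the later frame of each difference.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D series")
    if len(values) < order + 1:
        raise KinematicsError(
            f"series of length {len(values)} too short for order-{order} derivative"
        )
    out = values
    for _ in range(order):
        out = np.diff(out) * fps
    return DerivativeSeries(value=out, order=order, fps=fps)


def forward_trunk_angular_acceleration(trunk: AngleSeries) -> DerivativeSeries:
    """Second derivative of the trunk angle, deg/s^2.

    Positive values are acceleration in the direction of increasing lean
    ("forward" after orientation standardisation); per-phase maxima are
    taken over the positive part.
    """
    return differentiate(trunk.angle_deg, trunk.fps, order=2)


@dataclass
class STSParameters:
    """Per-recording kinematic summary.

    max_trunk_angle_deg and max_trunk_ang_acc_deg_s2 are per-STS-phase
    maxima averaged across however many cycles were detected;
    max_trunk_angle_global_deg is the secondary whole-test maximum.  Joint
    extrema are per-phase-kind min/max of the right-side interior angles.
    """

    total_time_s: float
    n_cycles: int
    corrected: bool
    max_trunk_angle_deg: float
    max_trunk_ang_acc_deg_s2: float
    max_trunk_angle_global_deg: float
    joint_extrema: dict[str, float] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "total_time_s": self.total_time_s,
            "n_cycles": self.n_cycles,
            "corrected": self.corrected,
            "max_trunk_angle_deg": self.max_trunk_angle_deg,
            "max_trunk_ang_acc_deg_s2": self.max_trunk_ang_acc_deg_s2,
            "max_trunk_angle_global_deg": self.max_trunk_angle_global_deg,
        }
        out.update(self.joint_extrema)
        return out


def _phase_slice(phase, n_frames: int, offset: int = 0) -> slice:
    # derivative frames at phase boundaries belong to the phase containing
    # the later sample: a derivative aligned to frame f is inside
    # (start, end] of the source-frame interval
    start = max(phase.start_frame + 1 - offset, 0)
    stop = min(phase.end_frame + 1 - offset, n_frames)
    return slice(start, stop)


def extract_parameters(series: CleanSeries, seg: Segmentation) -> STSParameters:
    """Aggregate kinematics over the segmented STS cycles."""
    sts_phases = [p for p in seg.phases if p.kind == "sit_to_stand"]
    if not sts_phases:
        raise KinematicsError("no sit-to-stand phases to summarise")

    trunk = trunk_angle(series)
    acc = forward_trunk_angular_acceleration(trunk)

    per_phase_max_angle = []
    per_phase_max_acc = []
    for p in sts_phases:
        ang = trunk.angle_deg[p.start_frame:p.end_frame + 1]
        per_phase_max_angle.append(np.nanmax(ang))
        a = acc.value[_phase_slice(p, len(acc.value), offset=acc.frame_offset)]
        pos = a[a > 0]
        per_phase_max_acc.append(pos.max() if pos.size else 0.0)

    joint_extrema: dict[str, float] = {}
    for joint in ("knee", "hip", "ankle"):
        ang = joint_angle_series(series, joint, "right").angle_deg
        for kind, phases in (("sts", sts_phases),
                             ("stand_to_sit", [p for p in seg.phases
                                               if p.kind == "stand_to_sit"])):
            if not phases:
                continue
            mins, maxs = [], []
            for p in phases:
                seg_ang = ang[p.start_frame:p.end_frame + 1]
                if np.all(np.isnan(seg_ang)):
                    continue
                mins.append(np.nanmin(seg_ang))
                maxs.append(np.nanmax(seg_ang))
            if mins:
                joint_extrema[f"{joint}_{kind}_min_deg"] = float(np.mean(mins))
                joint_extrema[f"{joint}_{kind}_max_deg"] = float(np.mean(maxs))

    return STSParameters(
        total_time_s=seg.total_time_s,
        n_cycles=seg.n_cycles_detected,
        corrected=seg.corrected,
        max_trunk_angle_deg=float(np.mean(per_phase_max_angle)),
        max_trunk_ang_acc_deg_s2=float(np.mean(per_phase_max_acc)),
        max_trunk_angle_global_deg=float(np.nanmax(trunk.angle_deg)),
        joint_extrema=joint_extrema,
        qc=series.qc.to_dict(),
    )
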