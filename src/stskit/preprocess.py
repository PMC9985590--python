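"""Trajectory cleaning: gap filling, zero-lag low-pass filtering,
orientation standardisation and height normalisation.

Pose-estimation output carries isolated missing frames (<1% in practice) and
high-frequency low-magnitude jitter.  The cleaning chain is, in order:

1. mark keypoints with confidence at or below a threshold as missing;
2. fill gaps by per-coordinate linear interpolation (edges by nearest value);
3. flip to an up-positive vertical axis (y_up = -y_image), so standing
   produces literal maxima of the nose trace;
4. low-pass filter every coordinate with a zero-lag (forward-backward)
   fifth-order Butterworth design, 6 Hz cutoff;
5. mirror horizontally when the subject faces the image-left, so downstream
   analysis always sees a rightward-facing subject with the camera-near side
   labelled "right";
6. divide all coordinates by the subject's height in pixels, approximated as
   the 95th percentile of the per-frame right-ankle-to-nose distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import KeypointSeries
from .landmarks import LEFT_RIGHT_PAIRS, N_LANDMARKS, LandmarkID


class ConfigurationError(ValueError):
    """Raised when a preprocessing configuration is unusable for the data."""


class DataError(ValueError):
    """Raised when a recording cannot be cleaned (e.g. no usable landmarks)."""


#: Landmarks that must be detected somewhere in the recording for the
#: standard analysis to proceed.
REQUIRED_LANDMARKS = (
    LandmarkID.NOSE,
    LandmarkID.NECK,
    LandmarkID.RIGHT_HIP,
    LandmarkID.RIGHT_ANKLE,
)


@dataclass
class PreprocessConfig:
    """Tunable cleaning parameters.

    cutoff_hz / filter_order define the Butterworth design (defaults 6 Hz,
    order 5); max_gap_frames is the longest gap considered routine (longer
    gaps are still filled but flagged for review); mirror_policy is
    ``auto`` (detect facing), ``force`` (always mirror) or ``off``.
    """

    cutoff_hz: float = 6.0
    filter_order: int = 5
    max_gap_frames: int = 3
    missing_conf_threshold: float = 0.0
    mirror_policy: str = "auto"
    normalize: bool = True
    facing_epsilon_px: float = 0.5

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if self.max_gap_frames < 1:
            raise ConfigurationError("max_gap_frames must be >= 1")
        if self.mirror_policy not in ("auto", "force", "off"):
            raise ConfigurationError(f"unknown mirror_policy {self.mirror_policy!r}")

    @classmethod
    def from_file(cls, path) -> "PreprocessConfig":
        """Load overrides from a plain-text YAML key-value file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class QCReport:
    """Per-recording quality-control bookkeeping."""

    n_interpolated_frames: int = 0
    longest_gap: int = 0
    mirrored: bool = False
    pause_flag: bool = False
    too_short_for_filter: bool = False
    unavailable_landmarks: list[int] = field(default_factory=list)
    degenerate_angle_frames: int = 0
    reasons: list[str] = field(default_factory=list)

    @property
    def exclusion_recommend(self) -> bool:
        return len(self.reasons) > 0

    def flag(self, reason: str) -> None:
        if reason not in self.reasons:
            self.reasons.append(reason)

    def to_dict(self) -> dict:
        return {
            "n_interpolated_frames": self.n_interpolated_frames,
            "longest_gap": self.longest_gap,
            "mirrored": self.mirrored,
            "pause_flag": self.pause_flag,
            "too_short_for_filter": self.too_short_for_filter,
            "unavailable_landmarks": list(self.unavailable_landmarks),
            "degenerate_angle_frames": self.degenerate_angle_frames,
            "exclusion_recommend": self.exclusion_recommend,
            "reasons": list(self.reasons),
        }


@dataclass
class CleanSeries:
    """Gap-free, filtered, orientation-standardised trajectories.

    ``xy``: (T, 25, 2) with up-positive y, in subject-height units when
    normalised (``height_px`` holds the divisor) or pixels otherwise.
    """

    xy: np.ndarray
    fps: float
    height_px: float
    mirrored: bool
    qc: QCReport
    source_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def trace(self, landmark: LandmarkID) -> np.ndarray:
        """(T, 2) trajectory of one landmark."""
        return self.xy[:, int(landmark), :]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _gap_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (half-open) runs of True in a boolean vector."""
    padded = np.concatenate([[False], missing, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def interpolate_gaps(
    series: KeypointSeries,
    config: PreprocessConfig | None = None,
    qc: QCReport | None = None,
) -> tuple[KeypointSeries, QCReport]:
    """Fill missing keypoints by per-coordinate linear interpolation.

    A keypoint is missing when its confidence is at or below the configured
    threshold.  Interior gaps are filled linearly against frame index;
    leading/trailing gaps take the nearest valid value.  Gaps longer than
    ``max_gap_frames`` are filled too but flagged, since only single-frame
    dropouts are routine.  A landmark missing in every frame is recorded as
    unavailable (left as-is; operations needing it raise a clear error).
    """
    config = config or PreprocessConfig()
    qc = qc or QCReport()
    T = series.n_frames
    xy = series.xy.copy()
    missing = series.confidence <= config.missing_conf_threshold  # (T, 25)
    t = np.arange(T, dtype=float)

    frames_touched = np.zeros(T, dtype=bool)
    for lm in range(N_LANDMARKS):
        miss = missing[:, lm]
        if not miss.any():
            continue
        if miss.all():
            qc.unavailable_landmarks.append(lm)
            if lm in REQUIRED_LANDMARKS:
                qc.flag(f"required landmark {LandmarkID(lm).name} never detected")
            continue
        valid = ~miss
        for coord in range(2):
            xy[miss, lm, coord] = np.interp(t[miss], t[valid], xy[valid, lm, coord])
        frames_touched |= miss
        longest = max(stop - start for start, stop in _gap_runs(miss))
        qc.longest_gap = max(qc.longest_gap, longest)

    qc.n_interpolated_frames = int(frames_touched.sum())
    if qc.longest_gap > config.max_gap_frames:
        qc.flag(
            f"gap of {qc.longest_gap} frames exceeds max_gap_frames="
            f"{config.max_gap_frames}"
        )
    conf = series.confidence.copy()
    # filled values are estimates, but downstream treats them as present
    out = KeypointSeries(xy=xy, confidence=conf, fps=series.fps,
                         source_id=series.source_id,
                         n_detections=series.n_detections)
    return out, qc


def lowpass_zero_lag(
    trace: np.ndarray,
    fps: float,
    config: PreprocessConfig | None = None,
    qc: QCReport | None = None,
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filtering along the first axis.

    The causal fifth-order design is applied forward then backward
    (``filtfilt``), cancelling phase so event timing is preserved; the
    effective magnitude response is the squared design response.  Edges are
    handled by odd-reflection padding of length 3 x (order + 1).  Traces too
    short for the padding are passed through unfiltered with a QC flag.
    """
    config = config or PreprocessConfig()
    if fps <= 2 * config.cutoff_hz:
        raise ConfigurationError(
            f"cutoff {config.cutoff_hz} Hz requires fps > {2 * config.cutoff_hz}"
            f" (got fps={fps})"
        )
    trace = np.asarray(trace, dtype=float)
    padlen = 3 * (config.filter_order + 1)
    if trace.shape[0] <= padlen:
        if qc is not None:
            qc.too_short_for_filter = True
            qc.flag(f"trace of {trace.shape[0]} frames too short to filter")
        return trace.copy()
    b, a = signal.butter(config.filter_order, config.cutoff_hz, btype="low", fs=fps)
    return signal.filtfilt(b, a, trace, axis=0, padtype="odd", padlen=padlen)


def detect_facing_and_mirror(
    xy: np.ndarray,
    config: PreprocessConfig | None = None,
    qc: QCReport | None = None,
) -> tuple[np.ndarray, bool]:
    """Standardise the subject to face the image-right.

    Facing is the sign of the median toe-minus-heel horizontal offset (toes
    point where the subject faces).  A left-facing subject is reflected
    about the series-wide x midline and bilateral landmark labels are
    swapped, so the camera-near side is always labelled "right".  Operates
    on a gap-free (T, 25, 2) array; returns (possibly mirrored) array and
    whether mirroring happened.
    """
    config = config or PreprocessConfig()
    xy = np.asarray(xy, dtype=float)
    if config.mirror_policy == "off":
        return xy.copy(), False
    if config.mirror_policy == "force":
        return _mirror(xy), True

    toes = xy[:, [LandmarkID.RIGHT_BIG_TOE, LandmarkID.LEFT_BIG_TOE], 0]
    heels = xy[:, [LandmarkID.RIGHT_HEEL, LandmarkID.LEFT_HEEL], 0]
    offset = float(np.median(toes.mean(axis=1) - heels.mean(axis=1)))
    if abs(offset) < config.facing_epsilon_px:
        if qc is not None:
            qc.flag("facing direction indeterminate; not mirrored")
        return xy.copy(), False
    if offset > 0:  # already facing image-right
        return xy.copy(), False
    return _mirror(xy), True


def _mirror(xy: np.ndarray) -> np.ndarray:
    out = xy.copy()
    axis = (xy[..., 0].min() + xy[..., 0].max()) / 2.0
    out[..., 0] = 2.0 * axis - out[..., 0]
    for right, left in LEFT_RIGHT_PAIRS:
        out[:, [int(right), int(left)], :] = out[:, [int(left), int(right)], :]
    return out


def height_normalize(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide coordinates by subject height in pixels.

    Height is approximated as the 95th percentile (linear-interpolation
    definition) of the per-frame Euclidean right-ankle-to-nose distance,
    which is robust to the seated frames where that distance shrinks.
    """
    xy = np.asarray(xy, dtype=float)
    d = np.linalg.norm(
        xy[:, LandmarkID.NOSE, :] - xy[:, LandmarkID.RIGHT_ANKLE, :], axis=1
    )
    height = float(np.percentile(d, 95))
    if not np.isfinite(height) or height <= 0:
        raise DataError(f"invalid subject height estimate {height!r} px")
    return xy / height, height


def preprocess(series: KeypointSeries, config: PreprocessConfig | None = None) -> CleanSeries:
    """Run the full cleaning chain on a raw keypoint series."""
    config = config or PreprocessConfig()
    qc = QCReport()
    filled, qc = interpolate_gaps(series, config, qc)
    for lm in REQUIRED_LANDMARKS:
        if int(lm) in qc.unavailable_landmarks:
            raise DataError(
                f"required landmark {lm.name} was never detected in "
                f"{series.source_id or 'recording'}"
            )

    xy = filled.xy.copy()
    xy[..., 1] = -xy[..., 1]  # up-positive vertical axis

    T, L, _ = xy.shape
    flat = xy.reshape(T, L * 2)
    flat = lowpass_zero_lag(flat, series.fps, config, qc)
    xy = flat.reshape(T, L, 2)

    xy, mirrored = detect_facing_and_mirror(xy, config, qc)
    qc.mirrored = mirrored

    height_px = float("nan")
    if config.normalize:
        xy, height_px = height_normalize(xy)

    if not np.all(np.isfinite(xy)):
        raise DataError("non-finite values survived preprocessing")
    return CleanSeries(xy=xy, fps=series.fps, height_px=height_px,
                       mirrored=mirrored, qc=qc, source_id=series.source_id)
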