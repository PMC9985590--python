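"""Reading pose-estimation output and cohort tables.

Input contract: one JSON file per video frame in the OpenPose output layout
(top-level ``"people"`` array, each person carrying a flat 75-value
``"pose_keypoints_2d"`` array of x, y, confidence triplets in the BODY_25
order).  Running the pose estimator itself is out of scope; its output format
is the interface.  When several people are detected in a frame, the analysis
subject is the person closest to the camera, operationalised as the detection
with the greatest nose-to-feet distance in pixels.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .landmarks import N_LANDMARKS, VALUES_PER_PERSON, LandmarkID


class FormatError(ValueError):
    """Raised when a keypoint file does not follow the expected layout."""


class SchemaError(ValueError):
    """Raised when a cohort table violates the required schema."""


@dataclass
class PoseFrame:
    """One frame of 25-landmark detections for the selected person.

    ``xy`` is a (25, 2) array in image pixel convention (y downward);
    ``confidence`` is the per-landmark detection score in [0, 1], with 0
    encoding an absent detection.
    """

    frame_index: int
    xy: np.ndarray
    confidence: np.ndarray
    n_detections_in_frame: int = 1

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(N_LANDMARKS, 2)
        self.confidence = np.asarray(self.confidence, dtype=float).reshape(N_LANDMARKS)

    def keypoint(self, landmark: LandmarkID) -> tuple[float, float, float]:
        i = int(landmark)
        return (self.xy[i, 0], self.xy[i, 1], self.confidence[i])

    def to_flat(self) -> np.ndarray:
        """Re-serialize to the 75-value (x, y, c) layout."""
        return np.column_stack([self.xy, self.confidence[:, None]]).ravel()


@dataclass
class KeypointSeries:
    """An ordered stack of frames for one recording.

    ``xy``: (T, 25, 2) pixel coordinates, ``confidence``: (T, 25).
    """

    xy: np.ndarray
    confidence: np.ndarray
    fps: float
    source_id: str = ""
    n_detections: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_LANDMARKS, 2):
            raise ValueError(f"xy must have shape (T, 25, 2), got {self.xy.shape}")
        if self.confidence.shape != self.xy.shape[:2]:
            raise ValueError("confidence shape must match xy frames x landmarks")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.n_detections is None:
            self.n_detections = np.ones(len(self.xy), dtype=int)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def frames(self) -> Iterator[PoseFrame]:
        for i in range(self.n_frames):
            yield PoseFrame(i, self.xy[i], self.confidence[i],
                            int(self.n_detections[i]))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def select_person(
    detections: Sequence[np.ndarray],
    missing_conf_threshold: float = 0.0,
) -> np.ndarray:
    """Pick the analysis subject among candidate detections of one frame.

    The person closest to the camera appears largest, so the candidate with
    the greatest Euclidean distance between the nose and the feet reference
    point wins.  The feet reference is the mean of the two ankles among those
    detected; heels, then big toes, are the fallbacks.  Ties keep the lowest
    list index.  If no candidate has both a nose and a foot landmark, an
    all-zero (all-missing) detection is returned rather than raising.

    Parameters
    ----------
    detections : sequence of (75,) or (25, 3) float arrays
    """
    if len(detections) == 0:
        raise ValueError("select_person requires at least one candidate")
    cands = [np.asarray(d, dtype=float).reshape(N_LANDMARKS, 3) for d in detections]

    fallbacks = (
        (LandmarkID.RIGHT_ANKLE, LandmarkID.LEFT_ANKLE),
        (LandmarkID.RIGHT_HEEL, LandmarkID.LEFT_HEEL),
        (LandmarkID.RIGHT_BIG_TOE, LandmarkID.LEFT_BIG_TOE),
    )

    def nose_feet_distance(kp: np.ndarray) -> float:
        if kp[LandmarkID.NOSE, 2] <= missing_conf_threshold:
            return -np.inf
        nose = kp[LandmarkID.NOSE, :2]
        for right, left in fallbacks:
            pts = [kp[i, :2] for i in (right, left)
                   if kp[i, 2] > missing_conf_threshold]
            if pts:
                feet = np.mean(pts, axis=0)
                return float(np.hypot(*(nose - feet)))
        return -np.inf

    dists = [nose_feet_distance(kp) for kp in cands]
    best = int(np.argmax(dists))  # argmax keeps the first index on ties
    if not np.isfinite(dists[best]):
        return np.zeros((N_LANDMARKS, 3))
    return cands[best]


def _parse_frame_file(path: Path, missing_conf_threshold: float) -> tuple[np.ndarray, int]:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise FormatError(f"unparsable keypoint file {path}: {exc}") from exc
    people = payload.get("people")
    if people is None:
        raise FormatError(f"{path}: missing top-level 'people' array")
    detections = []
    for person in people:
        flat = np.asarray(person.get("pose_keypoints_2d", []), dtype=float)
        if flat.size % VALUES_PER_PERSON != 0 or flat.size == 0:
            raise FormatError(
                f"{path}: pose_keypoints_2d has {flat.size} values, "
                f"expected a multiple of {VALUES_PER_PERSON} (BODY_25 layout)"
            )
        detections.append(flat[:VALUES_PER_PERSON])
    if not detections:
        return np.zeros((N_LANDMARKS, 3)), 0
    chosen = select_person(detections, missing_conf_threshold)
    return chosen, len(detections)


_FRAME_NUM_RE = re.compile(r"(\d+)")


def read_openpose_dir(
    path: str | Path,
    fps: float,
    missing_conf_threshold: float = 0.0,
) -> KeypointSeries:
    """Read a directory of per-frame OpenPose JSON files into a series.

    Files are taken in lexicographic order (zero-padded frame numbering
    assumed); non-contiguous embedded frame numbers are re-indexed 0..N-1
    with a warning.  Frames with an empty ``people`` list become all-missing
    frames (confidence 0 everywhere).
    """
    path = Path(path)
    # prefer the estimator's own *_keypoints.json naming so sidecar JSON
    # (ground truth, configs) in the same directory is not mistaken for frames
    files = sorted(path.glob("*keypoints.json")) or sorted(path.glob("*.json"))
    if not files:
        raise FormatError(f"no .json keypoint files found in {path}")

    numbers = []
    for f in files:
        m = _FRAME_NUM_RE.findall(f.stem)
        numbers.append(int(m[-1]) if m else None)
    if all(n is not None for n in numbers):
        diffs = np.diff(numbers)
        if len(diffs) and not np.all(diffs == 1):
            warnings.warn(
                f"{path}: non-contiguous frame numbering; re-indexing 0..{len(files) - 1}",
                stacklevel=2,
            )

    xy = np.zeros((len(files), N_LANDMARKS, 2))
    conf = np.zeros((len(files), N_LANDMARKS))
    n_det = np.zeros(len(files), dtype=int)
    for i, f in enumerate(files):
        kp, n = _parse_frame_file(f, missing_conf_threshold)
        xy[i] = kp[:, :2]
        conf[i] = kp[:, 2]
        n_det[i] = n
    return KeypointSeries(xy=xy, confidence=conf, fps=fps,
                          source_id=path.name, n_detections=n_det)


# ---------------------------------------------------------------------------
# Cohort tables

COHORT_COLUMNS = (
    "participant_id", "age", "sex", "bmi", "race_ethnicity",
    "gph", "gmh", "oa_diagnosis", "exclusion_flags",
)

_NUMERIC_COHORT_COLUMNS = ("age", "bmi", "gph", "gmh", "oa_diagnosis")


@dataclass
class ParticipantRecord:
    """Survey measures for one participant.

    gph / gmh are the PROMIS global physical / mental health summary scores
    (treated as plain numeric inputs); oa_diagnosis is a self-reported
    clinical hip or knee osteoarthritis diagnosis (0/1).
    """

    participant_id: str
    age: float
    sex: str
    bmi: float
    race_ethnicity: str
    gph: float
    gmh: float
    oa_diagnosis: float
    manual_exclusion_flags: frozenset[str] = field(default_factory=frozenset)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Required columns: participant_id, age, sex, bmi, race_ethnicity, gph,
    gmh, oa_diagnosis, exclusion_flags.  Missing numeric cells become NaN;
    unknown categorical values are preserved verbatim.  Inclusion criterion:
    adults only (age >= 18).  exclusion_flags is a semicolon-separated list
    of manual review labels (cushioned chair, arm use, planar camera angle,
    ...); empty means included.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "exclusion_flags": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"cohort table {path} is missing required columns {missing}; "
            f"required: {list(COHORT_COLUMNS)}"
        )
    for col in _NUMERIC_COHORT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise SchemaError(f"duplicated participant_id values: {dupes}")
    underage = df.loc[df["age"].notna() & (df["age"] < 18), "participant_id"].tolist()
    if underage:
        raise SchemaError(
            f"participants below the age-18 inclusion criterion: {underage}"
        )
    bad_oa = df["oa_diagnosis"].dropna()
    if not bad_oa.isin([0, 1]).all():
        raise SchemaError("oa_diagnosis must be binary 0/1")
    bad_bmi = df.loc[df["bmi"].notna() & (df["bmi"] <= 0), "participant_id"].tolist()
    if bad_bmi:
        raise SchemaError(f"non-positive BMI for participants: {bad_bmi}")
    df["exclusion_flags"] = df["exclusion_flags"].fillna("")
    return df


def cohort_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Materialise a validated cohort DataFrame as typed records."""
    out = []
    for row in df.itertuples(index=False):
        flags = frozenset(f for f in str(row.exclusion_flags).split(";") if f)
        out.append(ParticipantRecord(
            participant_id=row.participant_id, age=row.age, sex=row.sex,
            bmi=row.bmi, race_ethnicity=row.race_ethnicity, gph=row.gph,
            gmh=row.gmh, oa_diagnosis=row.oa_diagnosis,
            manual_exclusion_flags=flags,
        ))
    return out


def write_parameters_table(
    cohort: pd.DataFrame,
    params: dict[str, dict],
    path: str | Path,
) -> pd.DataFrame:
    """Join survey fields with extracted STS parameters and write a CSV.

    ``params`` maps participant_id to a flat dict of parameter columns (see
    :func:`stskit.kinematics.STSParameters.to_dict`).  Parameter rows whose
    id is absent from the cohort are still emitted, with blank survey fields
    and a warning.
    """
    param_df = pd.DataFrame.from_dict(params, orient="index")
    param_df.index.name = "participant_id"
    param_df = param_df.reset_index()
    unknown = set(param_df["participant_id"]) - set(cohort["participant_id"])
    if unknown:
        warnings.warn(
            f"parameters present for ids absent from cohort table: {sorted(unknown)}",
            stacklevel=2,
        )
    merged = cohort.merge(param_df, on="participant_id", how="outer")
    if len(params) == 0:
        merged = merged.iloc[0:0]
    merged.to_csv(path, index=False)
    return merged


def read_parameters_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_parameters_table`."""
    df = pd.read_csv(path, dtype={"participant_id": str, "exclusion_flags": str})
    if "participant_id" not in df.columns:
        raise SchemaError(f"{path}: missing participant_id column")
    if "exclusion_flags" in df.columns:
        df["exclusion_flags"] = df["exclusion_flags"].fillna("")
    return df
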