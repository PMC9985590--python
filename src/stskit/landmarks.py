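"""BODY_25 landmark layout.

The 25-landmark 2D pose layout used by OpenPose: nose, neck and mid-hip on
the midline, plus bilateral shoulder, elbow, wrist, hip, knee, ankle, eye,
ear, first metatarsal (big toe), fifth metatarsal (small toe) and heel.
Each landmark is emitted as an (x, y, confidence) triplet, 75 values per
person per frame, with image-convention coordinates (y grows downward) and
undetected points encoded as (0, 0, 0).
"""

from __future__ import annotations

from enum import IntEnum


class LandmarkID(IntEnum):
    """Index of each landmark in the BODY_25 layout."""

    NOSE = 0
    NECK = 1
    RIGHT_SHOULDER = 2
    RIGHT_ELBOW = 3
    RIGHT_WRIST = 4
    LEFT_SHOULDER = 5
    LEFT_ELBOW = 6
    LEFT_WRIST = 7
    MID_HIP = 8
    RIGHT_HIP = 9
    RIGHT_KNEE = 10
    RIGHT_ANKLE = 11
    LEFT_HIP = 12
    LEFT_KNEE = 13
    LEFT_ANKLE = 14
    RIGHT_EYE = 15
    LEFT_EYE = 16
    RIGHT_EAR = 17
    LEFT_EAR = 18
    LEFT_BIG_TOE = 19
    LEFT_SMALL_TOE = 20
    LEFT_HEEL = 21
    RIGHT_BIG_TOE = 22
    RIGHT_SMALL_TOE = 23
    RIGHT_HEEL = 24


N_LANDMARKS = 25
VALUES_PER_PERSON = 3 * N_LANDMARKS

#: Bilateral (right, left) landmark pairs, used when mirroring a recording.
LEFT_RIGHT_PAIRS: tuple[tuple[LandmarkID, LandmarkID], ...] = (
    (LandmarkID.RIGHT_SHOULDER, LandmarkID.LEFT_SHOULDER),
    (LandmarkID.RIGHT_ELBOW, LandmarkID.LEFT_ELBOW),
    (LandmarkID.RIGHT_WRIST, LandmarkID.LEFT_WRIST),
    (LandmarkID.RIGHT_HIP, LandmarkID.LEFT_HIP),
    (LandmarkID.RIGHT_KNEE, LandmarkID.LEFT_KNEE),
    (LandmarkID.RIGHT_ANKLE, LandmarkID.LEFT_ANKLE),
    (LandmarkID.RIGHT_EYE, LandmarkID.LEFT_EYE),
    (LandmarkID.RIGHT_EAR, LandmarkID.LEFT_EAR),
    (LandmarkID.RIGHT_BIG_TOE, LandmarkID.LEFT_BIG_TOE),
    (LandmarkID.RIGHT_SMALL_TOE, LandmarkID.LEFT_SMALL_TOE),
    (LandmarkID.RIGHT_HEEL, LandmarkID.LEFT_HEEL),
)
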