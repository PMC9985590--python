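"""File-based workflow: OpenPose JSON frames in, parameter table out.

Writes a synthetic recording to disk in the OpenPose per-frame JSON layout
(exactly what the pose estimator produces for a real video), analyses the
directory as a batch of one, and joins the result with a small cohort
table.  Swap the simulated directory for a real OpenPose output directory
to analyse real recordings; fps must come from the video metadata.
"""

import tempfile
from pathlib import Path

import pandas as pd

from stskit import (
    MotionScript,
    analyze_batch,
    simulate_sts,
    write_openpose_dir,
    write_parameters_table,
)

workdir = Path(tempfile.mkdtemp())
rec_dir = workdir / "P0001"
series, truth = simulate_sts(script=MotionScript.from_total_time(11.4))
write_openpose_dir(series, rec_dir)
print(f"wrote {series.n_frames} OpenPose frame files to {rec_dir}")

results, errors = analyze_batch([rec_dir], fps=30.0)
assert not errors
params = {pid: rec["parameters"] for pid, rec in results.items()}

cohort = pd.DataFrame({
    "participant_id": ["P0001"],
    "age": [62], "sex": ["female"], "bmi": [27.1],
    "race_ethnicity": ["white"], "gph": [48.1], "gmh": [52.3],
    "oa_diagnosis": [1], "exclusion_flags": [""],
})
table = write_parameters_table(cohort, params, workdir / "parameters.csv")
cols = ["participant_id", "age", "total_time_s", "max_trunk_angle_deg", "n_cycles"]
print(table[cols].to_string(index=False))
print()
print(f"total_time_s should be ~11.4 s (scripted); the CSV at "
      f"{workdir/'parameters.csv'} holds survey fields plus all kinematics.")
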