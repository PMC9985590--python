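# Methods

This note documents the models, conventions and numerical choices behind
`stskit`, in the order data flows through the package.

## Input model

The input contract is the OpenPose BODY_25 output layout: per frame, a
`people` array whose entries carry a flat 75-value `pose_keypoints_2d`
array of (x, y, confidence) triplets for 25 landmarks, image convention
(y downward), with undetected landmarks encoded as (0, 0, 0). Running the
pose estimator and probing video containers are out of scope; frames per
second is a required input. Arrays whose length is not a multiple of 75
(e.g. COCO-18 output) are rejected with a format error.

**Person selection.** When a frame contains several detections, the
analysis subject is the one closest to the camera, operationalised as the
largest Euclidean nose-to-feet distance in pixels. "Feet" is taken as the
mean of the two ankles among those detected — the most reliably detected
foot-adjacent landmark — falling back to heels, then big toes. Ties keep
the lowest list index. If no candidate has both a nose and a foot landmark,
the frame becomes all-missing rather than raising, so one bad frame cannot
abort a recording.

**Missingness.** A keypoint with confidence at or below a threshold
(default 0.0) is missing; the default matches the estimator's own encoding
of undetected points without discarding low-confidence but real detections.

## Cleaning chain

Order of operations: missing-marking → linear interpolation → vertical-axis
flip (y_up = −y_image) → zero-lag low-pass filtering → mirroring →
height normalisation. The up-positive convention makes standing positions
literal maxima of the nose trace. Angles are invariant to the flip,
mirroring and normalisation, so the exact order affects only bookkeeping;
this order is the one in which the artefacts naturally arise.

**Interpolation.** Interior gaps are filled linearly per coordinate against
frame index; leading/trailing gaps take the nearest valid value. Isolated
single-frame dropouts are the routine case; gaps longer than
`max_gap_frames` (default 3) are still filled but flagged for review, since
long gaps indicate an unusable recording rather than estimator noise. A
landmark missing in every frame is recorded as unavailable; analyses
requiring it (nose, neck, right hip, right ankle) fail with a clear error.

**Filtering.** A fifth-order 6 Hz low-pass Butterworth design applied
forward and backward (`scipy.signal.filtfilt`) gives zero net phase —
event timing is preserved — at the cost of squaring the magnitude
response. Edges use odd-reflection padding of length 3 × (order + 1).
Traces too short for the padding pass through unfiltered with a QC flag.
The design requires fps > 2 × cutoff; lower frame rates are a
configuration error. Note that the realised stopband attenuation of the
digital design is *stronger* than the squared analog prototype magnitude
1/(1 + (f/f_c)^10) at frequencies approaching Nyquist (bilinear frequency
warping); at 12 Hz on a 30 fps stream the measured amplitude ratio is
~5 × 10⁻⁷ against an analog prediction of ~1 × 10⁻³. Tests therefore check
the passband gain two-sidedly (within 1% at 1 Hz) and the stopband as a
bound (at least the predicted attenuation).

**Mirroring.** Facing is the sign of the median toe-minus-heel horizontal
offset (toes point where the subject faces); the heuristic is this
package's own, since identification of left-facing recordings is otherwise
a manual step. Left-facing subjects are reflected about the series-wide x
midline and bilateral labels swapped, so "right" always denotes the
camera-near side downstream. An offset below `facing_epsilon_px` (0.5 px)
leaves the series unmirrored with a QC warning.

**Height normalisation.** All coordinates are divided by the subject's
height in pixels, approximated as the 95th percentile
(linear-interpolation definition — the method is otherwise unstated
convention) of the per-frame right-ankle-to-nose distance. The percentile
is robust to seated frames where the distance shrinks. Non-positive or
non-finite height is a fatal data error.

## Segmentation

Standing and sitting events are local maxima/minima of the cleaned nose
vertical trace, found with prominence ≥ 0.2 × trace range and separation
≥ 0.5 s (defaults tuned on the simulator; configurable). Two refinements
matter in practice:

- **Boundary minima.** The protocol starts (and usually ends) seated, so
  the first sitting position is a boundary, invisible to interior peak
  detection. The segments before the first and after the last standing
  peak are scanned; a boundary minimum is accepted when it dips below the
  adjacent peak by the prominence threshold. Without it, a five-cycle
  recording yields only four sit-to-stand phases.
- **Sub-frame event times.** A dwell is a near-flat plateau; zero-lag
  filtering leaves ripple on it, so the raw argmax can sit anywhere on the
  plateau. Each extremum is re-centred midway between the fractional
  crossings of the level `height − plateau_tol_frac × range` (default
  0.05, wide enough to ride over filter ringing at dwell edges). For a
  smooth symmetric peak the midpoint is the true extremum; either way the
  timing becomes sub-frame, which matters because the cycle-count
  correction multiplies timing errors by five.

Non-alternating detections are resolved by keeping the more extreme of
adjacent same-kind extrema. Phases follow by definition: minimum → next
maximum is sit-to-stand, maximum → next minimum is stand-to-sit.

**Total time and the correction.** With exactly five detected cycles, the
total is the time from first to last standing maximum. For any other count
(generalising the observed 3, 4, 6), the mean stand-to-stand interval —
the average time per cycle — is multiplied by five. The two definitions
are not mutually consistent: a five-cycle first-to-last span covers four
stand-to-stand intervals, so the corrected estimate for a five-cycle
recording would be 25% longer than the uncorrected one. The literal
correction rule is implemented regardless and the `corrected` flag is
always reported, so users can stratify on it. "Time per cycle" is read as
the stand-to-stand interval (rather than sit-to-sit), matching the
standing-position anchors of the uncorrected definition.

**Pause detection.** A long pause between repetitions — an exclusion
ground in field use — is flagged when any stand-to-stand interval exceeds
2.5 × the median interval or 5 s outright. Subjective exclusion grounds
(cushioned chair, arm use, planar camera angle, clothing artefacts) cannot
be automated from keypoints; they live in a manual `exclusion_flags`
column of the cohort table.

## Kinematics

Joint angles are interior angles at the vertex landmark via the arccosine
of the normalised dot product, in [0, 180]°; no signed flexion/extension
split is attempted because a 2D projection cannot disambiguate it. The
trunk angle is measured at the right hip between vertical-up and the
hip→neck vector; after mirroring, "right" is the camera-near side, and 0°
is upright. Degenerate (zero-length) limb vectors yield per-frame missing
values and a QC counter.

Derivatives are first differences multiplied by fps per order (i.e.
divided by the frame period), aligned to the later frame of each
difference; a derivative value at a phase boundary belongs to the phase
containing that later frame. Dividing a finite difference *by* the frame
rate would be dimensionally wrong; the implementation treats "divide by
the framerate" phrasing in field descriptions as shorthand for dividing by
the frame period.

Per-recording parameters average each per-sit-to-stand-phase maximum
(trunk angle; positive — "forward" — trunk angular acceleration) across
however many cycles were detected, mirroring the correction philosophy.
Whether a published "maximum trunk angle" is a per-cycle maximum averaged
over cycles or a global maximum is genuinely ambiguous; the per-cycle mean
is the primary output and the global maximum is emitted as a secondary
column (`max_trunk_angle_global_deg`).

**Known limitation — second derivatives amplify noise.** Keypoint jitter
that survives the 6 Hz filter is multiplied by fps² in the angular
acceleration; with 2-px jitter at ~520-px subject height the extracted
peak acceleration can exceed the noiseless value severalfold even though
the trunk *angle* is recovered within a fraction of a degree. The
parameter remains useful for between-participant comparison (the noise
floor is shared), not as an absolute biomechanical quantity.

## Statistics

- **Pearson/BH screen.** Pearson r with two-sided p from the t transform
  (n − 2 df), pairwise-complete deletion; binary variables enter as 0/1
  (point-biserial). The Benjamini–Hochberg family size is an explicit
  argument (21 for the primary screen: 3 STS parameters × 7 measures; 6
  for the ≥ 50-years subgroup: 3 parameters × physical/mental health), so
  partial reruns keep the published correction; m may exceed the number of
  supplied tests. The primary and subgroup families are treated as
  disjoint.
- **Group comparisons.** Tie-corrected Kruskal–Wallis H with a χ²(k − 1)
  p value across the four largest race/ethnicity groups, then Dunn's
  pairwise z from pooled mean ranks with the standard tie correction,
  two-sided normal p, BH-adjusted within the pairwise family. Dunn's test
  is implemented in-package (with an independent oracle in the tests); the
  other fits delegate to scipy/statsmodels.
- **Regressions.** OLS and maximum-likelihood logit (Newton, tolerance
  1e-8, ≤ 100 iterations) with normal-theory/Wald 95% CIs, listwise
  deletion, explicit rank check naming collinear terms, and clear errors
  on separation or single-class outcomes. Covariate sets are declared per
  model (default: each kinematic–outcome association adjusted for age,
  sex, BMI and, where applicable, STS time); sex is coded female = 1,
  race/ethnicity regression contrasts the two largest groups.
- **SMD balance.** Continuous: (mean_a − mean_b)/pooled SD (equal-weight
  two-group pooling); binary: (p_a − p_b)/√((p_a(1−p_a)+p_b(1−p_b))/2);
  95% CI from the large-sample variance 1/n_a + 1/n_b + d²/(2(n_a+n_b));
  |SMD| < 0.1 flags negligible imbalance.

## Synthetic data

The simulator drives a sagittal linked-segment chain (foot anchored at the
ankle; shank, thigh, trunk, head) through seated ↔ standing configurations
with raised-cosine profiles: the pose phase s(t) rises 0 → 1 as
(1 − cos(πτ/T_rise))/2 and the thigh angle interpolates 90° (horizontal,
seated) → 0° (vertical). The trunk lean bump L·sin(πs) peaks mid-rise,
giving closed-form event times, peak lean and peak angular acceleration —
the oracles the pipeline is tested against. Each cycle is seated dwell →
rise → standing dwell → descent (35/15/35/15% of the period by default),
with a final seated dwell.

The 45° recording obliquity is modelled as a single horizontal
foreshortening factor cos(45°) — a deliberate simplification of full
perspective, sufficient to exercise 2D-projection behaviour. The scripted
peak trunk lean is defined *in the camera projection plane*: the generator
poses the trunk at world lean arctan(tan(lean)/cos(obliquity)) so the
scripted value equals the angle a 2D analysis should measure. Non-modelled
landmarks (eyes, ears, crossed arms, far-side limbs) are anatomically
plausible rigid offsets that exist so the 25-slot format contract holds;
their kinematics are not meaningful.

Corruption adds Gaussian keypoint jitter, whole-pose dropout runs capped
at one frame by default (failures are isolated single frames in practice),
and an optional left-facing rendering (reflection + bilateral label swap —
exactly what a pose estimator produces when the subject's left side faces
the camera). Everything is reproducible from the seed.

**Cohorts.** Survey covariates and target test times come from a Gaussian
copula over latent normals (age, sex, BMI, GPH, GMH, osteoarthritis, test
time); planted correlations are entries of the latent matrix, checked for
positive semi-definiteness before sampling, and binary traits threshold
their latents at the target prevalence. Marginals follow the study
population this design emulates: age 37.3 ± 17.8 years truncated to
[18, 96], test time 11.4 ± 3.4 s in [4.3, 32.9], PROMIS scores on the
T-score scale (50 ± 10), 53% female, 15% osteoarthritis prevalence,
race/ethnicity proportions 60/25/9/6%. Default planted effects:
corr(age, time) = 0.35, corr(BMI, time) = 0.20, corr(GPH, time) = −0.20,
corr(age, OA latent) = 0.30, an osteoarthritis trunk-lean shift of +5.8°
(the observed group difference this design targets) and a +4° lean shift
for the second-largest race group. Each participant's script realises
their target time exactly (period = target/4 for five cycles) and their
lean as base N(17°, 4°) plus shifts, clipped to [3°, 45°]. Exclusion on
manual review is planted at a mildly sex-dependent rate (20% female, 13%
male) so the balance table has realistic signal. Truncation of the
marginals slightly attenuates planted Pearson correlations (the latent
0.35 realises at ~0.345 on average); tests band the recovery accordingly.

What the generator does *not* emulate: perspective distortion and camera
motion, outlier (as opposed to missing or jittered) keypoints,
within-test fatigue or irregular cycle timing, arm use, chair variation,
and clothing-driven hip mislocalisation. Passing tests therefore
demonstrate correctness of the measurement chain under the stated noise
model, not robustness to every field artefact; QC flags and manual
exclusion fields are the mechanism for the rest.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic recordings of
roughly 200–1,100 frames (30 fps, 3–6 cycles), 100 randomized segmentation
scripts, 200 cohort draws at n = 405 for correlation recovery, and a
40-participant rendered cohort for the osteoarthritis-shift check — sizes
chosen so the full run completes in seconds while estimator variance stays
well inside the tested bands. All randomness flows from explicit seeds;
identical inputs give byte-identical outputs.
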