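# Methods

This note records the models, conventions and numerical choices behind
`bodycues`, in the spirit of a package's model documentation: what is
computed, under which assumptions, and where genuinely open design choices
were settled.

## Skeleton and normalization

The canonical skeleton has 23 joints in the layout of inertial capture
suits: an axial chain Pelvis–L5–L3–T12–T8–Neck–Head, arms parented at T8
(Shoulder–Elbow–Wrist–Hand per side), legs parented at the pelvis
(Hip–Knee–Ankle–Toe per side). Body parts partition the 22 non-root
joints into left/right arm (4 each), left/right leg (4 each), torso (4)
and head (2); 8 left joints pair with right counterparts and 6 axial
joints are midline. This layout is the unique assignment consistent with
the feature counts below (22 movement joints, 9 angle pivots, 11 distance
pairs, 8 + 6 symmetry comparisons). The definition ships as
`data/skeleton.yaml` so adapters can declare alternates without code
changes.

Normalization is resample → center → scale, fixed in that order for
reproducibility (the three commute for every feature computed here):

* **Resampling** 60 → 5 Hz by decimation (every 12th frame, starting at
  frame 0). Decimation preserves instantaneous poses; block averaging is
  available as `method="mean"`. The window statistics absorb most of the
  difference between the two.
* **Centering** subtracts the same-frame pelvis from every joint and drops
  the pelvis, removing global position exactly (translation invariance is
  tested at 1e-12).
* **Segment scaling** rebuilds the kinematic tree root-outward, placing
  each joint at its parent plus the original unit direction times a
  reference length. Reference lengths are the corpus-wide mean
  parent–child distance, computed once on the resampled corpus — not per
  cross-validation fold — because the transformation needs no knowledge of
  the subject's class and a single pass keeps train/test geometry
  identical. A zero-length segment has no direction and is treated as an
  input-data error.

Rotation is deliberately not normalized: all downstream features are
functions of body-relative distances and angles and are invariant to
global rigid transforms (verified to 1e-9).

## Features (67)

* **Movement (30):** Euclidean displacement of each of the 22 joints
  between consecutive (5 Hz) frames; totals over the six body parts; an
  upper-body total (arms + torso + head) and a full-body total. Computed
  on normalized data, so root translation does not contribute.
* **Joint angles (10):** at the neck, shoulders, elbows, hips and knees,
  the angle between the incoming segment (parent → pivot) and the outgoing
  one (pivot → child), in degrees; a fully extended chain measures 0°.
  The tenth feature is the mean of the nine.
* **Joint distances (12):** head–left/right elbow, left hand–right hand,
  left hand–right elbow, right hand–left elbow, left hand–left knee,
  right hand–right knee, knee–knee, ankle–ankle, pelvis–left/right ankle
  (the pelvis being the origin after centering), plus their mean.
* **Symmetry (15):** poses are mirrored in the plane through the root
  whose normal is the unit vector from left hip to right hip (recomputed
  per frame). Eight features compare each mirrored left joint with its
  right counterpart; six compare each midline joint with its own mirror
  image; the fifteenth is the mean of the fourteen. Coincident hips make
  the plane undefined and raise an error.

Catalogue metadata link every feature to the body parts it involves:
per-joint features to their own part; angle features to the pivot joint's
part; two-joint distances and paired symmetry features to both endpoints'
parts; upper/full-body totals and the three means to all parts. The
breakdowns additionally class features by extent — *single* (one part),
*two* (exactly two), *all* (three or more, i.e. the aggregates and
means) — giving 45/17/5 of the 67.

## Windows (335 dimensions)

Streams are cut into consecutive non-overlapping windows (whole session,
60, 30, 10, 5 or 1 s); a trailing remainder shorter than the window is
dropped rather than padded, avoiding biased tail statistics. Movement
streams, defined on frame transitions, are assigned to the window holding
the later frame of each pair. Each feature is summarized by mean, minimum,
maximum, range and standard deviation — 335 values per window regardless
of window length. The standard deviation uses the sample (n−1)
denominator, consistent with the classifier's sample estimates (`ddof=0`
is available). Windows need at least two samples per feature.

## Classifier

Per feature and class, training windows yield a sample mean and sample
standard deviation; a test value is assigned to the class with the larger
Gaussian density, with equal priors (the lab setting's 50/50 design;
priors can be overridden only by way of the densities, deliberately not
exposed as a tuning knob). Degenerate σ = 0 estimates are floored at
1e-9 times the feature's pooled training sd (1e-9 absolute if that is
also zero) so the argmax stays defined. Exact density ties and exact vote
ties resolve deterministically to "truth" — reproducible and aligned with
the truth bias such voting exhibits anyway; seeded random tie-breaking is
available. Votes are combined by strict majority over the selected
features.

Feature selection uses a two-sample test per feature on the training
windows: Welch's unequal-variance t-test by default — the safest default
among plausible location tests; Student's t and Mann–Whitney are config
options, and the choice should be calibrated against reported selection
sizes when the original corpus is available. Features with zero variance
in both classes get p = 1. *stat-95* keeps p < 0.05, *stat-99* p < 0.01,
and *all* bypasses the filter. Ranking for top-k analyses sorts ascending
p with ties broken by catalogue order, so top-k lists are prefixes of each
other.

Evaluation is leave-one-interviewee-out: both sessions of one interviewee
are held out per fold; fitting and selection use only the remaining
interviewees' windows (optionally restricted to Game or Wallet sessions).
The detection rate is the mean of per-fold window accuracies; sub-session
windows are scored independently (no session-level fusion — published
window-length curves do not describe one, so none is invented). A
leakage assertion in every fold guarantees train and test windows are
disjoint.

The noise experiment adds zero-mean Gaussian noise to every test-window
feature with sd = r × the feature's *pooled* (class-agnostic) training sd:
class-conditional sds exist, but the true class of a test sample is
unknown at measurement time, so the pooled scale is the physically
coherent default; the class-conditional variant remains available for
sensitivity analysis. Noise is injected into the aggregated window
features, not raw coordinates.

## Synthetic corpus generator

The generator emulates a seated interview, not biomechanically realistic
motion:

* a fixed, mirror-symmetric seated template pose;
* postural sway: independent AR(1) processes (coefficient 0.99 at 60 Hz,
  i.e. a ~1.7 s correlation time; innovation scale `sway_sd` = 2 mm,
  stationary amplitude ≈ 1.4 cm) on every coordinate of every joint —
  smooth, stationary, simple;
* gestures: Poisson arrivals at 0.05 events/s (~7–8 per 2.5-minute
  session), each displacing one randomly chosen arm chain along a random
  direction with a raised-cosine envelope (amplitude 8 cm at the hand,
  tapering toward the shoulder) over 1 s;
* the condition effect: in lie sessions both the sway scale and the
  gesture rate are multiplied by `lie_movement_multiplier`, leaving the
  template pose unchanged — the simplest mechanism consistent with the
  replicated finding that liars move more in every limb. No quantitative
  per-limb effect size is available to calibrate against, so the default
  multiplier (1.5, a moderate effect) is an explicit modeling choice
  exposed in the config.

Corpora are balanced (half truth, half lie, assigned by a seeded
permutation; an even interviewee count is required) and paired: each
interviewee keeps one condition across their Game and Wallet sessions.
Everything is bit-reproducible from (config, seed).

What the generator does **not** emulate: speech and turn-taking, posture
shifts and leg gestures, interviewer behavior, inter-subject differences
in body dimensions or movement style, sensor drift, or correlated
measurement noise. Passing tests on synthetic corpora therefore
demonstrate that the pipeline is correctly wired and statistically
calibrated (chance level on null data, recovery of planted effects,
monotone degradation under noise) — not that real interviews are
classifiable at any particular rate.

## Problem sizes and test design

Unit tests run on 6-interviewee, 30 s corpora. Calibration checks use
20-interviewee, 150 s corpora: the null calibration averages 20 seeded
corpora, the multiplier sweep (1.0/1.5/2.0/3.0) 10 seeds per level, and
the noise-degradation check 10 seeds with 100 noise repetitions each —
sizes at which the binomial noise of a LOOCV rate (~11 points sd per
corpus, ~2.5 after averaging) is small against the 10-point calibration
band. `scripts/acceptance.py` recomputes the same quantities from scratch
at a user-supplied seed.

## Known limitations

* The significance test behind stat-95/stat-99 is a package choice
  (Welch); selection sizes on real data will shift slightly under
  Student's t or Mann–Whitney.
* Reference lengths are corpus-wide, which mixes a negligible amount of
  test-set geometry (segment lengths only, never labels) into training
  folds; a per-fold variant would need per-fold renormalization of all
  windows.
* Feature correlations are deliberately ignored — per-feature Gaussians
  plus voting is the analysis, not an optimal classifier.
* With very small corpora (fewer than ~3 interviewees per class) the
  per-class sample sds are unstable and LOOCV folds can fail the
  two-samples-per-class requirement.
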