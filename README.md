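# bodycues

Mining bodily cues to deception from motion-capture interview recordings.

Research on nonverbal deception cues has long relied on manually coded,
discrete behaviors. `bodycues` implements the alternative: a data-mining
pipeline that codes full-body motion capture quantitatively and asks which
geometric signals separate truthful from deceptive accounts. It is aimed at
researchers in behavioral kinematics and deception who want a transparent,
per-feature analysis rather than a black-box classifier, plus a synthetic
corpus generator so every stage can be exercised and calibrated without
access to recorded participants.

## The pipeline

**Input.** Interview sessions recorded as 23-joint 3-D trajectories at
60 Hz (the layout of Xsens MVN inertial suits), with a binary veracity
label per interviewee and two paired sessions each (a *Game* task with
reverse-order questions and a *Wallet* task).

**Coding.** Each session is resampled to 5 Hz, expressed relative to the
pelvis, and rescaled so every body segment has the corpus-average length.
From the normalized pose, 67 per-frame features are computed in four
families: 30 *movement* features (per-joint displacement between
consecutive frames plus body-part, upper-body and full-body totals), 10
*joint angles* (neck, shoulders, elbows, hips, knees, and their mean), 12
*joint distances* (11 named pairs such as head–elbow and hand–hand, plus
their mean), and 15 *symmetry* features (distance between each left joint
mirrored in the sagittal plane and its right counterpart, midline joints
against their own mirror image, and the mean). Features are aggregated over
non-overlapping windows (whole session down to 1 s) with five statistics —
mean, minimum, maximum, range, standard deviation — giving a
67 × 5 = 335-dimensional vector per window.

**Classification.** Every window feature gets its own two-class Gaussian
classifier with equal priors: for class $c$ and feature $i$, training data
yield $\mu_{ci}, \sigma_{ci}$ and a test value $x_i$ is assigned to

$$\hat c_i = \arg\max_c \frac{1}{\sigma_{ci}\sqrt{2\pi}}
  \, e^{-(x_i-\mu_{ci})^2 / 2\sigma_{ci}^2}.$$

A window's class is the majority vote of the per-feature decisions, either
over *all* 335 features or only those whose truth/lie training
distributions differ at the 5% (*stat-95*) or 1% (*stat-99*) level of a
two-sample test. Evaluation is leave-one-interviewee-out cross-validation,
so reported detection rates always refer to unseen subjects. On the study
corpus this style of analysis yields rates around 60–65%, against a 50%
chance level.

The `experiments` module reproduces the systematic analyses: train/test
crossings between session kinds, the window-length sweep, per
feature-type / window-type / body-part breakdowns, the top-k
most-significant-features sweep, per-feature ranking, and a measurement
noise simulation that perturbs test features by $r$ times their training
standard deviation.

## Worked example

```sh
python examples/03_classify_loocv.py
```

builds a 20-interviewee synthetic corpus whose liars move more (sway and
gesture rate doubled) and prints:

```
all      rate 100.00%  mean selected features  335.0 / 335
stat-95  rate 100.00%  mean selected features  323.8 / 335
stat-99  rate 100.00%  mean selected features  321.0 / 335
confusion (% of windows, rows = actual truth/lie, cols = guessed):
[[50.  0.]
 [ 0. 50.]]
```

The planted effect is deliberately far stronger than real interview
behavior, so the cross-validated rate saturates at 100% and nearly all 335
window features pass the stat-95 filter; with the multiplier set to 1.0
(no effect) the same pipeline scores at chance (~50%). The other examples
show corpus generation and I/O (`01`), feature extraction for a single
session (`02`), and the window-length/top-k/noise sweeps (`04`). A thin
CLI wraps the same functions: `bodycues simulate | extract | crossings |
sweep-windows | sweep-topk | rank-features | breakdowns | noise`.

## Using the published corpus

The motion-capture corpus this analysis was designed around is public
(`github.com/sophievanderzee/To-freeze-or-not-to-freeze`). It is not
redistributed here. To analyze it, convert each session to the native CSV
dialect (one row per frame, `<Joint>_x,_y,_z` columns in canonical order —
see `src/bodycues/data/skeleton.yaml`) or supply a YAML column-mapping
dialect to `read_session`, write a manifest
(`path,interviewee_id,session_kind,condition`), and point
`bodycues.read_manifest` or any CLI verb's `--manifest` at it. The
reproduction test in `tests/test_acceptance.py` expects the prepared
manifest at `data/to-freeze-or-not-to-freeze/manifest.csv`.

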