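# Methods

## Problem setting

A DLD device separates particles by size: below the array's critical
diameter they zigzag along streamlines toward one side of the outlet
manifold, above it they are bumped laterally toward the other. The
recording analysed here covers the 12 outlet channels — a stack of
horizontal channels separated by dark wall lines — filmed by a
high-speed camera with flow running left→right. The tool answers two
questions per video: *how many particles left through each outlet*, and,
given flow rate and particle size, *which separation mode the run
exhibits*.

## Vision pipeline

### Skew estimation and removal

Walls are near-horizontal lines, so frame tilt is estimated as the mean
angle-from-horizontal of probabilistic-Hough segments (Canny edges,
Hough normals restricted to ±15° around vertical). The mean is
unweighted; to keep it unbiased the detector only accepts segments at
least half the image width long — shorter fragments track the stair
steps of anti-aliased edges and have angles biased toward zero (with a
25 %-width minimum the estimate of a 2.0° fixture came out 1.72°; at
50 % it is 1.99°).

De-skewing iterates estimate → rotate → re-estimate until the residual
is within a tolerance (default 0.5°, max 5 iterations). Rotation is
about the frame center with the output cropped to the largest
axis-aligned interior rectangle, so no fill pixels reach the edge
detectors; each iteration re-rotates the *original* frame by the running
total so crops do not compound. Damping rule: when a cumulative rotation
request exceeds twice the first correction in magnitude, 1.5× the first
correction is applied instead (replacing, not adding to, the request);
oscillating estimates therefore cannot run away. Non-convergence is
reported in the result object, not raised.

### Observation window and walls

Horizontal bounds come from template matching: two small reference
images mark the upper and lower ends of the outlet array, each is
located by normalized cross-correlation (best-match upper-left corner,
confidence floor 0.5), and the window's left bound is the mean of the
two matched columns with the right bound one mean-template-width
further. The templates-average rule is one reading of an ambiguous
convention and is isolated in `locate_horizontal_bounds` should a
per-side rule be wanted. Without templates the full width is used.

Vertical bounds are the extreme rows touched by Hough segments inside
the column bounds; a span under 5 rows is rejected as degenerate (a
single wall yields two Canny flanks ~2 rows apart). The window is padded
by 4 rows so the outermost walls keep both intensity transitions inside
the crop.

Wall detection pools a multiset of row votes — one vote per Canny edge
pixel plus one per row covered by each Hough segment — sorts the unique
rows, and splits groups wherever the inter-row gap exceeds
`gap_threshold` (default 3 rows). Each group's most-voted row is a wall;
ties go to the smaller row, which makes the result deterministic and
order-independent. Channel *i* spans `(wall[i−1], wall[i]]`, 1-based,
top→bottom.

### Particle counting

The background is the zeroth frame with any blob-detected region
replaced, row by row, by the mean of that row's non-blob pixels (a fully
blob-covered row falls back to the global non-blob mean and is flagged).
Excluding the blob pixels from the row mean is deliberate: including
them biases the patch toward the particle it is meant to erase. The
construction is idempotent.

Counting then runs over strictly consecutive frame pairs:
`D_t = max(max(I_t−B,0) − max(I_{t−1}−B,0), 0)`. The clamped double
subtraction removes the static scene and the previous particle
positions, leaving the newly occupied ones. Dark-on-bright recordings
are handled by inverting intensities first (`particle_polarity` flag).

Blob extraction mimics a threshold-sweep detector: the difference image
is binarised at each level of `intensity_threshold_range` (default
10→220 step 10), 8-connected components are filtered by area and by
circularity `4πA/P² ≥ 0.6`, and per-threshold centroids are greedily
merged within 5 px; a blob must appear at ≥ 2 thresholds to count. The
default area window derives from the nominal particle diameter and the
µm/px scale: half to four times the projected disk area.

Repeat suppression (row tolerance 1 px, centroids rounded to 0.1 px):
a current centroid is **new** when its row is farther than the tolerance
from every previous-pair centroid row, or when it coincides *exactly*
with a previous centroid — a stationary repeat cannot be a real particle
in a moving flow, so it is treated as a new arrival (the aggressive
reading; `filter_new_particles` keeps the rule table in one place if the
conservative alternative is ever wanted). Anything else — same row
within tolerance, position changed — is the same particle advected
downstream and is suppressed. Duplicates within a pair are collapsed
before classification. The known blind spot: two particles co-present
on the same row are indistinguishable from a repeat and count once.

Summaries report per-channel counts, percentages over the *assigned*
total (so they always sum to 100 % when anything was assigned, even if
some detections fell outside the wall span), the grand total, and the
per-particle table (frame, row, col, channel).

## Mode classification

Features per run: flow rate (mL/min), particle size (µm), and the 12
outlet fractions — fractions rather than raw counts so the features are
invariant to the number of injected particles, and non-negative, which
complement naive Bayes requires. KNN and SVM-RBF standardize features on
each split's training fold (14 mixed-unit dimensions would otherwise be
scale-dominated); CNB uses raw features to preserve non-negativity. SVM
uses C = 1.0 with automatic kernel width; all knobs are exposed.

Stratified 5-fold CV: each family is fitted per split and scored on the
held-out fold; KNN sweeps k = 2…55 (capped at the training-fold size)
and keeps the smallest k attaining the split's maximum. The persisted
model is refit on the best split's training data — selection on test
folds is optimistic by construction, so all five split accuracies are
stored in the model metadata where the optimism is visible. Ties among
splits go to the lowest index. Evaluation reports a 3×3 confusion matrix
(zigzag/mixed/bumped order) with per-class precision, recall, f1, and
accuracy.

## Synthetic fixtures

`generate_dld_video` renders what the pipeline assumes: a bright field
with 13 dark wall lines (12 channels of 30 px at default), anti-aliased
bright disks (radius 6 px ≈ a 10–15 µm particle at ~1 µm/px) advecting
left→right at constant rows, Gaussian sensor noise clipped to [0, 255],
and a global skew applied last. Frame 0 is particle-free unless
`frame0_particles` stamps static disks to exercise background patching.
Ground truth records per-channel counts, trajectories, wall rows, and
the applied skew; everything is determined by `(config, seed)`.

Two scheduling constraints keep the fixture inside the method's stated
operating envelope rather than hiding its limits: a row slot is reused
only after its previous occupant has fully exited (co-row co-present
particles are the rule set's blind spot), and entries within one channel
are staggered ≥ 2 frames so neighbouring-row disks never overlap into a
single blob. The default advection of 14 px/frame exceeds the particle
diameter — the operator-matched frame rate the counting method assumes —
so each difference image contains full disks, not crescents.

What the fixture does *not* emulate: pillar-wake optics, defocus,
illumination drift, particle-size polydispersity, in-window lateral
migration, or compression artifacts. Passing tests therefore demonstrate
the algorithmic contract (no double counting, correct assignment,
geometry recovery), not robustness to every optical artifact of a real
recording.

`generate_mode_dataset` draws flow rates uniformly from the device's
0.5–4.0 mL/min operating range, ties particle size to mode (10 µm
zigzag, 15 µm mixed, 20 µm bumped), and confines each mode's Dirichlet
outlet profile to a disjoint 4-outlet band (bumped → outlets 1–4, mixed
→ 5–8, zigzag → 9–12, numbering top→bottom); `noise_sd` bleeds mass
across bands. At zero noise the classes are separable by construction,
which is the regime in which all three families reach 100 % CV accuracy.

## Problem sizes and numerical choices

The acceptance run analyses twelve videos of 50–200 particles
(≈ 60–170 frames each, 430×320 px) — sized so the full recomputation
finishes in minutes while every particle still transits the full window.
Centroids are rounded to 0.1 px before duplicate collapse; wall-group
ties and split-accuracy ties break toward the smaller index; division by
zero in percentages is guarded (all-zero summary). Rotation uses
bilinear interpolation with clipping back to uint8.

## Known limitations

- Counting accuracy degrades when advection per frame is much smaller
  than the particle diameter (difference crescents fail the circularity
  filter) — match the frame rate to the flow, as the method assumes.
- The repeat rule set cannot separate co-row, co-present particles.
- Wall detection expects near-horizontal walls after de-skew; curved or
  strongly defocused walls are out of scope.
- Persisting the best-CV-split model is test-set selection; treat its
  headline accuracy as optimistic and consult the stored per-split
  accuracies.
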