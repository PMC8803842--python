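# Methods

## Input model

A trial is a fixed-camera overhead recording of one dam and one displaced
pup in the home cage, already tracked: per frame, 14 body parts (nose,
ear_left, ear_right, spine1, spine2, spine3, tail_base for each animal)
with x, y pixel coordinates and a tracking likelihood in [0, 1], in the
three-header-row CSV dialect of DeepLabCut exports. Frame rate is supplied
by trial metadata (recordings vary between 10 and 30 fps and the dialect
does not carry it). Frames are indexed from 0 and the time of frame *t* is
*t*/fps seconds, so all latencies are unambiguous. Two fixed regions of
interest are defined per video: the *nest* (simple polygon around the
nesting site) and the *core nest* (circle around the pups' position).
Boundary points count as inside both shapes — nest edges are exactly where
scoring disagreements concentrate, so the convention is explicit.

## Tracking quality control

Pose estimators occasionally emit impossible locations or movements. Both
outlier criteria derive from the median frame-wise nose–spine1 distance
*m*, computed per animal so the pup's smaller body gets a proportionally
smaller criterion:

* movement outlier: displacement from the part's last accepted location
  > 2.5 *m* (factor configurable);
* location outlier: distance > 4 *m* from at least two other body parts of
  the same animal (same-animal comparison, so dam–pup separation can never
  trigger corrections).

Replacement is the part's last accepted location — causal carry-forward
with no look-ahead. A single movement-then-location sweep is not
necessarily stable (a location replacement can re-expose a movement
violation against a neighbouring frame), so the two passes are iterated to
a fixed point (capped at 25 sweeps; in practice 2–3). Consequences:
re-applying the correction makes zero changes, and the output never
contains a frame-to-frame displacement above the movement criterion. A
frame-0 outlier has no accepted predecessor; it is kept and flagged.
Likelihoods pass through untouched — the criteria are purely geometric —
but an optional confidence floor filter (carry-forward below a likelihood
threshold, default off) is available.

Carry-forward restores a jumped part to the *previous frame's* location,
so sub-pixel restoration is a property of the mechanism only when the
underlying motion is itself sub-pixel per frame; the jump-recovery checks
therefore run on near-stationary scripted trials (0.15 px wander,
0.1 px jitter), where ≥ 95% of injected jumps (≥ 3× the movement
criterion, rate 0.01 per part-frame) are restored to within 1 px.

## Calibration

Pixel coordinates are standardised to millimetres with the scale
`reference_mm / ‖landmark_a − landmark_b‖`, using the span between the
home-cage lid hinges (265 mm on a Type-II cage) as the in-frame reference.
The ROI is scaled by the same factor so occupancy is unit-invariant.
Double scaling is an error, enforced by a unit tag on the track that also
survives file round-trips.

## Feature registry

The classifiers consume a deterministic, versioned feature registry
computed from the corrected millimetre track and the ROI: per-animal
centroids; per-part frame displacement and per-animal mean movement;
animal extent (sum of pairwise within-animal part distances — a posture
measure that oscillates during digging); dam-nose↔pup-centroid and
centroid↔centroid distances with their absolute and signed rates of change
(the signed closing rate separates approach from withdrawal); nest and
core-nest occupancy flags and centroid distances; and centred rolling
mean/median/std of every base feature over 0.2, 0.5 and 1.0 s windows
(converted to frames, minimum 1, edge-replicated padding). Windows are
specified in seconds so 10–30 fps recordings are comparable. ROI-relative
columns are included for all behaviors by default with a switch to drop
them (digging is the behavior whose classification depends on nest
position; the others are position-independent). The registry maps every
column to a formula string; its hash is recorded in trained bundles and
verified at prediction time. Classifiers trained here are procedure-
compatible, not weight-compatible, with previously distributed model
files: the recipe is reproducible, opaque binaries are not.

## Classifiers

Per behavior (approach, carry, digging) a binary random forest with 2000
trees, entropy split criterion, sqrt feature subsampling and minimum leaf
size 1. Training uses a stratified 75:25 train/test split; the majority
(absent) class of the *training* portion is randomly undersampled keeping
⌊ratio × n_present⌋ absent frames, so the hold-out keeps the natural class
balance for threshold selection. The discrimination threshold is the
candidate (unique held-out probabilities ∪ a 0.01-step grid, restricted to
(0, 1)) maximising present-class F1; since F1 as a function of the
threshold is a step function with breakpoints at the observed
probabilities, this candidate set attains the global optimum. Ties break
to the lowest threshold, favouring sensitivity. A frame is present iff its
probability ≥ threshold. Minimum-bout smoothing runs after thresholding:
maximal runs shorter than round(min_bout_ms/1000 × fps) frames (at least
one) are erased; smoothing never creates present frames, hence it is
idempotent and element-wise non-increasing. The fitted presets from the
original dam-pup dataset ship as named defaults — undersample ratio /
threshold / minimum bout: approach 8.5 / 0.47 / 500 ms, carry 16 / 0.47 /
200 ms, digging 2 / 0.24 / 1000 ms — and are dataset-specific starting
points, not universal constants. Seeds are mandatory and recorded in the
bundle manifest for bit-reproducible training.

## Retrieval scoring

An *entry* is a false→true transition of pup nest occupancy (any-part
rule); frame 0 counts as an entry when the trial starts occupied, but its
look-back window is empty and cannot qualify — a conservative choice for a
trial that should begin with the pup outside the nest. The look-back
window is left-closed, right-open: [entry − round(3 s × fps), entry),
clipped at frame 0; "before entering" is read strictly, so carry on the
entry frame itself does not count. All entries are scanned in order and
the first with ≥ 1 carry-positive frame in its window sets
retrieval_time_s = entry/fps; with none, the trial fails and receives the
maximum trial time (default 90 s), matching the manual convention. Carry
labels fed to the rule are post-smoothing. Per behavior the summary
reports latency to first frame (max trial time if never present), total
duration, and bout count.

## Evaluation

Manual and automated binary calls are cross-tabulated as a = both 0,
b = manual 1/predicted 0, c = manual 0/predicted 1, d = both 1. Accuracy
(a+d)/N carries an exact Clopper–Pearson interval in the beta-quantile
form (lower bound 0 at 0 successes, upper bound 1 at n successes). The
positive class defaults to label **0**: the published
sensitivity/specificity figures follow the convention of R's caret
package, whose first factor level (the absent/not-retrieved class) is
positive, so sensitivity = a/(a+c) and specificity = d/(b+d); passing
positive_label=1 swaps the two exactly. Every report records the
convention used. Rates are stored at full precision and rounded only for
display. Pearson correlations of per-video totals use the standard
product-moment definition.

## Synthetic trials

The generator's purpose is exercising the pipeline's logic and giving the
classifiers learnable structure, not simulating mouse biomechanics. Two
rigid 7-part body templates (pup scaled to 0.6 of the dam) follow a smooth
centroid/heading state — heading turn rate capped so a body sweep can
never mimic a tracking jump — across scripted, non-overlapping episodes:

* **idle**: Gaussian wander (dam 0.8 px/frame, pup 0.15 px/frame);
* **approach**: the dam travels toward the pup (default 50–70 mm/s);
  frames where she is actually closing distance carry the label, with a
  latch so arrival jitter cannot emit spurious one-frame bouts;
* **carry / retrieve**: the dam's nose rides within the coupling distance
  (10 mm) of the pup centroid while both translate toward the core nest
  (45–55 mm/s, chosen so the carried pup's per-frame step stays below half
  its movement criterion — see the correction limitation below); *retrieve*
  is a carry scripted to cross the nest boundary;
* **dig**: the dam holds near the nest with per-part sinusoidal motion
  (4 mm, 2 Hz);
* **nest_shift**: the pup translates into the nest with no carry label —
  the failure mode where a moved nest puts pup parts inside a stale ROI.

Default geometry mirrors the recording setup: 1280×720 px frame, lid
landmarks 530 px apart (calibration scale 0.5 mm/px), nest polygon and
core circle in one corner, pup start in the far corner. Default frame rate
is 10 fps, the low end of the recorded 10–30 fps range; 0.1 s resolution
resolves the shortest bout definition (200 ms) and the 3 s carry window.
Training scripts keep behavior prevalences (approach ≈ 9%, carry ≈ 3–6%,
digging ≈ 15%) inside the feasibility bounds of the preset undersampling
ratios. Tracking faults are layered on separately: per part-frame
teleports of a chosen multiple of the movement criterion (one frame,
uniform direction) and likelihood drops below 0.2, every injection
recorded with the displaced true location.

Ground truth is script-intent based: a trial counts as retrieved only when
the pup's first nest entry falls inside a scripted retrieve episode, so
agreement between the scoring rule and the ground truth is a genuine
recovery check, not a tautology; the closure property (ground truth equals
the rule applied to true occupancy + true carry) is asserted separately.

What the generator does **not** emulate: deformable bodies, occlusion
geometry (occlusion only drops likelihood), nest material moving, pup
vocalisation-driven kinematics, multiple pups, fractional-second fps
drift. Passing synthetic recovery therefore demonstrates the pipeline's
*logic* — criteria arithmetic, event rules, classifier plumbing — and
learnability of well-separated kinematic signatures; it does not certify
classifier accuracy on real video, which the published validation figures
(reproduced by the evaluation module from the shipped confusion matrices)
address instead.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 90 s trials at
10 fps (900 frames): 200 trials for the retrieval-rule property, 5 for
jump recovery, 10 train + 5 held-out for classifier recovery at the full
protocol hyperparameters (2000 trees). Threshold candidates are restricted
to (0, 1); probability-at-threshold counts as present; bout ends are
inclusive; Clopper–Pearson endpoints use scipy's beta quantiles (tail
equations hold to < 1e-8). Feature extraction is a pure function of
(track, ROI, fps, windows) — identical inputs give bit-identical output.

## Known limitations

* ROIs are fixed per trial; a dam that moves the nest mid-trial can
  defeat the occupancy rule (the carry look-back mitigates, and the
  nest-shift script exercises, exactly this case).
* Carry-forward correction can *freeze*: when an animal's true per-frame
  motion exceeds half its movement criterion, a corrected jump leaves the
  last-accepted anchor permanently behind the moving part (every
  subsequent frame is farther than the criterion from the stale anchor)
  until the animal slows down. The per-animal criteria (2.5× the median
  nose–spine1 distance, roughly a body length per frame) make this rare
  for real locomotion, but it is inherent to the scheme; the synthetic
  fault injector therefore never corrupts frame 0, whose value anchors
  the scan and is uncorrectable by definition.
* The feature registry is this package's own minimal, documented set; it
  is sufficient for the three behaviors here but is not the feature set
  of any external tool, and trained bundles are not interchangeable with
  externally distributed model files.
* The published digging sensitivity figure disagrees with its own
  confusion matrix arithmetic by 0.05 percentage points (81.75% computed
  vs 81.8% printed); this package reports the full-precision value
  computed from the matrix.
* Undersampling ratios are infeasible when ratio × n_present exceeds the
  available absent frames; the error reports both counts rather than
  silently sampling with replacement.
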