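# Methods

`ustrack` implements a cascade tracker for point landmarks (vessel
cross-sections and similar hypoechoic structures) in 2D B-mode liver
ultrasound sequences, together with a synthetic-data generator and the
evaluation protocol used to measure it. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## The tracking cascade

Tracking is per landmark and causal: the output at frame *t* uses only
frames ≤ *t*. Given the landmark position at frame *t−1*, each frame runs
four stages.

**1. Attention search-region regression.** A 100 × 100 px patch centered on
the previous position (zero-padded at image borders) is mapped by a small
convolutional network to a box delta

t_x = (x − x_a)/w_a, t_y = (y − y_a)/h_a, t_w = log(w/w_a), t_h = log(h/h_a)

decoded against the patch itself as the anchor. The training objective is
the squared error of the delta encodings of the predicted and ground-truth
boxes plus the mean squared intensity difference over the N intersection
pixels of the two boxes. Two points the objective leaves open were resolved
as follows: (a) "intersection pixels" are the overlap region of the two
boxes, each patch cropped and aligned to that overlap; when the boxes do not
intersect the image term is defined as 0 and flagged, so the box term still
drives learning; (b) the two terms are combined unweighted. During
gradient-based training the image term is evaluated and logged but treated
as a constant: differentiating it with respect to the box would require
spatial resampling machinery that the box term makes unnecessary at this
scale. The final layer of the attention head is zero-initialized, so an
untrained network returns its own anchor — the previous search region —
which is the correct "no information" behavior.

**2. Detection core.** Inside the (fixed-size, attention-positioned) search
region, a small backbone (three 3×3 conv + 2× pool stages) feeds a
two-level feature pyramid (strides 4 and 8). Sliding-window anchors are
generated on a 4 px stride grid and retained only if their IoU with the
search box exceeds 0.7; this is applied literally, which constrains window
sizes to be close to the search-box size (defaults 28/32/36 px for a 32 px
region). A proposal head scores and regresses each anchor's pooled (4×4
bilinear ROI-sampled) features; the top-K proposals are re-pooled and pass
through three heads:

* **classification** — binary landmark/background scores trained with the
  large-margin hinge
  max{0, γ + (f_o − f_t)/(ε + ‖∇_l f_o − ∇_l f_t‖₂)},
  summed over supervised layers l (deep supervision) and samples. Gradients
  ∇_l f are taken with respect to layer-l activations in closed form (the
  head is linear-ReLU-linear), and the denominator is held constant during
  backpropagation — a first-order treatment that keeps the hinge a simple
  scaled margin. γ defaults to 1.0 (unspecified in the source method),
  ε = 1e-6. The supervised layers are the head trunk and the hidden
  classification activation.
* **box regression** — only the center is regressed; the box size is fixed
  at 20 × 20 px. The loss is smooth-L1 on the center deltas.
* **mask** — per-pixel binary classification on a 10 × 10 grid over the
  proposal box with a large-margin (angular) softmax: the true-class logit
  ‖W_y‖‖x‖φ(θ_y) uses φ(θ) = (−1)^k cos(mθ) − 2k on θ ∈ [kπ/m, (k+1)π/m],
  plus λ‖W‖²_F. Defaults m = 2, λ = 1e-4. The mask ground truth — never
  defined for point-annotated data — is a filled disk of radius 5 px around
  the landmark. φ is continuous and strictly decreasing on [0, π], checked
  numerically.

The three head losses combine as L = 0.2·L_cls + 0.2·L_mask + 0.6·L_box,
weighting box regression highest. The proposal stage itself is trained with
standard objectness cross-entropy and smooth-L1 anchor regression — routine
detector plumbing kept outside the weighted combination.

**3. LSTM temporal heads.** Each proposal's pooled feature vector,
concatenated with its scaled center motion relative to the previous record,
passes through a standard LSTM cell (input/forget/cell/output gates,
c_t = f⊙c_{t−1} + i⊙g, h_t = o⊙tanh c_t) over a window of up to five
consecutive frames (truncated at sequence start). Two fully connected heads
on the final hidden state produce a refined classification score (sigmoid,
hence bounded in [0, 1]) and a refined center. The mask head deliberately
bypasses the LSTM so that abrupt motion cannot corrupt pixel
classification. During training the windows are built from the proposals
with greatest overlap with the ground-truth box across five consecutive
frames (top-2 per frame by default); since annotations are sparse
(10%–13% of frames), positions between annotated frames are linearly
interpolated to center the training search regions — a pseudo-dense
supervision choice documented here because the data protocol leaves it open.

**4. Similarity-based selection.** Every refined proposal is a candidate
(x_k, S_k). The tracker picks

x_t = argmax_k [ γ·S_k + (1−γ)·1/(1 + e^{‖x_k − x_{t−1}‖}) ], γ = 0.5.

The source expression is printed as an argmin, but the text calls it a
combined score in [0, 1] and the proximity term is larger for nearer
candidates, so minimizing would prefer distant low-score candidates;
maximization is the only reading consistent with the surrounding text, and
a `printed_argmin` flag preserves the literal behavior for audit. Distances
are in pixels by default (the exponent saturates within ~40 px; a
millimetre option exists). Ties break by higher raw score, then smaller
distance. If the detector yields no proposals the tracker keeps the
previous position, flags the frame, and leaves the temporal memory
untouched. After selection the search box is re-centered on the chosen
position, which keeps the 100 × 100 predefinition valid under drift.

## Numerical engine

No deep-learning framework is used: the networks run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`ustrack.autodiff`), with convolution via im2col and bilinear ROI sampling
expressed as multiplication by a constant sampling matrix. All forward
passes are deterministic functions of (input, weights); training is
single-threaded and reproducible bit-for-bit under a fixed seed. The pure
numpy loss implementations in `ustrack.losses` are the reference; the
differentiable training graphs mirror them and are tested for agreement,
including a finite-difference gradient check of the angular-margin softmax.

## Training

Three stages, each with Adam and an epoch-mean stopping rule (stop when the
epoch-to-epoch decrease falls below 1e-3, or at the epoch cap):

1. attention, on pairs of (patch at previous annotated position, box at
   current annotated position) plus same-frame identity pairs, with ±3 px
   center jitter;
2. detector, on search regions jittered ±4 px around annotated positions
   (positives) and background regions ≥ 14 px from any landmark
   (negatives);
3. temporal heads, on precomputed frozen-detector proposal windows
   (positive landmark tracks and static background tracks).

Two profiles exist. The `paper` profile keeps the documented defaults
(learning rate 1e-6, up to 1000 epochs per stage) and is not expected to
converge in a desk-scale session. The `scaled` profile — used by all tests
and the demo — uses learning rate 1e-3, epoch caps 40/30/30, batch size 8,
a 32 px search region, and the tiny backbone described above. The attention
network trains separately first (input/target pairs are defined
independently of the detector); a joint fine-tune flag exists but defaults
off.

## Synthetic data

The generator emulates the salient properties of free-breathing liver
ultrasound at desk scale, not its physics (no point-spread-function or
curved-array modeling):

* **speckle**: a Rayleigh-distributed multiplicative field smoothed with a
  σ = 1 px Gaussian — the conventional first-order B-mode texture
  surrogate;
* **landmarks**: 1–5 radially smooth hypoechoic Gaussian disks
  (multiplicative attenuation 1 − c·exp(−r²/2σ²), σ = radius/2), default
  radius 4.5 px and contrast 0.85, so the landmark is the darkest local
  structure in its neighborhood;
* **confounders**: rendered from the *same* template as landmarks and
  placed ≥ 3 radii from every landmark trajectory, so appearance alone
  cannot separate them — the property the selection rule is tested
  against;
* **shadows**: an optional vertical band multiplying intensity by a factor
  in (0, 1);
* **motion**: per-landmark sinusoid (amplitude 2–6 px, period 2.5–5 s,
  random phase, vertical amplitude scaled by 0.6 because respiration moves
  the liver mostly along one axis) plus slow drift (±0.3 px/s) and, with
  probability 0.3, one instantaneous jump of 3–6 px (cough/sneeze-like;
  jumps are position steps, not velocity changes, as the simplest abrupt
  event);
* **acquisition**: frame rates in [6, 30] Hz, pixel spacing in
  [0.27, 0.77] mm (defaults 15 Hz, 0.5 mm), 8-bit frames;
* **annotations**: max(1, ⌊fraction·n_frames⌋) frames with fraction in
  [0.10, 0.13], frame 0 always included.

The full simulation is a pure function of its configuration (including the
seed). What passing tests on this data do **not** show: robustness to real
speckle decorrelation, out-of-plane motion, probe pressure deformation,
unseen landmark appearance classes, or scanner-specific artifacts — the
known failure modes of appearance-based trackers on real data.

## Evaluation protocol

The frame error is the Euclidean distance between prediction and ground
truth in millimetres. (The source formula prints a squared norm, but its
reported sub-millimetre magnitudes against a 2 mm clinical bound are only
consistent with the plain distance; a `squared` flag preserves the printed
form.) Errors are computed only on frames that carry ground truth.
Summaries report mean, sample standard deviation (n−1; defined as 0 for
n = 1), the 95th percentile with linear interpolation between order
statistics, and the maximum. Group aggregation pools frame-level records
(not a mean of means); "AVE.MaxError" is interpreted as the mean of
per-landmark maximum errors, since it is otherwise undefined.
Cross-validation splits use a seeded shuffle into near-equal folds (24
sequences → 5, 5, 5, 5, 4). Confidence intervals for the mean error use the
Student-t distribution, default level 0.99; coverage is verified by Monte
Carlo.

Coordinates are 0-based (x, y) = (column, row) with pixel centers at
integer coordinates throughout; the annotation reader exposes an
`origin_offset` so 1-based data can be ingested without guessing.

## Problem sizes of the shipped experiment

The end-to-end demo trains on 3 simulated sequences and evaluates on 2
held-out sequences of 60 frames each (64 × 64 px, 2 landmarks, 2
confounders per sequence), chosen so the whole
simulate → train → track → evaluate loop is a single-CPU desk-scale run.
Reported quantities are the attention containment fraction (predicted
search box contains the truth, given a patch centered at the previous
frame's true position) and held-out tracking errors in px and mm; the 2 px
bound used in tests is the desk-scale analogue of the 2 mm clinical
acceptability bound.

## Known limitations

* The scaled backbone is far smaller than a production mask R-CNN; it is
  sized for CPU training on 32 px search regions.
* The anchor IoU > 0.7 retention rule, applied against the search box as
  stated, restricts proposals to near-concentric windows; candidate
  diversity therefore comes from the box-regression and temporal heads, not
  from spatially spread anchors.
* Landmarks are tracked independently; there is no cross-landmark data
  association or online model updating.
* The `paper` hyperparameter profile is documented but not validated here:
  convergence at learning rate 1e-6 over 1000 epochs requires the original
  external data and compute scale.
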