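# Methods

This note documents the models, numerical choices and limitations of
`t1qc`: what is simulated, what is fitted, how the classifier and its
attention supervision are constructed, and what the tests do and do not
demonstrate.

## Signal model and relaxation fitting

Every pixel of a simulated acquisition follows the signed three-parameter
inversion recovery `S(TI) = A − B·exp(−TI/T1*)` at the seven inversion
times. Magnitude reconstruction and polarity restoration are deliberately
out of scope: the signed model is sufficient to create the R² artefact
phenomenology that quality control reads. The default inversion times
{100, 180, 260, 1100, 1180, 2100, 3180} ms and tissue T1 values
(myocardium 950 ms, blood 1600 ms, background 300 ms) are plausible 1.5 T
stand-ins and fully configurable; equilibrium amplitudes are 1.0 / 1.4 /
0.3 signal units with perfect inversion (B = 2A), and Gaussian noise of
standard deviation `noise_sd` (default 0.02, i.e. SNR 50 relative to
myocardium) is added per pixel and frame.

`fit_relaxation` profiles T1* out of the least-squares problem: for fixed
T1* the optimal (A, B) is a closed-form 2×2 solve (variable projection), so
the fit reduces to a 1-D minimisation per pixel. A 40-point log-spaced grid
over [30, 8000] ms acts as a multi-start that avoids local minima, followed
by 40 vectorised golden-section iterations, giving T1* to well below
10⁻³ ms on noiseless data at about 0.2 s per 160² map. R² = 1 − SS_res/SS_tot
is clipped to [0, 1]; pixels with a constant time-series are degenerate and
get R² = 0 and T1 = NaN. With three parameters fitted to seven samples,
pure-noise pixels still reach moderate R² by chance (median ≈ 0.35,
~20% above 0.5); the quality map works through the *contrast* between
well-fitted tissue (R² ≈ 1) and corrupted pixels, not through any absolute
threshold, and the tests assert exactly that distributional separation.

## Phantom geometry and motion

A case is an annular "myocardium" (inner radius ≈ 0.17·size, outer ≈
0.30·size, small seeded jitter) around a blood-pool disk on a low-signal
background, divided into six 60° AHA-ordered sectors counter-clockwise from
a configurable RV-insertion angle. Motion is rigid per-frame translation
(bilinear interpolation, edge padding); the reference frame never moves,
and shifts above a quarter of the field of view are rejected as
non-physical. T1 and R² maps are always refit from the (possibly shifted)
stack, exactly as for acquired data.

Ground-truth labels are generative: segment *s* is positive iff some frame
moved at least 2 px **and** the segment's mean R² dropped at least 0.05
against the motion-free fit (both thresholds configurable). This ties the
label to the observable a human reader scores — a visible dark band — rather
than to the hidden motion parameters. Two consequences shaped the dataset
generator:

* Default shift magnitudes scale with the field of view (6.25–12.5% of
  `image_size`, about 1–2 cm at clinical resolution), because a fixed
  pixel shift that darkens a 64² segment noticeably is diluted in the
  mean R² of a 160² segment.
* `artefact_prevalence` is the rate of *expressed* artefacts: a case
  assigned to the artefact arm redraws its schedule (deterministically,
  bounded at 12 attempts) until at least one segment fires, since roughly
  15% of random rigid schedules fail to depress any segment past the
  labelling threshold. Positive cases therefore always show the phenotype
  their labels claim.

## Classifier

The network follows the canonical 34-layer residual design with block
counts [3, 4, 6, 3] and stage widths [64, 128, 256, 512] (quarter-width
64² variant for CPU experiments). The first convolution is replaced by
three streams — 3×3 2D kernels on the T1 and R² images, a 3×3×3 3D kernel
on the IRW stack, each stride 1 with 3 output channels — whose outputs are
concatenated along the depth axis into a crop×crop×9 volume. A 3×3×3
max-pool (stride 2) and the stride-2 first blocks of stages 2–4 reduce
depth as 9→5→3→2→1 (ceil mode); a convolution becomes 2D exactly when its
incoming depth is 1. Every convolution is followed by batch normalisation
and ReLU; projection shortcuts (1×1×1 convolution + BN) appear only where
shape changes. Global average pooling feeds one fully connected layer with
a sigmoid per segment. Depth audit: 1 (stem level) + 32 block convolutions
+ 1 fully connected = 34, with shortcuts and pooling uncounted as usual.

Inputs are cropped to `crop_size`² (default 160, the LV centroid at index
crop/2) and normalised: T1 divided by a fixed 3000 ms so absolute T1
semantics survive, R² used as-is, IRW frames jointly z-scored per case.
Degenerate T1 pixels (NaN) become 0 before normalisation.

Ambiguities resolved as design choices: the stem emits 3 channels per
stream before depth-wise fusion (channel-wise fusion would triple the
fused depth instead; the depth-9 reading matches the stated 160×160×9
fusion); the whole-image machine score for ROC purposes is the maximum of
the six segment scores, the continuous analogue of the "any segment
positive" rule; agreement binarises machine scores at 0.5 (exposed as a
flag) since the ROC sweeps all thresholds anyway.

## Attention maps and supervision

Saliency is the input gradient of one segmental score, combined pixel-wise
as |∂l/∂T1| + |∂l/∂R²| + Σ_frames |∂l/∂IRW|. Grad-CAM weights each last-layer
feature map by the spatial mean of ∂l_s/∂A_k, sums, applies ReLU, and
bilinearly upsamples (align-corners) to input resolution.

For supervision, the per-segment maps are built from the same forward pass
(one cheap backward per segment, stopped at the feature maps) and compared
to the segment masks by pixel-mean binary cross-entropy, summed over the
six segments; the total objective is `L_att + α·L_cl` with α = 1 and
`L_cl` the mean binary cross-entropy of scores against labels. Numerical
conventions:

* Cross-entropy needs [0, 1] but Grad-CAM is unbounded above, so a map is
  divided by its per-sample maximum only when that maximum exceeds 1, then
  clamped to [ε, 1−ε], ε = 10⁻⁶. Maps already in [0, 1] pass through
  unchanged, which gives the exact ln 2 closed form for a uniform-½ map.
* The normalising maximum and the neuron weights `w_k` are treated as
  constants of the forward pass: gradients flow into the feature maps `A`
  (and from there into all shared parameters), not through the weight
  computation itself. This first-order construction is the engine's native
  mode; it preserves the supervision signal (a gradient step provably
  decreases L_att, and trained models concentrate attention inside the
  scored segment) while avoiding second-order differentiation.
* Pixel reduction uses the mean, not the sum, so the attention term's scale
  is independent of crop size.

## Training protocol

Adam with batch 16 and initial learning rate 10⁻³; the rate drops by a
factor of 10 when the validation loss fails to improve by more than 10⁻⁴
for 30 consecutive epochs, and training stops after 50 epochs without
improvement (both patiences configurable); the model at the best validation
loss is kept. Augmentation draws one rotation ~U(−5°, 5°) and translation
~U(−10, 10) px per sample per epoch, applied identically to the nine images
and the six masks (bilinear, zero fill, masks re-binarised at 0.5).
Validation tracks the same objective as training (total loss for the
attention arm). Cross-validation assigns cases to five near-equal folds,
stratified by whole-image label to stabilise prevalence at small cohort
sizes (switchable off); repetition *r* tests on fold *r*, validates on fold
*r+1*, trains on the rest. Deterministic mode (seeded generators, serial
data order) is the default, and identical seeds reproduce histories
bit-for-bit.

## Evaluation

Agreement is the percentage of matching binary decisions at per-segment
(all 6n), per-image (OR rule on both tables) or per-segment-index level.
ROC curves come from thresholding scores over [0, 1]; AUC uses midrank tie
handling and equals the Mann–Whitney pairwise statistic (verified against
an O(n²) oracle). The DeLong test compares two correlated AUCs through
placement values computed with midranks; identical score tables give p = 1
exactly, a degenerate variance with a nonzero AUC difference is flagged
rather than forced to a number, and pooled per-segment comparisons treat
the 6n decisions as independent — a statistical caveat inherited from the
reporting convention it mirrors.

## Numerical engine

All network computation runs on a small reverse-mode autodiff engine over
NumPy arrays: float32 working precision (float64 switchable for oracle
tests), im2col convolutions executed as batched BLAS matmuls, explicit
backward rules for convolution, max-pooling, batch normalisation and
bilinear upsampling, and a backward pass that can stop at designated
tensors so feature-map gradients are extracted without touching the layers
below. Gradient correctness is tested against central finite differences
with a two-step-size screen that discards probes sitting on ReLU/max-pool
kinks, where the true derivative is discontinuous.

## Scale of the shipped experiments

The CPU experiments use the quarter-width network on 64² phantoms:
200-case cohorts (60% expressed-artefact prevalence, 8 px shifts,
noise 0.02), 140/30/30 train/validation/test splits, 8 epochs at learning
rate 3×10⁻³. Augmentation stays on by default for full-scale training but
is disabled in these desk-scale experiments: the simulated cohort already
randomises geometry and pose across cases, and at 200 cases the extra
input jitter slows convergence without improving held-out agreement.
Under these conditions the
classifier reaches ≈90% held-out per-segment agreement with the generative
labels, and attention supervision raises the fraction of Grad-CAM mass
inside the scored segment severalfold over the baseline arm. The same code
paths scale to the full-size configuration (160² crops, full width,
5-fold protocol) unchanged.

## Limitations

The phantom is deliberately minimal: no realistic cardiac anatomy, no
through-plane motion, no ECG mistriggering, off-resonance banding or
parallel-imaging artefacts, and rigid whole-frame displacement only.
Passing tests therefore demonstrate that the pipeline recovers *generative*
labels tied to R² dark bands, not clinical reader performance; absolute
agreement numbers on synthetic data are not comparable to agreement with
human operators on patient data. The LV centroid is an input (no contour
detection), apical slices and RV-insertion inference are out of scope, and
the classifier detects motion only — other artefact families are neither
simulated nor labelled.
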