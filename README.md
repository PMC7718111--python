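# t1qc — automated motion-artefact quality control for cardiac T1 mapping

Quantitative cardiac T1 mapping (e.g. ShMOLLI) reconstructs a T1 map by
fitting the mono-exponential inversion recovery

    S(TI) = A − B · exp(−TI / T1*)

pixel-wise across 7 inversion-recovery-weighted (IRW) images acquired in one
breath-hold. The fit assumes perfect pixel-to-pixel correspondence between
frames; breathing or poor ECG triggering displaces frames, mixes tissues
with different relaxation into single pixels, and shows up as dark bands in
the per-pixel R² (coefficient-of-explained-variance) map. In clinical
practice a trained reader inspects the T1 map, the R² map and the raw
frames, and scores each of the six AHA mid-ventricular myocardial segments
for motion artefact.

`t1qc` automates that reading. It provides, as a library for image-analysis
researchers:

* **A segment-level classifier** — a multi-stream 34-layer 3D residual
  network. Three convolutional stems (2D on the T1 map, 2D on the R² map,
  3D on the 7-frame IRW stack) are fused into a 160×160×9 volume; residual
  blocks down-sample it with stride-2 convolutions, switching from 3D to 2D
  kernels once the depth axis is exhausted (9→5→3→2→1); global average
  pooling and a fully connected layer with sigmoids emit six per-segment
  motion scores in [0, 1].
* **Attention supervision** — during training, per-segment Grad-CAM maps
  `W_s = ReLU(Σ_k w_k A_k)` (channel weights `w_k` = global-average-pooled
  gradients `∂l_s/∂A_k` on the last convolutional feature maps `A`) are
  penalised by pixel-wise cross-entropy against the segment masks `I_s`,

      L = L_att + α · L_cl,   L_att = Σ_s CE(W_s, I_s),   α = 1,

  teaching the network to base each segmental score on the scored segment
  rather than on distractors elsewhere in the thorax.
* **Attention visualisation** — saliency maps (input gradients `∂l_s/∂I`)
  and Grad-CAM maps at input resolution.
* **A synthetic phantom simulator** — annular myocardium phantoms whose
  pixels follow the inversion-recovery signal model, with rigid per-frame
  displacements that corrupt the fit and produce the low-R² dark bands;
  per-segment ground-truth labels are generative (a segment is positive when
  a frame moved ≥ 2 px *and* its mean R² dropped ≥ 0.05).
* **Evaluation tools** — per-segment / whole-image agreement percentages
  (whole image positive ⇔ any segment positive), ROC-AUC with Mann–Whitney
  tie handling, the DeLong test for correlated AUCs, and pairwise
  observer-agreement matrices.
* **A training protocol** — Adam (batch 16, initial learning rate 1e-3,
  ÷10 on validation-loss plateaus with patience 30, early stopping after 50
  epochs without improvement), on-the-fly augmentation (±5° rotation,
  ±10 px translation about the LV centre), and 5-fold cross-validation
  (train on 3 folds / validate on 1 / test on 1, rotated so every case is
  scored once by a model that never saw it).

The network, attention machinery and training loop run on a compact NumPy
reverse-mode autodiff engine built into the package (`t1qc.autodiff`), so
the whole pipeline needs only the scientific Python stack.

## Worked example

Fit recovery (from `examples/02_fit_relaxation.py`):

```
noise_sd=0.00: recovered T1* =  950.000 ms (true 950.0), mean R2 = 1.0000
noise_sd=0.05: recovered T1* =  962.014 ms (true 950.0), mean R2 = 0.9991
noise_sd=0.20: recovered T1* = 1017.617 ms (true 950.0), mean R2 = 0.9861
```

Noiseless inversion-recovery data is recovered exactly (R² = 1, the "all
white" quality map); noise broadens the T1 estimate and lowers R².

Simulated motion (from `examples/01_simulate_phantoms.py`):

```
case_00002: max shift  7.3 px, myocardial mean R2 0.944, worst segment R2 0.924, labels [1, 0, 1, 1, 0, 1]
case_00003: max shift  8.0 px, myocardial mean R2 0.915, worst segment R2 0.829, labels [0, 1, 1, 1, 1, 0]
case_00004: max shift  0.0 px, myocardial mean R2 0.999, worst segment R2 0.999, labels [0, 0, 0, 0, 0, 0]
```

Displaced frames depress R² in the segments they touch; those segments are
the positive labels the classifier learns to reproduce.

Training both arms at desk scale (from `examples/05_train_and_compare.py`;
140 cases, quarter-width 64² network, 8 epochs, a few minutes on one CPU):

```
baseline: trained 8 epochs, best val loss 0.124
  held-out per-segment agreement: 93.1%
  held-out per-segment ROC-AUC:   0.971
  grad-cam mass in scored segment: 0.039

attention: trained 8 epochs, best val loss 1.056
  held-out per-segment agreement: 90.3%
  held-out per-segment ROC-AUC:   0.950
  grad-cam mass in scored segment: 0.145

DeLong comparison of the correlated AUCs: ΔAUC = -0.021, p = 0.016
```

Both arms classify the synthetic artefacts near ceiling; the reliable effect
of attention supervision at this scale is the several-fold concentration of
Grad-CAM attention inside the scored segment (0.039 → 0.145, against a
segment occupying ~0.03 of the image).

The remaining examples cover scoring a case (`03`), attention maps (`04`),
and observer agreement matrices (`06`). A command-line interface wraps the same stages:

```bash
t1qc simulate --n 100 --prevalence 0.4 --seed 1 --out-dir runs/data
t1qc train --data-dir runs/data --out-dir runs/model --fold all
t1qc evaluate --scores runs/model/scores.csv --out runs/metrics.json
t1qc attend --case-dir runs/data/cases/case_00002 --checkpoint runs/model/model_rep0.npz --out-dir runs/maps
t1qc run-all --seed 1 --out-dir runs/demo    # all stages, both training arms
```

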