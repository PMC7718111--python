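"""Train the classifier with and without attention supervision and compare.

A miniature version of the full experiment: simulate a cohort with strong
motion artefacts, train the quarter-width network twice (baseline
classification loss only; classification + attention supervision), and
compare held-out agreement, ROC-AUC and the DeLong p-value, plus how much
Grad-CAM mass each arm puts inside the scored segment.

Takes a few minutes on one CPU.  Increase n_cases/max_epochs for a closer
look at the effect.
"""

import numpy as np

from t1qc import AcquisitionConfig, NetworkConfig, TrainConfig, generate_dataset
from t1qc.attention import attention_mass_fraction, supervised_attention_maps
from t1qc.evaluation import agreement, binarise, delong_compare, roc_auc
from t1qc.training import predict_scores, prepare_samples, train_fold

cases, _ = generate_dataset(
    140, 0.6, AcquisitionConfig(image_size=64, noise_sd=0.02),
    seed=11, shift_range=(8.0, 8.0),
)
samples = prepare_samples(cases, 64)
idx = np.random.default_rng(0).permutation(140)
train_idx, val_idx, test_idx = list(idx[:96]), list(idx[96:116]), list(idx[116:])
test = [samples[i] for i in test_idx]
labels = np.stack([s.labels for s in test])


def target_mass(model):
    scores, feats = model.forward([s.model_input for s in test],
                                  training=False, capture_features=True)
    maps = supervised_attention_maps(scores, feats, out_size=64)
    model.zero_grad()
    return float(np.mean([
        attention_mass_fraction(maps[s].data[b], smp.masks[s])
        for s in range(6) for b, smp in enumerate(test)
    ]))


arm_scores = {}
for arm, supervised in (("baseline", False), ("attention", True)):
    cfg = TrainConfig(batch_size=16, initial_lr=3e-3, max_epochs=8,
                      plateau_patience_epochs=6, early_stop_patience_epochs=8,
                      augment=False, seed=101)
    model, hist = train_fold(samples, train_idx, val_idx, NetworkConfig.tiny(),
                             cfg, supervised_attention=supervised, seed=101)
    scores = predict_scores(model, test)
    arm_scores[arm] = scores
    print(f"\n{arm}: trained {len(hist)} epochs, "
          f"best val loss {hist.best_val.iloc[-1]:.3f}")
    print(f"  held-out per-segment agreement: "
          f"{agreement(binarise(scores), labels):.1f}%")
    print(f"  held-out per-segment ROC-AUC:   "
          f"{roc_auc(scores.ravel(), labels.ravel()).auc:.3f}")
    print(f"  grad-cam mass in scored segment: {target_mass(model):.3f}")

cmp = delong_compare(arm_scores["attention"].ravel(),
                     arm_scores["baseline"].ravel(), labels.ravel())
print(f"\nDeLong comparison of the correlated AUCs: "
      f"ΔAUC = {cmp.delta:+.3f}, p = {cmp.p_two_sided:.3f}")
print("On synthetic data both arms classify near ceiling, so the AUC "
      "difference is small and its sign varies run to run; the reliable "
      "effect of attention supervision here is the several-fold increase of "
      "Grad-CAM mass inside the scored segment.")
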