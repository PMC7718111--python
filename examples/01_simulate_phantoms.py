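"""Simulate ShMOLLI-like phantoms with and without motion artefacts.

Generates a small labelled cohort and prints what the R² quality map shows:
motion-free myocardium fits the mono-exponential recovery almost perfectly
(R² ≈ 1, "all white"), while rigid frame displacements depress R² in the
affected segments — the dark bands a human reader scores.
"""

import numpy as np

from t1qc import AcquisitionConfig, generate_dataset

acq = AcquisitionConfig(image_size=64, noise_sd=0.02)
cases, labels = generate_dataset(12, artefact_prevalence=0.5, config=acq, seed=7)

print(labels.to_string(index=False))
print()
for case in cases[:6]:
    myo = case.segment_masks.annulus
    seg_r2 = [case.r2_map[m].mean() for m in case.segment_masks.masks]
    print(
        f"{case.case_id}: max shift {case.motion.max_shift:4.1f} px, "
        f"myocardial mean R2 {case.r2_map[myo].mean():.3f}, "
        f"worst segment R2 {min(seg_r2):.3f}, labels {case.labels.tolist()}"
    )
print(
    "\nPositive segments coincide with depressed per-segment mean R2: the "
    "labels are generative, tied to the same observable a human scores."
)
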