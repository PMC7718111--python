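"""Score the six AHA segments of one case with the multi-stream classifier.

Builds the quarter-width 64² variant of the 34-layer residual network, crops
a simulated case around the LV centroid, and prints the six segmental motion
scores (each in (0, 1); an untrained network scores near chance).
"""

import numpy as np

from t1qc import (
    AcquisitionConfig,
    MotionSchedule,
    NetworkConfig,
    apply_motion,
    build_classifier,
    crop_and_stack,
    generate_phantom,
)

config = NetworkConfig.tiny()
net = build_classifier(config, seed=0)
print(f"network: {net.layer_count()} layers, "
      f"feature maps {config.stage_channels[-1]}x{config.feature_size}²")

case = generate_phantom(AcquisitionConfig(image_size=64), seed=3)
shifts = [(0.0, 0.0)] * 7
shifts[3] = (8.0, 0.0)
shifts[4] = (0.0, 8.0)
shifts[5] = (-6.0, 6.0)
moved = apply_motion(case, MotionSchedule(per_frame_shift=tuple(shifts)))

model_input = crop_and_stack(moved, crop_size=64)
scores = net.predict(model_input)
print("ground-truth labels:", moved.labels.tolist())
print("machine scores:     ", np.round(scores, 3).tolist())
print(
    "\nEach score is the sigmoid output for one AHA segment. This network is "
    "untrained (its scores are arbitrary and typically saturated); see "
    "05_train_and_compare.py for the trained behaviour."
)
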