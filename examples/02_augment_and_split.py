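"""Dirichlet augmentation and the calibration/validation splits.

Expands 80 replicate spectra into 1352 artificial samples by convex
combination within each concentration class, then forms the two stratified
splits used by the linear models (800/552) and the network (1148/204).
"""

import numpy as np

import ftirq

raw = ftirq.generate_dataset("melamine", noise=ftirq.NoiseConfig(seed=42))
aug = ftirq.dirichlet_augment(raw, ftirq.DirichletConfig(alpha=1.0, seed=7))
print(f"{raw.n_samples} replicates -> {aug.n_samples} artificial samples "
      f"({aug.n_samples // len(aug.classes())} per concentration class)")

# convexity: every artificial spectrum stays inside its class envelope
for c in raw.classes():
    reps = raw.intensities[raw.concentration == c]
    mixed = aug.intensities[aug.concentration == c]
    inside = np.all(mixed >= reps.min(0) - 1e-9) and np.all(mixed <= reps.max(0) + 1e-9)
    assert inside
print("all augmented spectra lie inside their class [min, max] envelope")

cal, val = ftirq.stratified_split(aug, ftirq.SplitPlan(seed=1))
print(f"linear-model split: {cal.n_samples} calibration / {val.n_samples} validation "
      f"(100/69 per class)")

cal2, val2 = ftirq.stratified_split(
    aug, ftirq.SplitPlan(scheme="cnn_1148_204", seed=1)
)
print(f"network split:      {cal2.n_samples} calibration / {val2.n_samples} prediction")
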