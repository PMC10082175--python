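"""The training objective, term by term.

The density branch is supervised by the masked multi-scale structural loss
SL* (1 - SSIM across average-pooled scales, with near-zero-density cells
masked out); the segmentation branch by a class-balanced cross-entropy CE
(background weighted by h = 0.5); the total objective is SL* + 0.1 * CE.
"""

import numpy as np

from densicount import (
    LossConfig,
    masked_structural_loss,
    ssim_index,
    structural_loss,
    total_loss,
    weighted_cross_entropy,
)

rng = np.random.default_rng(0)
# sparse target: a few density bumps on an otherwise empty map, like a
# sum-pooled ground-truth density of a sparsely populated tile
target = np.zeros((16, 16))
cells = rng.choice(256, size=12, replace=False)
target.ravel()[cells] = rng.uniform(0.3, 2.0, size=12)
pred = np.clip(target + 0.15 * rng.standard_normal((16, 16)), 0, None)
mask = (target > 1e-3).astype(float)

cfg = LossConfig()
print(f"SSIM(pred, target)        = {ssim_index(pred, target, cfg):.4f}")
print(f"SSIM(target, target)      = {ssim_index(target, target, cfg):.4f}")
print(f"SL  (3 pooling levels)    = {structural_loss(pred, target, cfg):.4f}")
sl_star = masked_structural_loss(pred, target, mask, cfg)
print(f"SL* (masked)              = {sl_star:.4f}")

seg_pred = np.clip(mask * 0.9 + 0.05, 0, 1)
ce = weighted_cross_entropy(seg_pred, mask, cfg)
print(f"CE  (h = 0.5)             = {ce:.4f}")
print(f"total = SL* + 0.1 * CE    = {total_loss(sl_star, ce, cfg):.4f}")
# A perfect density prediction gives SSIM 1 at every scale, hence SL* = 0.
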