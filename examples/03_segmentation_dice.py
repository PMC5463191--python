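"""Intensity-based layer segmentation scored against the ground truth.

For each annotated layer, a 3-component Gaussian mixture is fitted to the
layer's grey values and to those of its two neighbors; pixels in the union
of the three regions are then assigned by maximum likelihood, and the
automatic layer is compared with the ground-truth one via the Dice index
(1 = perfect overlap).  More averaging -> better-separated intensity
distributions -> higher Dice.
"""

import numpy as np

from octqc import (
    LABEL_NAMES,
    LAYER_LABELS,
    NoiseConfig,
    SceneConfig,
    average_frames,
    generate_clean_scan,
    generate_frames,
    image_dice,
    rasterize,
)

scene = SceneConfig(width=256, depth=240)
clean, boundaries = generate_clean_scan(scene)
mask = rasterize(boundaries, depth=scene.depth, band=scene.band)
noise = NoiseConfig.clear_media()

print("frames averaged -> per-layer Dice (clear media)")
for m in (2, 16):
    stack = generate_frames(clean, m, noise, seed=np.random.SeedSequence([3, m]))
    scores, _ = image_dice(average_frames(stack), mask, seed=0)
    per_layer = "  ".join(
        f"{LABEL_NAMES[lab]}={scores[k]:.3f}"
        for k, lab in enumerate(LAYER_LABELS)
    )
    print(f"  M={m:3d}   {per_layer}   image={np.nanmean(scores):.3f}")
print("Layers with low contrast to a neighbor (GCL+IPL, INL) profit most:")
print("their intensity distributions overlap until noise is suppressed.")
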