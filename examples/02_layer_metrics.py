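"""Per-layer quality metrics on one averaged scan, clear vs opaque media.

Computes per-layer SNR and the neighbor-layer Cohen's d for a 16-frame
average under both media conditions.  Cohen's d is the absolute standardized
mean difference against the layers above and below (averaged); larger values
mean the layer's intensity distribution is better separated from its
neighbors, i.e. easier to delineate.
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
    image_quality,
    rasterize,
)

scene = SceneConfig(width=256, depth=240)
clean, boundaries = generate_clean_scan(scene)
mask = rasterize(boundaries, depth=scene.depth, band=scene.band)

for name, noise in (("clear media (postoperative)", NoiseConfig.clear_media()),
                    ("opaque media (preoperative)", NoiseConfig.opaque_media())):
    stack = generate_frames(clean, 16, noise, seed=np.random.SeedSequence([7]))
    report = image_quality(average_frames(stack), mask)
    print(f"{name}, 16 frames averaged")
    for k, label in enumerate(LAYER_LABELS):
        print(f"  {LABEL_NAMES[label]:8s} SNR={report.snr[k]:6.2f}   "
              f"d={report.d[k]:6.2f}")
    print(f"  image    SNR={report.image_snr:6.2f}   d={report.image_d:6.2f}\n")
print("Opacity attenuates signal and inflates noise, so every layer scores")
print("lower preoperatively at the same averaging setting.")
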