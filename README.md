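# octqc — image-quality analysis for averaged OCT B-scans

Spectral-domain OCT scanners suppress speckle noise by averaging repeated
B-scans of the same retinal location, but heavier averaging costs
acquisition time and can blur detail — and its benefit depends strongly on
the optical media: an eye with cataract scatters light, attenuating signal
and inflating noise. `octqc` is a library for quantifying that trade-off.
It implements three annotation-based image-quality measures, a synthetic
layered-retina B-scan generator with known ground truth, and a study
pipeline that reproduces the classic two-visit (opaque vs clear media),
seven-setting averaging protocol (2, 4, 8, 16, 32, 48, 96 frames).

It is aimed at OCT methodologists and reading-center analysts who need
objective, reproducible quality numbers for choosing averaging settings.

## The measures

For each of five annotated retinal layers (NFL, GCL+IPL, INL, OPL, ONL),
delimited by six boundary curves, with grey values of layer *l* having mean
μ_l, sample SD σ_l and count N_l:

- **SNR** per layer: `SNR = μ_l / σ_l`. Under uncorrelated noise it grows
  as √M with the number M of averaged frames; a frame-correlated noise
  floor caps it.
- **Cohen's d** between neighboring layers L1, L2:
  `d = |μ_l1 − μ_l2| / sqrt(((N_l1−1)σ_l1² + (N_l2−1)σ_l2²) / (N_l1+N_l2−2))`.
  Each layer's d averages its values against the layer above and below
  (the vitreous and a sub-ELM band flank the outermost layers).
- **Segmentation Dice**: a 3-component Gaussian mixture is fitted to the
  intensity distribution of each layer and its two neighbors; pixels are
  classified by maximum likelihood, and the automatic layer S_auto is scored
  against the manual one S_manual with
  `Dice = 2|S_auto ∩ S_manual| / (|S_auto| + |S_manual|)`.

Image-level values are unweighted means over the five layers.

## Worked example

```sh
python examples/01_simulate_and_average.py
```

```
frames averaged -> image SNR (clear media)
  M=  1   SNR=  5.77
  M=  2   SNR=  7.21
  M=  4   SNR=  8.70
  M=  8   SNR=  9.74
  M= 16   SNR= 10.50
  M= 32   SNR= 11.02
  M= 96   SNR= 11.25
```

SNR roughly doubles from 1 to 4 frames (the √M law) but gains only ~7%
from 16 to 96 frames: the frame-correlated noise floor has taken over, so
under clear media ~16 frames already buy nearly all the attainable quality.
The other examples show per-layer SNR/d under both media conditions
(`02_layer_metrics.py`), segmentation Dice versus averaging
(`03_segmentation_dice.py`), and a small end-to-end study with the per-eye
matching analysis (`04_study_matching.py`), where every synthetic eye needs
≥ 16 — typically 48–96 — preoperative frames to match the postoperative
16-frame quality.

A thin CLI wraps the same pipeline for batch use:

```sh
octqc simulate --config cfg.yaml --out data/
octqc analyze  --data data/ --out results.csv
octqc report   --results results.csv --out report/
```

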