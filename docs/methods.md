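# Methods

## Scope and model

`octqc` quantifies how B-scan frame averaging affects OCT image quality
under clear and opaque optical media. Because no public image set
accompanies the protocol it emulates, the package ships a synthetic
generator whose statistical structure matches the assumptions of the three
quality measures; all pipeline results in this repository are computed on
that synthetic data, with exact ground-truth layer boundaries.

### Scene model

A B-scan is a `depth × width` grey image in [0, 1] (512 columns by default,
one per A-scan; depth 496 rows — scan depth in pixels is not standardized,
so this default is an assumption). Six boundary curves (low-order
polynomial plus an optional Gaussian foveal dip, rounded half-up to pixel
rows) delimit five layers: NFL, the GCL+IPL composite (no boundary internal
to GCL/IPL is annotated), INL, OPL, ONL. Each region, including the
vitreous above, a sub-ELM band below (default 20 rows) and the remaining
background, is rendered at a constant clean reflectivity. Default
reflectivities (vitreous 0.05, NFL 0.72, GCL+IPL 0.40, INL 0.26, OPL 0.48,
ONL 0.14, sub-ELM 0.42, background 0.08) follow the qualitative
bright/dark alternation of real SD-OCT B-scans; the 0.14–0.26 contrast
between the darkest adjacent pair keeps segmentation non-trivial at low
averaging. Real retinal texture, vessels and shadowing are not modelled, so
absolute metric values are not comparable to clinical scans — only their
behaviour across averaging settings and media conditions is.

### Acquisition model

Each frame of a stack of M repeats is

    frame_i = jitter(clean · opacity · speckle_i + u_i) + c,   clipped to [0, 1]

- `u_i`: per-frame iid Gaussian noise, scale `sigma_u` (× `noise_inflation`
  when opacity < 1);
- `c`: one Gaussian field of scale `sigma_c` drawn **once per stack** and
  shared by all frames. Averaging cannot remove it, which is precisely what
  produces the quality plateau at high M;
- `speckle_i`: optional unit-mean multiplicative gamma noise (off by
  default — the additive Gaussian term already carries the averaging
  behaviour of interest);
- `jitter`: optional per-frame sub-pixel axial shift (default 0), an
  opt-in mechanism for the detail-smoothing cost of heavy averaging.

The averaged scan is the pixel-wise arithmetic mean (the device-internal
averaging arithmetic is unknown; the mean is the natural assumption).
Scans export as 8-bit single-channel TIFF (×255, rounded half-up), which
models the saturation/quantization of exported clinical scans. Within a
layer the clean image is constant, so the spatial SD measured by the SNR
metric is exactly the residual noise scale
`sqrt((opacity-inflated sigma_u)² / M + sigma_c²)` away from clip limits.

### Media-condition defaults

Opacity is modelled phenomenologically (no physical cataract model):
attenuation of the mean signal plus inflation of the per-frame noise.
Defaults were chosen once from the closed form above so that the synthetic
study reproduces the qualitative clinical pattern — clear media saturate by
~16 frames while opaque media keep improving through 96, and each eye needs
at least 16 (typically 48–96) opaque-media frames to match its own
clear-media 16-frame quality:

| parameter | clear (post) | opaque (pre) |
|---|---|---|
| sigma_u | 0.06 | 0.06 |
| noise_inflation | 1 | 4 |
| sigma_c | 0.035 | 0.012 |
| opacity | 1.0 | 0.85 |

The opaque-media correlated floor is smaller than the clear-media one: the
model attributes opacity-induced degradation almost entirely to the
uncorrelated (speckle-like) term, which must dominate the floor for quality
to keep rising at 96 frames — a large shared floor under attenuated signal
would cap opaque-media quality below the clear-media 16-frame level for
every eye, contradicting the per-eye matching pattern the simulation is
meant to exhibit.

### Study design

13 eyes × 2 conditions × settings (2, 4, 8, 16, 32, 48, 96). Per eye, one
seeded random effect perturbs reflectivities (±4% multiplicative, clipped
to [0.02, 0.95]) and boundary offsets (shared shift SD 1.2% of depth,
per-boundary SD 0.3%, with a minimum spacing guard), giving the between-eye
heterogeneity the matching analysis needs. All 14 scans of an eye share one
boundary set, modelling follow-up alignment to the identical position.
Acquisition order per visit is randomized and recorded (it has no effect on
synthesis). All randomness flows from one seed through spawned
`numpy.random.SeedSequence` children.

## Metrics

- SNR and Cohen's d use the sample SD (divisor N−1) throughout: the pooled
  d formula is explicitly (N−1)-weighted, and consistency is preferred for
  SNR, where the convention is unstated.
- d is reported as a magnitude (absolute value), so averaging a layer's
  upper and lower d is meaningful.
- The outermost layers take the vitreous and the sub-ELM band as
  pseudo-neighbors, keeping the two-neighbor averaging rule literal for all
  five layers; `image_quality(..., one_sided_outer=True)` falls back to
  one-sided d instead.
- Image-level values are unweighted means over the five annotated layers
  (the vitreous is not included). Degenerate regions (empty, or
  zero-variance where variance is required) yield flagged NaNs and a
  logged warning; image means are taken over the available layers. Gaps
  never propagate as zeros.
- Summary curves normalize SNR and d per eye to the 2-frame baseline
  before averaging over eyes; Dice, already on [0, 1], is averaged raw.
- The matching analysis compares raw within-eye values (normalization
  would cancel for d and Dice but alter the SNR comparison); ties count as
  achieving the target, and `None` records that no setting up to 96
  sufficed.

## Segmentation

Per layer, 3-component Gaussian mixtures are fitted (scikit-learn EM:
seeded k-means init, tol 1e-6, ≤200 iterations, variance floor 1e-8 — these
EM settings are fixed for determinism, not estimated) to the grey values of
the layer and of its two (pseudo-)neighbors, taken from the manual mask of
the same scan being evaluated: the procedure is deliberately
fit-and-classify on one image, with no train/test split. Classification is
restricted to the union of the three manual regions — an unconstrained
full-image classification would conflate non-adjacent layers of similar
reflectivity — and assigns each pixel by maximum mixture density, ties
going to the anatomically upper label (arbitrary but deterministic). Each
of the five overlapping three-way problems is solved independently; region
models are fitted once per scan and shared, with per-region seeds that make
layer-by-layer and whole-image calls bit-identical. Fits on regions larger
than 2000 pixels use a seeded subsample of that size: a 1-D,
three-component density estimate is stable at that sample size, and it
bounds the per-scan cost of the slow EM tail on near-Gaussian layer data.
Regions under 30 pixels fall back to a single Gaussian (logged); constant
regions yield a flagged degenerate single-component model.

## Rasterization conventions

0-based coordinates; each layer occupies the half-open row band
[b_k, b_{k+1}) per column, guaranteeing an exact partition (verified by
pixel-count conservation). Boundaries are stored as integers — annotation
clicks land on pixels — and the generator rounds its real-valued curves
half-up at export. A sub-ELM band overrunning the image bottom is truncated
with a warning rather than an error.

## Problem sizes used in tests and the acceptance script

The √M law is verified on a 128×100 flat-layer phantom with mid-range
reflectivities (no clipping), 50 replicate stacks at M ∈ {1, 4, 16, 64};
the plateau contrast on a 128×120 default scene with 20 replicates at
M ∈ {16, 96}; the separability sweep on a 96×100 phantom with adjacent
contrast Δ ∈ {0, 0.05, 0.1, 0.2, 0.4} at noise 0.05. The end-to-end
determinism check runs the full default 13-eye, 182-scan study twice at
256×240; the acceptance script runs it once at the full default 512×496.
These sizes were chosen so Monte-Carlo error is far below the asserted
tolerances while each check runs in minutes on one core.

## Known limitations

- Constant within-layer reflectivity means SNR measures pure noise; real
  layers have texture, so clinical SNR values are lower and layer-dependent.
- No modelling of cataract subtypes, vessel shadows, motion artifacts
  beyond axial jitter, or the photoreceptor/RPE complex (left unannotated,
  as in the emulated protocol).
- The clinical dip of postoperative d at 32 frames (attributed to ocular
  surface changes after surgery) is deliberately not reproduced.
- Passing tests demonstrate internal consistency and the qualitative
  averaging/media behaviour on synthetic data, not performance on real
  scans.
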