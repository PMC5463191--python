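"""Per-layer intensity-model segmentation and Dice scoring.

Each annotated layer is segmented by (1) fitting a three-component Gaussian
mixture to the grey-value distribution of the layer and of its two anatomical
neighbors (the manual annotation of the same scan provides the training
pixels — there is no train/test split), then (2) classifying every pixel in
the union of the three manual regions to the layer whose mixture density at
its grey value is maximal.  Ties break to the anatomically upper label, which
is arbitrary but deterministic.  Agreement of the automatic layer with the
manual one is scored with the Dice index 2|A∩B|/(|A|+|B|).

The outermost layers use the vitreous and a fixed sub-ELM band as
pseudo-neighbors, mirroring the metrics module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .annotations import (
    LABEL_NAMES,
    LAYER_LABELS,
    SUB_ELM,
    VITREOUS,
    LayerMask,
    PixelSample,
    layer_pixels,
)
from .errors import ConfigurationError, DegenerateRegionError
from .image import BScan

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityGMM", "SegmentationResult",
    "fit_layer_gmm", "classify_region", "segment_layer", "dice", "image_dice",
]

# EM settings fixed for determinism.
_EM_TOL = 1e-6
_EM_MAX_ITER = 200
_VARIANCE_FLOOR = 1e-8
_MIN_GMM_SAMPLES = 30
_DEFAULT_MAX_FIT_SAMPLES = 2_000


@dataclass
class IntensityGMM:
    """A fitted Gaussian-mixture intensity model for one region."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    label: int | None = None
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")  # mean per-sample log-likelihood
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.maximum(
            np.asarray(self.variances, dtype=float), _VARIANCE_FLOOR
        )
        if not np.isclose(self.weights.sum(), 1.0):
            raise ConfigurationError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ConfigurationError("mixture weights must be >= 0")

    @property
    def n_components(self) -> int:
        return self.weights.size

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Log mixture density at each grey value in ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = (
            np.log(self.weights)[:, None]
            - 0.5 * np.log(2.0 * np.pi * self.variances)[:, None]
            - 0.5 * (x[None, :] - self.means[:, None]) ** 2 / self.variances[:, None]
        )
        return logsumexp(comp, axis=0)


def fit_layer_gmm(
    sample: PixelSample | np.ndarray,
    seed: int,
    max_fit_samples: int = _DEFAULT_MAX_FIT_SAMPLES,
) -> IntensityGMM:
    """EM-fit a 3-component mixture to a region's grey values.

    Deterministic given ``seed`` (seeded k-means initialization, tolerance
    1e-6, at most 200 iterations, variance floor 1e-8).  Regions with fewer
    than 30 pixels fall back to a single Gaussian; constant regions yield a
    flagged degenerate single-component model.  Very large regions are fitted
    on a seeded subsample capped at ``max_fit_samples`` pixels.
    """
    label = sample.label if isinstance(sample, PixelSample) else None
    values = (
        sample.values if isinstance(sample, PixelSample)
        else np.asarray(sample, dtype=float)
    ).ravel()
    if values.size == 0:
        raise DegenerateRegionError("cannot fit a mixture to an empty region")
    if np.ptp(values) == 0.0:
        logger.warning("constant region %s: degenerate single-component model",
                       LABEL_NAMES.get(label, label))
        return IntensityGMM(
            weights=[1.0], means=[float(values[0])],
            variances=[_VARIANCE_FLOOR], label=label, degenerate=True,
        )
    if values.size < _MIN_GMM_SAMPLES:
        logger.warning(
            "region %s has %d < %d pixels: single-Gaussian fallback",
            LABEL_NAMES.get(label, label), values.size, _MIN_GMM_SAMPLES,
        )
        mean = float(values.mean())
        var = float(values.var(ddof=1)) if values.size > 1 else _VARIANCE_FLOOR
        model = IntensityGMM(
            weights=[1.0], means=[mean], variances=[var], label=label
        )
        model.log_likelihood = float(model.logpdf(values).mean())
        return model
    rng = np.random.default_rng(seed)
    fit_values = values
    if values.size > max_fit_samples:
        fit_values = rng.choice(values, size=max_fit_samples, replace=False)
    gm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        tol=_EM_TOL,
        max_iter=_EM_MAX_ITER,
        reg_covar=_VARIANCE_FLOOR,
        init_params="kmeans",
        n_init=1,
        random_state=int(np.uint32(seed)),
    )
    with warnings.catch_warnings():
        # slow EM tail on near-Gaussian data; the flag is kept on the model
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(fit_values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    model = IntensityGMM(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        variances=gm.covariances_.reshape(3)[order],
        label=label,
        converged=bool(gm.converged_),
        n_iter=int(gm.n_iter_),
    )
    model.log_likelihood = float(model.logpdf(fit_values).mean())
    return model


def classify_region(
    img: BScan | np.ndarray,
    region: np.ndarray,
    models: list[tuple[int, IntensityGMM]],
) -> np.ndarray:
    """Maximum-likelihood label assignment within a region.

    ``models`` lists (label, model) pairs in anatomical top-to-bottom order;
    ties in density go to the first (upper) entry.  Returns an int raster the
    shape of the image with -1 outside the region.
    """
    arr = img.image if isinstance(img, BScan) else np.asarray(img, dtype=float)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise DegenerateRegionError("empty classification region")
    values = arr[region]
    ll = np.stack([m.logpdf(values) for _, m in models])
    # argmax returns the first maximal index, i.e. the upper label on ties
    winner = np.argmax(ll, axis=0)
    labels = np.array([lab for lab, _ in models])
    out = np.full(arr.shape, -1, dtype=np.int64)
    out[region] = labels[winner]
    return out


@dataclass
class SegmentationResult:
    """Outcome of segmenting one layer against its manual annotation."""

    target: int
    region: np.ndarray          # union of the three manual regions
    auto: np.ndarray            # pixels classified as the target layer
    manual: np.ndarray          # the manual target region
    dice: float
    models: dict[int, IntensityGMM] = field(default_factory=dict)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b|/(|a|+|b|) of two boolean pixel sets."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise DegenerateRegionError("Dice undefined for two empty sets")
    return 2.0 * int((a & b).sum()) / (na + nb)


def _region_seed(seed: int, label: int) -> int:
    """Stable per-region fitting seed; identical whether a region model is
    fitted via segment_layer or image_dice."""
    return int(
        np.random.SeedSequence([int(seed), int(label)]).generate_state(1)[0]
    )


def _neighbors(target: int) -> tuple[int, int]:
    if target not in LAYER_LABELS:
        raise ConfigurationError(f"{target} is not an annotated layer label")
    return target - 1, target + 1  # VITREOUS above L1, SUB_ELM below L5


def segment_layer(
    img: BScan | np.ndarray,
    mask: LayerMask,
    target: int,
    seed: int,
    models: dict[int, IntensityGMM] | None = None,
) -> SegmentationResult:
    """Fit-and-classify segmentation of one layer.

    Models are fitted on the manual pixels of the target and its two
    neighbors; classification is restricted to the union of those manual
    regions (an unconstrained full-image classification would conflate
    non-adjacent layers of similar reflectivity).  A degenerate (empty)
    neighbor yields a flagged NaN Dice rather than an abort.
    """
    above, below = _neighbors(target)
    regions = {lab: mask.region(lab) for lab in (above, target, below)}
    try:
        fitted = dict(models) if models else {}
        for lab in (above, target, below):
            if lab not in fitted:
                fitted[lab] = fit_layer_gmm(
                    layer_pixels(img, mask, lab), seed=_region_seed(seed, lab)
                )
    except DegenerateRegionError as exc:
        logger.warning("layer %s: %s — Dice flagged missing",
                       LABEL_NAMES[target], exc)
        empty = np.zeros(mask.labels.shape, dtype=bool)
        return SegmentationResult(
            target=target, region=empty, auto=empty,
            manual=regions[target], dice=float("nan"),
        )
    union = regions[above] | regions[target] | regions[below]
    assigned = classify_region(
        img, union, [(lab, fitted[lab]) for lab in (above, target, below)]
    )
    auto = assigned == target
    return SegmentationResult(
        target=target,
        region=union,
        auto=auto,
        manual=regions[target],
        dice=dice(auto, regions[target]),
        models={lab: fitted[lab] for lab in (above, target, below)},
    )


def image_dice(
    img: BScan | np.ndarray,
    mask: LayerMask,
    seed: int,
) -> tuple[np.ndarray, list[SegmentationResult]]:
    """Per-layer Dice for all five annotated layers plus their results.

    Region models are fitted once per region and shared across the five
    overlapping three-way problems; seeds depend only on (seed, region), so
    the outcome matches layer-by-layer calls to ``segment_layer``.
    """
    fitted: dict[int, IntensityGMM] = {}
    for lab in (VITREOUS, *LAYER_LABELS, SUB_ELM):
        try:
            fitted[lab] = fit_layer_gmm(
                layer_pixels(img, mask, lab), seed=_region_seed(seed, lab)
            )
        except DegenerateRegionError:
            pass  # handled per layer below
    results = []
    scores = np.full(5, np.nan)
    for k, lab in enumerate(LAYER_LABELS):
        res = segment_layer(img, mask, lab, seed=seed, models=fitted)
        results.append(res)
        scores[k] = res.dice
    if np.isnan(scores).any():
        logger.warning("missing Dice for %d layer(s); image mean over the rest",
                       int(np.isnan(scores).sum()))
    return scores, results
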