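"""Image-quality metrics: per-layer SNR and neighbor-layer Cohen's d.

SNR of a layer is mu/sigma of its grey values; Cohen's d between two
neighboring layers is the absolute standardized mean difference with the
pooled, (N-1)-weighted sample standard deviation.  Each annotated layer's d
is the average of its d against the layer above and the layer below; the
outermost layers use the vitreous and a fixed sub-ELM band as
pseudo-neighbors (a config switch falls back to one-sided d).  Image-level
values are unweighted means over the five annotated layers.

Both statistics are invariant under multiplying the image by a positive
constant; SNR (unlike d) is not invariant under additive offsets, since the
mean shifts while the standard deviation does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotations import (
    BELOW,
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
    "LayerStats", "QualityReport",
    "layer_stats", "snr_layer", "cohens_d_pair", "cohens_d_layer",
    "image_quality", "relative_to_baseline",
]


@dataclass(frozen=True)
class LayerStats:
    """Sufficient statistics of one layer's intensity distribution."""

    mean: float
    sd: float  # sample standard deviation, divisor n-1
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateRegionError("layer statistics require n >= 2")
        if self.sd < 0:
            raise ConfigurationError("standard deviation must be >= 0")


def layer_stats(sample: PixelSample | np.ndarray) -> LayerStats:
    """Mean, sample standard deviation and count of a pixel sample."""
    values = sample.values if isinstance(sample, PixelSample) else np.asarray(sample, dtype=float)
    if values.size < 2:
        raise DegenerateRegionError("need at least 2 pixels for layer stats")
    return LayerStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
    )


def snr_layer(stats: LayerStats) -> float:
    """Signal-to-noise ratio mu/sigma of one layer."""
    if stats.sd == 0:
        raise DegenerateRegionError(
            "zero-variance layer: SNR undefined (saturated/constant region)"
        )
    return stats.mean / stats.sd


def cohens_d_pair(a: LayerStats, b: LayerStats) -> float:
    """Absolute Cohen's d between two intensity distributions.

    d = |mu_a - mu_b| / sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a+n_b-2)).
    The absolute value makes d a separation magnitude, so that averaging the
    above/below values per layer is meaningful.
    """
    if a.n + b.n < 3:
        raise DegenerateRegionError("cohens_d_pair requires n_a + n_b >= 3")
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if pooled_var == 0:
        if a.mean == b.mean:
            return 0.0
        raise DegenerateRegionError(
            "zero pooled variance with unequal means: infinite separation"
        )
    return abs(a.mean - b.mean) / math.sqrt(pooled_var)


def cohens_d_layer(
    target: LayerStats,
    above: LayerStats | None,
    below: LayerStats | None,
) -> float:
    """Average of a layer's d against its neighbors above and below.

    Pass ``None`` for a missing neighbor to get the one-sided value; both
    missing is an error.
    """
    ds = [cohens_d_pair(target, nb) for nb in (above, below) if nb is not None]
    if not ds:
        raise DegenerateRegionError("layer d needs at least one neighbor")
    return float(np.mean(ds))


@dataclass
class QualityReport:
    """Per-scan quality summary: per-layer and image-level SNR, d, Dice.

    Per-layer arrays are ordered NFL, GCL+IPL, INL, OPL, ONL; missing
    (degenerate) layers carry NaN and are excluded from image-level means.
    """

    eye: str | None = None
    condition: str | None = None
    n_averaged: int | None = None
    snr: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    d: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    dice: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))

    @staticmethod
    def _mean(values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        if np.all(np.isnan(values)):
            return float("nan")
        return float(np.nanmean(values))

    @property
    def image_snr(self) -> float:
        return self._mean(self.snr)

    @property
    def image_d(self) -> float:
        return self._mean(self.d)

    @property
    def image_dice(self) -> float:
        return self._mean(self.dice)

    def value(self, measure: str, layer: int | None = None) -> float:
        arr = {"snr": self.snr, "d": self.d, "dice": self.dice}[measure]
        return self._mean(arr) if layer is None else float(arr[layer])


def _stats_or_none(
    img: BScan, mask: LayerMask, label: int
) -> LayerStats | None:
    try:
        return layer_stats(layer_pixels(img, mask, label))
    except DegenerateRegionError:
        return None


def image_quality(
    img: BScan,
    mask: LayerMask,
    one_sided_outer: bool = False,
) -> QualityReport:
    """Compute per-layer and image-level SNR and Cohen's d for one scan.

    With ``one_sided_outer=True`` the NFL and ONL use only their annotated
    neighbor instead of the vitreous / sub-ELM pseudo-neighbor.
    """
    region_stats: dict[int, LayerStats | None] = {
        label: _stats_or_none(img, mask, label)
        for label in (VITREOUS, *LAYER_LABELS, SUB_ELM)
    }
    report = QualityReport(
        eye=img.eye, condition=img.condition, n_averaged=img.n_averaged
    )
    for k, label in enumerate(LAYER_LABELS):
        st = region_stats[label]
        if st is None:
            logger.warning("degenerate layer %s: metrics flagged missing",
                           LABEL_NAMES[label])
            continue
        try:
            report.snr[k] = snr_layer(st)
        except DegenerateRegionError:
            logger.warning("zero-variance layer %s: SNR flagged missing",
                           LABEL_NAMES[label])
        above = region_stats.get(label - 1)
        below = region_stats.get(label + 1)
        if one_sided_outer:
            if label == LAYER_LABELS[0]:
                above = None
            if label == LAYER_LABELS[-1]:
                below = None
        try:
            report.d[k] = cohens_d_layer(st, above, below)
        except DegenerateRegionError:
            logger.warning("degenerate neighborhood of %s: d flagged missing",
                           LABEL_NAMES[label])
    return report


def relative_to_baseline(
    values: Mapping[int, float], baseline_m: int = 2
) -> dict[int, float]:
    """Normalize a per-setting series by its lowest-averaging baseline.

    Each value is divided by the same series' value at ``baseline_m`` (the
    2-frame scan by default), so the baseline maps to 1.0.
    """
    if baseline_m not in values:
        raise ConfigurationError(
            f"baseline setting M={baseline_m} missing from series"
        )
    base = values[baseline_m]
    if base == 0 or not np.isfinite(base):
        raise ConfigurationError("baseline value is zero or not finite")
    return {m: v / base for m, v in values.items()}
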