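"""Retinal layer-boundary annotations, their CSV format, and rasterization.

Six ordered boundary curves (vitreous/NFL, NFL/GCL, IPL/INL, INL/OPL,
OPL/ONL, ONL/ELM) delimit five annotated layers per column: NFL, the
GCL+IPL composite, INL, OPL and ONL.  No boundary internal to GCL/IPL is
annotated, so the five layers follow from the six listed boundaries.

Conventions: 0-based coordinates; each layer occupies the half-open row band
[b_k, b_{k+1}) per column, which guarantees a partition of the image with no
double counting.  Above the first boundary lies VITREOUS; a fixed-height band
below the last boundary is SUB_ELM (used as a pseudo-neighbor of the outer
nuclear layer); any remaining rows are BELOW background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundaryOrderError, ConfigurationError, DegenerateRegionError, FormatError
from .image import BScan

logger = logging.getLogger(__name__)

__all__ = [
    "VITREOUS", "L1", "L2", "L3", "L4", "L5", "SUB_ELM", "BELOW",
    "LAYER_LABELS", "LABEL_NAMES", "BOUNDARY_NAMES",
    "BoundarySet", "LayerMask", "PixelSample",
    "read_boundaries", "write_boundaries", "rasterize", "layer_pixels",
]

# Integer label codes, anatomically ordered top to bottom.
VITREOUS, L1, L2, L3, L4, L5, SUB_ELM, BELOW = range(8)

#: The five annotated layers, top to bottom.
LAYER_LABELS: tuple[int, ...] = (L1, L2, L3, L4, L5)

LABEL_NAMES: dict[int, str] = {
    VITREOUS: "VITREOUS",
    L1: "NFL",
    L2: "GCL+IPL",
    L3: "INL",
    L4: "OPL",
    L5: "ONL",
    SUB_ELM: "SUB_ELM",
    BELOW: "BELOW",
}

BOUNDARY_NAMES: tuple[str, ...] = (
    "vitreous/NFL", "NFL/GCL", "IPL/INL", "INL/OPL", "OPL/ONL", "ONL/ELM",
)

N_BOUNDARIES = 6
_BOUNDARY_COLUMNS = [f"b{i}" for i in range(1, N_BOUNDARIES + 1)]


@dataclass
class BoundarySet:
    """Six per-column boundary row positions for one B-scan.

    ``boundaries`` has shape (6, width); ``boundaries[k, c]`` is the first
    image row of the region below boundary k at column c.  Rows are 0-based
    integers and must be non-decreasing top to bottom at every column.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b.ndim != 2 or b.shape[0] != N_BOUNDARIES:
            raise FormatError(
                f"expected {N_BOUNDARIES} boundary rows, got shape {b.shape}"
            )
        self.boundaries = b.astype(np.int64)
        self.validate()

    @property
    def width(self) -> int:
        return self.boundaries.shape[1]

    def validate(self, depth: int | None = None) -> None:
        """Check per-column ordering and (optionally) the depth range."""
        b = self.boundaries
        if np.any(b < 0):
            col = int(np.argmax((b < 0).any(axis=0)))
            raise ConfigurationError(f"negative boundary row at column {col}")
        bad = (np.diff(b, axis=0) < 0).any(axis=0)
        if bad.any():
            raise BoundaryOrderError(int(np.argmax(bad)))
        if depth is not None and np.any(b >= depth):
            col = int(np.argmax((b >= depth).any(axis=0)))
            raise ConfigurationError(
                f"boundary row >= depth {depth} at column {col}"
            )

    def shifted(self, k: int) -> "BoundarySet":
        """Return a copy with every boundary moved down by ``k`` rows."""
        return BoundarySet(self.boundaries + k)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BoundarySet):
            return NotImplemented
        return np.array_equal(self.boundaries, other.boundaries)


@dataclass
class LayerMask:
    """Per-pixel layer labels (int8 raster, codes VITREOUS..BELOW)."""

    labels: np.ndarray
    band: int

    @property
    def depth(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of pixels carrying ``label``."""
        return self.labels == label

    def counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}


@dataclass
class PixelSample:
    """The multiset of grey values within one labelled region."""

    values: np.ndarray
    label: int

    @property
    def n(self) -> int:
        return self.values.size


def write_boundaries(bs: BoundarySet, path: str | Path) -> None:
    """Write a BoundarySet as CSV with columns column_index, b1..b6."""
    df = pd.DataFrame({"column_index": np.arange(bs.width, dtype=np.int64)})
    for k, name in enumerate(_BOUNDARY_COLUMNS):
        df[name] = bs.boundaries[k]
    df.to_csv(path, index=False)


def read_boundaries(path: str | Path) -> BoundarySet:
    """Read a boundary CSV; validates schema and per-column ordering."""
    df = pd.read_csv(path)
    missing = [c for c in ["column_index", *_BOUNDARY_COLUMNS] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.sort_values("column_index")
    if not np.array_equal(df["column_index"].to_numpy(), np.arange(len(df))):
        raise FormatError(f"{path}: column_index must enumerate 0..width-1")
    rows = df[_BOUNDARY_COLUMNS].to_numpy().T
    return BoundarySet(rows)


def rasterize(bs: BoundarySet, depth: int, band: int = 20) -> LayerMask:
    """Rasterize boundaries into a per-pixel label image.

    Each column is labelled independently: rows [0, b1) are VITREOUS, rows
    [b_k, b_{k+1}) are layer k, rows [b6, b6+band) SUB_ELM and the remainder
    BELOW.  If b6+band exceeds the image depth the sub-ELM band is truncated
    (with a warning) rather than failing — annotations near the lower image
    edge are legitimate.
    """
    if band < 1:
        raise ConfigurationError("sub-ELM band height must be >= 1")
    bs.validate(depth=depth)
    b = bs.boundaries
    rows = np.arange(depth)[:, None]
    # Count how many boundaries each pixel sits at or below: 0 -> VITREOUS,
    # 1..5 -> L1..L5, 6 -> at/below b6.
    labels = (rows >= b[:, None, :]).sum(axis=0).astype(np.int8)
    below = rows >= (b[-1] + band)[None, :]
    labels[(labels == N_BOUNDARIES) & below] = BELOW
    if np.any(b[-1] + band > depth):
        logger.warning(
            "sub-ELM band truncated at image bottom (b6 + band > depth %d)", depth
        )
    return LayerMask(labels=labels, band=band)


def layer_pixels(img: BScan | np.ndarray, mask: LayerMask, label: int) -> PixelSample:
    """Extract the grey values of all pixels carrying ``label``."""
    arr = img.image if isinstance(img, BScan) else np.asarray(img, dtype=float)
    if arr.shape != mask.labels.shape:
        raise ConfigurationError(
            f"image shape {arr.shape} != mask shape {mask.labels.shape}"
        )
    values = arr[mask.labels == label]
    if values.size == 0:
        raise DegenerateRegionError(
            f"region {LABEL_NAMES.get(label, label)} is empty"
        )
    return PixelSample(values=values, label=label)
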