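"""B-scan container and greyscale TIFF round-trip.

Intensities are floats in [0, 1] in memory; scans are exported as
single-channel 8-bit TIFF (scaled by 255, rounded half-up), which models the
saturation of exported clinical scans while keeping metric code scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["BScan", "write_scan_tiff", "read_scan_tiff", "round_half_up"]


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with exact halves going up (toward +inf)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


@dataclass
class BScan:
    """A single greyscale B-scan with acquisition metadata.

    Parameters
    ----------
    image : ndarray of shape (depth, width)
        Grey values in [0, 1]; rows are axial (depth), columns are A-scans.
    eye : str, optional
        Eye identifier.
    condition : str, optional
        Media condition, ``"pre"`` (opaque) or ``"post"`` (clear).
    n_averaged : int, optional
        Number of frames averaged into this scan.
    """

    image: np.ndarray
    eye: str | None = None
    condition: str | None = None
    n_averaged: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("BScan image must be 2-D (depth, width)")

    @property
    def depth(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def write_scan_tiff(scan: BScan, path: str | Path) -> None:
    """Write a scan as single-channel 8-bit TIFF (values x255, half-up)."""
    data = round_half_up(np.clip(scan.image, 0.0, 1.0) * 255.0).astype(np.uint8)
    tifffile.imwrite(str(path), data)


def read_scan_tiff(
    path: str | Path,
    eye: str | None = None,
    condition: str | None = None,
    n_averaged: int | None = None,
) -> BScan:
    """Read an 8-bit greyscale TIFF back into a float [0, 1] scan."""
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected single-channel 2-D TIFF")
    return BScan(
        image=data.astype(float) / 255.0,
        eye=eye,
        condition=condition,
        n_averaged=n_averaged,
    )
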