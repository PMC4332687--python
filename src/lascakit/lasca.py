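"""Block-wise speckle statistics and the LASCA contrast map.

The image is partitioned into non-overlapping ``window x window`` blocks
starting at pixel (0, 0); trailing rows/columns that do not fill a block are
discarded, so a 700x700 image with the default window of 4 yields a 175x175
map. Each cell holds the local speckle contrast

    C = sigma / <I>

with ``<I>`` the block mean and ``sigma`` the sample (n-1 denominator)
standard deviation over the n = window**2 pixels. Cells whose block mean is
zero are flagged invalid rather than propagating a division by zero.

Contrast values are *not* clamped to [0, 1]: the ideal statistic of fully
developed speckle is bounded by 1, but a finite 16-pixel sample of a
heavy-tailed intensity distribution can legitimately exceed it, and clamping
would bias every downstream region mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np

from .errors import ParameterError
from .imaging import IntensityImage

__all__ = ["LascaMap", "block_stats", "lasca_map", "average_image", "DEFAULT_WINDOW"]

#: Default block edge length in pixels (n = 4x4 pixels per block).
DEFAULT_WINDOW = 4


@dataclass(frozen=True)
class LascaMap:
    """Block-wise contrast map with per-cell validity flags.

    ``contrast``, ``mean``, ``std`` and ``valid`` all share the shape
    ``(floor(H / window), floor(W / window))``; for every valid cell
    ``contrast == std / mean`` exactly and ``mean > 0``.
    """

    contrast: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    valid: np.ndarray
    window: int

    @property
    def shape(self) -> Tuple[int, int]:
        return self.contrast.shape

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def to_csv(self, csv_path: Union[str, Path], sidecar_path: Union[str, Path, None] = None) -> None:
        """Write the contrast grid as a plain matrix CSV (invalid cells as NaN)
        plus a JSON sidecar with the map metadata."""
        out = np.where(self.valid, self.contrast, np.nan)
        np.savetxt(csv_path, out, delimiter=",", fmt="%.10g")
        if sidecar_path is None:
            sidecar_path = Path(csv_path).with_suffix(".json")
        meta = {
            "window": self.window,
            "rows": int(self.shape[0]),
            "cols": int(self.shape[1]),
            "n_valid": self.n_valid,
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def _blocks(image: IntensityImage, window: int) -> np.ndarray:
    """View the image as (rows, cols, window*window) non-overlapping blocks."""
    if not isinstance(window, (int, np.integer)) or window < 2:
        raise ParameterError(f"window must be an integer >= 2, got {window!r}")
    h, w = image.height, image.width
    nr, nc = h // window, w // window
    if nr < 1 or nc < 1:
        raise ParameterError(
            f"image {h}x{w} is smaller than one {window}x{window} block"
        )
    px = image.pixels[: nr * window, : nc * window]
    return (
        px.reshape(nr, window, nc, window)
        .transpose(0, 2, 1, 3)
        .reshape(nr, nc, window * window)
    )


def block_stats(image: IntensityImage, window: int = DEFAULT_WINDOW) -> Tuple[np.ndarray, np.ndarray]:
    """Per-block mean intensity <I> and sample standard deviation sigma.

    Returns ``(mean, std)`` grids of shape ``(H // window, W // window)``.
    The standard deviation uses the n-1 denominator with n = window**2.
    """
    blocks = _blocks(image, window)
    return blocks.mean(axis=2), blocks.std(axis=2, ddof=1)


def lasca_map(image: IntensityImage, window: int = DEFAULT_WINDOW) -> LascaMap:
    """Compute the spatial-domain LASCA contrast map C = sigma / <I>."""
    mean, std = block_stats(image, window)
    valid = mean > 0
    contrast = np.zeros_like(mean)
    np.divide(std, mean, out=contrast, where=valid)
    return LascaMap(contrast=contrast, mean=mean, std=std, valid=valid, window=int(window))


def average_image(image: IntensityImage, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Block-mean grid only — the averaged-intensity false-color rendering input."""
    return block_stats(image, window)[0]
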