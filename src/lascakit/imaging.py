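"""Image I/O, cropping and false-color rendering.

All file-format handling lives here so the math core (:mod:`lascakit.lasca`,
:mod:`lascakit.metrics`) only ever sees plain intensity arrays.

Conventions
-----------
Coordinates are 0-based, half-open, row-major: a rectangle is
``(top, left, bottom, right)`` with ``bottom``/``right`` exclusive and row =
y measured from the top of the image.

The default channel policy is ``red``: with HeNe (633 nm) illumination the
red channel of a color camera carries the coherent signal. ``luminance``
(Rec. 601 weights) is offered for robustness; ``single`` demands a
1-channel file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import matplotlib
import numpy as np

from .errors import BoundsError, ChannelPolicyError, FormatError, ParameterError

__all__ = [
    "IntensityImage",
    "RegionSpec",
    "load_image",
    "save_image_tiff16",
    "crop",
    "render_false_color",
    "CHANNEL_POLICIES",
    "SATURATION_WARN_FRACTION",
]

logger = logging.getLogger(__name__)

CHANNEL_POLICIES = ("red", "green", "blue", "luminance", "single")

#: Above this saturated-pixel fraction a warning is logged: clipped pixels
#: truncate the negative-exponential intensity distribution and bias the
#: contrast statistics downward.
SATURATION_WARN_FRACTION = 0.01

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class IntensityImage:
    """A 2-D grid of non-negative pixel intensities in arbitrary linear units.

    Parameters
    ----------
    pixels
        2-D float array, all values >= 0.
    bit_depth
        Source quantization, 8 or 16, or the string ``"synthetic"`` for
        simulator output that was never quantized.
    saturation_fraction
        Fraction of pixels at the maximum representable value of the source
        bit depth (0.0 for synthetic images).
    """

    pixels: np.ndarray
    bit_depth: Union[int, str] = "synthetic"
    saturation_fraction: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("pixels must be a non-empty 2-D array")
        if np.any(px < 0):
            raise ParameterError("pixel intensities must be non-negative")
        if self.bit_depth not in (8, 16, "synthetic"):
            raise ParameterError(f"unsupported bit_depth: {self.bit_depth!r}")
        if not 0.0 <= self.saturation_fraction <= 1.0:
            raise ParameterError("saturation_fraction must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionSpec:
    """A labeled rectangle in pixel coordinates (0-based, half-open)."""

    label: str
    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if self.label not in ("sound", "lesion"):
            raise ParameterError(f"label must be 'sound' or 'lesion', got {self.label!r}")
        if not (0 <= self.top < self.bottom and 0 <= self.left < self.right):
            raise ParameterError(
                f"invalid rectangle (top={self.top}, left={self.left}, "
                f"bottom={self.bottom}, right={self.right})"
            )

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    def overlaps(self, other: "RegionSpec") -> bool:
        return (
            self.top < other.bottom
            and other.top < self.bottom
            and self.left < other.right
            and other.left < self.right
        )


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"unsupported sample type {arr.dtype}; need 8- or 16-bit integer")


def load_image(path: Union[str, Path], channel_policy: str = "red") -> IntensityImage:
    """Load a PNG or TIFF photograph as an :class:`IntensityImage`.

    ``channel_policy`` selects which plane of a 3-channel image is analyzed
    (``red``/``green``/``blue``/``luminance``); ``single`` asserts the file is
    1-channel. The saturation fraction is computed against the bit-depth
    maximum of the *selected channel* before any conversion.
    """
    if channel_policy not in CHANNEL_POLICIES:
        raise ParameterError(
            f"channel_policy must be one of {CHANNEL_POLICIES}, got {channel_policy!r}"
        )
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such image file: {path}")
    try:
        raw = np.asarray(iio.imread(path))
    except Exception as exc:  # imageio raises several backend-specific types
        raise FormatError(f"cannot read {path}: {exc}") from exc

    if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.ndim == 2:
        nchan = 1
    elif raw.ndim == 3 and raw.shape[2] == 3:
        nchan = 3
    else:
        raise FormatError(f"{path}: expected 1 or 3 channels, got shape {raw.shape}")
    depth = _bit_depth_of(raw)
    maxval = (1 << depth) - 1

    if nchan == 1:
        plane = raw.astype(np.float64)
    else:
        if channel_policy == "single":
            raise ChannelPolicyError(
                f"{path}: channel_policy 'single' on a {nchan}-channel image"
            )
        if channel_policy == "luminance":
            plane = raw.astype(np.float64) @ _LUMA
        else:
            plane = raw[:, :, "rgb".index(channel_policy[0])].astype(np.float64)

    # saturation measured on the source channel(s), not the float conversion
    if nchan == 1 or channel_policy != "luminance":
        src = raw if nchan == 1 else raw[:, :, "rgb".index(channel_policy[0])]
        sat = float(np.count_nonzero(src == maxval)) / src.size
    else:
        sat = float(np.count_nonzero(np.all(raw == maxval, axis=2))) / (
            raw.shape[0] * raw.shape[1]
        )
    if sat > SATURATION_WARN_FRACTION:
        logger.warning(
            "%s: %.1f%% of pixels saturated; speckle statistics are biased",
            path,
            100 * sat,
        )
    return IntensityImage(plane, bit_depth=depth, saturation_fraction=sat)


def save_image_tiff16(image: IntensityImage, path: Union[str, Path]) -> float:
    """Write an intensity image as a 16-bit grayscale TIFF.

    Intensities are linearly rescaled so the image maximum maps to 65535
    (contrast statistics are invariant under global rescaling). Returns the
    scale factor applied, so a sidecar can record it.
    """
    peak = float(image.pixels.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    data = np.round(image.pixels * scale).astype(np.uint16)
    iio.imwrite(Path(path), data)
    return scale


def crop(image: IntensityImage, top: int, left: int, bottom: int, right: int) -> IntensityImage:
    """Extract the rectangle ``[top:bottom, left:right]`` as a new image.

    Pixel (0, 0) of the output equals pixel (top, left) of the input.
    """
    if not (0 <= top < bottom and 0 <= left < right):
        raise BoundsError("crop rectangle is empty or has negative coordinates")
    if bottom > image.height or right > image.width:
        raise BoundsError(
            f"crop rectangle ({top},{left},{bottom},{right}) exceeds "
            f"{image.height}x{image.width} image"
        )
    return IntensityImage(
        image.pixels[top:bottom, left:right].copy(),
        bit_depth=image.bit_depth,
        saturation_fraction=image.saturation_fraction,
    )


def crop_region(image: IntensityImage, region: RegionSpec) -> IntensityImage:
    """Crop using a :class:`RegionSpec` rectangle."""
    return crop(image, region.top, region.left, region.bottom, region.right)


#: RGB color used for cells flagged invalid in a rendered map. Magenta does
#: not occur in the perceptually ordered colormaps used for the maps.
INVALID_CELL_COLOR = (255, 0, 255)


def render_false_color(
    grid: np.ndarray,
    out_path: Union[str, Path],
    colormap_name: str = "jet",
    valid: np.ndarray | None = None,
) -> None:
    """Render a contrast or averaged-intensity grid as a false-color PNG.

    Valid values are mapped linearly from ``[min valid, max valid]`` onto the
    colormap (a constant grid maps to the colormap's lower end); invalid
    cells get :data:`INVALID_CELL_COLOR`. One grid cell becomes one pixel.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(grid)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(grid)
    if not valid.any():
        raise ParameterError("cannot render a map with no valid cells")

    vmin = float(grid[valid].min())
    vmax = float(grid[valid].max())
    span = vmax - vmin
    norm = np.zeros_like(grid)
    if span > 0:
        norm[valid] = (grid[valid] - vmin) / span
    cmap = matplotlib.colormaps[colormap_name]
    rgb = (cmap(norm)[:, :, :3] * 255).round().astype(np.uint8)
    rgb[~valid] = INVALID_CELL_COLOR
    iio.imwrite(Path(out_path), rgb)
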