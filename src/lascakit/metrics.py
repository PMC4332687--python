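"""Erosion metrics: region mean contrasts and the contrast-ratio statistic.

The per-sample biomarker is

    CR = 1 - <C_sound> / <C_lesion>

where ``<C_sound>`` and ``<C_lesion>`` are the mean LASCA contrasts over the
sound and eroded (lesion) regions of one sample, restricted to the centrally
illuminated part of the map. Demineralized enamel scatters more
heterogeneously and backscatters less, raising its local contrast, so CR is
positive for an eroded lesion and grows with erosion severity. CR is
reported *signed*: a negative value (sound contrast above lesion contrast)
flags a pathological measurement and must not be silently hidden by an
absolute value.

Region rectangles are given in pixel coordinates and converted to block
coordinates by the rule: a block belongs to a region iff the block's
top-left pixel lies inside the region rectangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    DomainError,
    InsufficientDataError,
    ParameterError,
)
from .imaging import IntensityImage, RegionSpec
from .lasca import DEFAULT_WINDOW, LascaMap, lasca_map

__all__ = [
    "SampleMeasurement",
    "GroupSummary",
    "central_mask",
    "mean_contrast",
    "contrast_ratio",
    "measure_sample",
    "summarize_group",
    "DEFAULT_CENTRAL_FRACTION",
    "DEFAULT_MIN_CELLS",
]

#: Linear fraction of the map retained by the central-illumination mask.
DEFAULT_CENTRAL_FRACTION = 0.5
#: Minimum number of valid masked cells a region mean may be computed from.
DEFAULT_MIN_CELLS = 25


@dataclass(frozen=True)
class SampleMeasurement:
    """Mean region contrasts and contrast ratio for one sample."""

    sample_id: str
    group_duration: float
    c_sound: float
    c_lesion: float
    contrast_ratio: float
    n_valid_sound: int
    n_valid_lesion: int


@dataclass(frozen=True)
class GroupSummary:
    """Contrast-ratio statistics of one acid-etching duration group."""

    duration: float
    n: int
    mean_cr: float
    sd_cr: Optional[float]  # None for n = 1


def central_mask(lmap: LascaMap, fraction: float = DEFAULT_CENTRAL_FRACTION) -> np.ndarray:
    """Mask selecting the centered sub-grid of linear size ceil(fraction*dim).

    Restricts analysis to the centrally illuminated portion of the image,
    where beam intensity is approximately homogeneous; the returned mask is
    intersected with the map's validity flags.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction!r}")
    rows, cols = lmap.shape
    sub_r = math.ceil(fraction * rows)
    sub_c = math.ceil(fraction * cols)
    r0 = (rows - sub_r) // 2
    c0 = (cols - sub_c) // 2
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0 : r0 + sub_r, c0 : c0 + sub_c] = True
    return mask & lmap.valid


def region_block_mask(lmap: LascaMap, region: RegionSpec) -> np.ndarray:
    """Boolean grid of blocks whose top-left pixel lies inside ``region``."""
    rows, cols = lmap.shape
    w = lmap.window
    ri = np.arange(rows) * w
    ci = np.arange(cols) * w
    in_rows = (ri >= region.top) & (ri < region.bottom)
    in_cols = (ci >= region.left) & (ci < region.right)
    return in_rows[:, None] & in_cols[None, :]


def mean_contrast(
    lmap: LascaMap,
    region: RegionSpec,
    mask: np.ndarray,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> tuple[float, int]:
    """Arithmetic mean of contrast over valid, masked cells inside a region.

    Returns ``(mean, n_cells_used)``; raises
    :class:`~lascakit.errors.InsufficientDataError` when fewer than
    ``min_cells`` cells are usable.
    """
    sel = region_block_mask(lmap, region) & np.asarray(mask, dtype=bool) & lmap.valid
    n = int(np.count_nonzero(sel))
    if n < min_cells:
        raise InsufficientDataError(
            f"region {region.label!r}: only {n} usable cells (< {min_cells})"
        )
    return float(lmap.contrast[sel].mean()), n


def contrast_ratio(c_sound: float, c_lesion: float) -> float:
    """The erosion statistic CR = 1 - c_sound / c_lesion.

    Positive when the lesion's mean contrast exceeds the sound region's;
    negative CR is returned as-is.
    """
    if not (c_sound > 0 and c_lesion > 0):
        raise DomainError(
            f"mean contrasts must be positive, got c_sound={c_sound}, c_lesion={c_lesion}"
        )
    return 1.0 - c_sound / c_lesion


def measure_sample(
    image: IntensityImage,
    sound: RegionSpec,
    lesion: RegionSpec,
    window: int = DEFAULT_WINDOW,
    fraction: float = DEFAULT_CENTRAL_FRACTION,
    sample_id: str = "sample",
    group_duration: float = 0.0,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> SampleMeasurement:
    """Full single-sample pipeline: LASCA map -> central mask -> region means -> CR."""
    if sound.label != "sound" or lesion.label != "lesion":
        raise ParameterError("regions must be labeled 'sound' and 'lesion'")
    if sound.overlaps(lesion):
        raise ConsistencyError(f"{sample_id}: sound and lesion regions overlap")
    try:
        lmap = lasca_map(image, window)
        mask = central_mask(lmap, fraction)
        c_sound, n_sound = mean_contrast(lmap, sound, mask, min_cells)
        c_lesion, n_lesion = mean_contrast(lmap, lesion, mask, min_cells)
        cr = contrast_ratio(c_sound, c_lesion)
    except Exception as exc:
        exc.add_note(f"while measuring sample {sample_id!r}")
        raise
    return SampleMeasurement(
        sample_id=sample_id,
        group_duration=group_duration,
        c_sound=c_sound,
        c_lesion=c_lesion,
        contrast_ratio=cr,
        n_valid_sound=n_sound,
        n_valid_lesion=n_lesion,
    )


def summarize_group(samples: Sequence[SampleMeasurement], duration: float) -> GroupSummary:
    """Mean and sample SD of contrast ratio over one duration group.

    Excluded samples must be removed by the caller beforehand — exclusion is
    always explicit, never automatic.
    """
    if len(samples) == 0:
        raise ParameterError("cannot summarize an empty group")
    durations = {s.group_duration for s in samples}
    if durations != {duration}:
        raise ConsistencyError(
            f"samples carry durations {sorted(durations)}, expected only {duration}"
        )
    crs = np.array([s.contrast_ratio for s in samples], dtype=float)
    sd = float(crs.std(ddof=1)) if len(crs) >= 2 else None
    return GroupSummary(duration=duration, n=len(crs), mean_cr=float(crs.mean()), sd_cr=sd)


def measurements_to_rows(samples: Sequence[SampleMeasurement]) -> List[dict]:
    """Plain-dict rows for CSV export of per-sample results."""
    return [
        {
            "sample_id": s.sample_id,
            "duration_min": s.group_duration,
            "c_sound": s.c_sound,
            "c_lesion": s.c_lesion,
            "contrast_ratio": s.contrast_ratio,
            "n_valid_sound": s.n_valid_sound,
            "n_valid_lesion": s.n_valid_lesion,
        }
        for s in samples
    ]
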