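"""Synthetic coherent-speckle phantoms.

Fully developed polarized speckle is synthesized by low-pass filtering a
complex circular-Gaussian random field in the frequency domain and taking
the squared magnitude. The resulting pixel intensities follow the
negative-exponential law

    P(I) = exp(-I / <I>) / <I>

and the speckle grain (intensity-autocorrelation FWHM) is set by the
circular cutoff radius. Averaging N independent such patterns lowers the
global contrast std/mean to 1/sqrt(N) — the standard mechanism for emulating
reduced contrast from multiple scattering or depolarization.

A two-region erosion phantom places low-N (high-contrast), low-mean speckle
on the left of a boundary column ("lesion") and high-N, high-mean speckle on
the right ("sound"), reproducing the two signatures of eroded enamel: lower
mean backscatter and higher local contrast. Phantom region rectangles are
inset by 2x grain from the image edges and the boundary so region statistics
are not contaminated by boundary mixing.

Grain calibration: the intensity autocorrelation of speckle from a circular
frequency-domain aperture follows |2 J1(x)/x|^2, which reaches half maximum
at x ~= 1.61633; mapping its FWHM to ``grain`` pixels gives the cutoff
radius rho_c = 1.61633 / (pi * grain) ~= 0.5145 / grain cycles per pixel.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
from scipy import stats

from .errors import ParameterError
from .imaging import IntensityImage, RegionSpec

__all__ = [
    "PhantomConfig",
    "generate_speckle",
    "generate_nsum_speckle",
    "generate_phantom",
    "validate_exponential",
    "GRAIN_CUTOFF_CONSTANT",
]

#: rho_c * grain: frequency cutoff (cycles/pixel) times grain (pixels); fixed
#: so the intensity-autocorrelation FWHM equals the requested grain.
GRAIN_CUTOFF_CONSTANT = 1.61633 / math.pi  # ~= 0.51448


@dataclass(frozen=True)
class PhantomConfig:
    """Full parameterization of a two-region erosion phantom.

    ``n_sum_lesion < n_sum_sound`` and ``mean_lesion < mean_sound`` emulate
    an eroded lesion (higher contrast, darker) next to sound enamel. The
    ideal contrast ratio of the phantom is
    ``1 - sqrt(n_sum_lesion / n_sum_sound)``.
    """

    height: int = 700
    width: int = 700
    grain: float = 1.5
    mean_sound: float = 120.0
    mean_lesion: float = 80.0
    n_sum_sound: int = 4
    n_sum_lesion: int = 1
    boundary_col: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ParameterError("phantom dimensions must be >= 16 pixels")
        if not 0 < self.boundary_col < self.width:
            raise ParameterError("boundary_col must lie strictly inside the image")
        if self.grain < 1:
            raise ParameterError("grain must be >= 1 pixel")
        if self.mean_sound <= 0 or self.mean_lesion <= 0:
            raise ParameterError("region mean intensities must be positive")
        if self.n_sum_sound < 1 or self.n_sum_lesion < 1:
            raise ParameterError("n_sum values must be positive integers")

    @property
    def ideal_contrast_ratio(self) -> float:
        return 1.0 - math.sqrt(self.n_sum_lesion / self.n_sum_sound)


def _speckle_field_intensity(height: int, width: int, grain: float, rng: np.random.Generator) -> np.ndarray:
    """One un-normalized fully developed speckle intensity pattern."""
    field = rng.standard_normal((height, width)) + 1j * rng.standard_normal((height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    rho_c = GRAIN_CUTOFF_CONSTANT / grain
    lowpass = (fy * fy + fx * fx) <= rho_c * rho_c
    filtered = np.fft.ifft2(np.fft.fft2(field) * lowpass)
    return np.abs(filtered) ** 2


def _check_speckle_args(height: int, width: int, grain: float, mean_intensity: float) -> None:
    if height < 16 or width < 16:
        raise ParameterError("speckle dimensions must be >= 16 pixels")
    if grain < 1:
        raise ParameterError("grain must be >= 1 pixel")
    if mean_intensity <= 0:
        raise ParameterError("mean_intensity must be positive")


def generate_nsum_speckle(
    height: int,
    width: int,
    grain: float,
    mean_intensity: float,
    n_sum: int,
    seed: Union[int, np.random.SeedSequence],
) -> IntensityImage:
    """Average of ``n_sum`` independent speckle patterns, rescaled to
    ``mean_intensity``; ideal global contrast 1/sqrt(n_sum)."""
    _check_speckle_args(height, width, grain, mean_intensity)
    if n_sum < 1:
        raise ParameterError("n_sum must be >= 1")
    rng = np.random.default_rng(seed)
    acc = np.zeros((height, width))
    for _ in range(n_sum):
        acc += _speckle_field_intensity(height, width, grain, rng)
    acc /= n_sum
    acc *= mean_intensity / acc.mean()
    return IntensityImage(acc, bit_depth="synthetic", saturation_fraction=0.0)


def generate_speckle(
    height: int,
    width: int,
    grain: float,
    mean_intensity: float,
    seed: Union[int, np.random.SeedSequence],
) -> IntensityImage:
    """A single fully developed polarized speckle pattern (negative-exponential
    intensities, ideal contrast 1), deterministic given the seed."""
    return generate_nsum_speckle(height, width, grain, mean_intensity, 1, seed)


def generate_phantom(config: PhantomConfig) -> Tuple[IntensityImage, RegionSpec, RegionSpec]:
    """Two-region erosion phantom: ``(image, lesion_region, sound_region)``.

    Sub-seeds for the two half-images are spawned from
    ``numpy.random.SeedSequence(config.seed)`` (children 0 = lesion,
    1 = sound), so phantoms are reproducible across platforms.
    """
    lesion_ss, sound_ss = np.random.SeedSequence(config.seed).spawn(2)
    h, w, b = config.height, config.width, config.boundary_col
    lesion_img = generate_nsum_speckle(
        h, b, config.grain, config.mean_lesion, config.n_sum_lesion, lesion_ss
    )
    sound_img = generate_nsum_speckle(
        h, w - b, config.grain, config.mean_sound, config.n_sum_sound, sound_ss
    )
    pixels = np.concatenate([lesion_img.pixels, sound_img.pixels], axis=1)
    inset = math.ceil(2 * config.grain)
    lesion = RegionSpec("lesion", top=inset, left=inset, bottom=h - inset, right=b - inset)
    sound = RegionSpec("sound", top=inset, left=b + inset, bottom=h - inset, right=w - inset)
    image = IntensityImage(pixels, bit_depth="synthetic", saturation_fraction=0.0)
    return image, lesion, sound


def write_phantom(
    config: PhantomConfig, image_path: Union[str, Path], sidecar_path: Union[str, Path, None] = None
) -> Tuple[RegionSpec, RegionSpec]:
    """Generate a phantom, write it as 16-bit TIFF plus a JSON sidecar holding
    the full config and the derived region rectangles."""
    from .imaging import save_image_tiff16

    image, lesion, sound = generate_phantom(config)
    scale = save_image_tiff16(image, image_path)
    if sidecar_path is None:
        sidecar_path = Path(image_path).with_suffix(".json")
    sidecar = {
        "config": asdict(config),
        "intensity_scale": scale,
        "lesion_region": asdict(lesion),
        "sound_region": asdict(sound),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return lesion, sound


def validate_exponential(
    image: IntensityImage, subsample_stride: int, alpha: float = 0.01
) -> Tuple[float, bool]:
    """One-sample KS test of subsampled intensities against the
    negative-exponential law parameterized by their own mean.

    Subsampling at ``subsample_stride`` pixels (use >= 4x grain) decorrelates
    neighboring speckle grains so the KS null approximately holds. Returns
    ``(ks_distance, passed_at_alpha)``.
    """
    if subsample_stride < 1:
        raise ParameterError("subsample_stride must be >= 1")
    sample = image.pixels[::subsample_stride, ::subsample_stride].ravel()
    if sample.size < 500:
        raise ParameterError(
            f"only {sample.size} subsampled pixels; need >= 500 for the KS test"
        )
    mean = sample.mean()
    if mean <= 0 or sample.std() == 0:
        return 1.0, False  # degenerate: not an exponential sample
    result = stats.kstest(sample, "expon", args=(0.0, mean))
    return float(result.statistic), bool(result.pvalue > alpha)
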