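"""Lattice spacing from periodic images and gray-profile segmentation.

The row-spacing estimator takes a Hann-windowed 2D power spectrum, folds it
into a radial profile, and reads the dominant spatial frequency outside a
DC guard band; sub-bin accuracy comes from a parabolic refinement of the
peak bin. Profiles are segmented by thresholding at a background gray
level, in the spirit of measuring light/dark subdivisions along a line cut
through a hexagonally packed tube lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import (
    InsufficientProfileError,
    MalformedInputError,
    NoPeriodicityError,
    ParameterError,
)

#: 2D row spacing -> 3D tube-to-tube distance for hexagonal packing.
PLANAR_TO_SPATIAL_FACTOR = 2.0 / math.sqrt(3.0)

DC_GUARD_BINS = 3


@dataclass
class CalibratedImage:
    """Grayscale image with physical pixel size (nm per pixel)."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise MalformedInputError("image must be 2D grayscale")
        if min(self.data.shape) < 64:
            raise MalformedInputError("image must be at least 64x64 pixels")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")


@dataclass
class SpacingEstimate:
    spacing: float  # nm
    uncertainty: float  # nm, one radial frequency bin
    frequency: float  # cycles / nm
    snr: float  # peak power over median radial power

    def to_dict(self) -> dict:
        return {
            "spacing_nm": self.spacing,
            "uncertainty_nm": self.uncertainty,
            "frequency_cycles_per_nm": self.frequency,
            "snr": self.snr,
        }


def _radial_power(image: CalibratedImage, window: str = "hann"):
    """Radially binned power spectrum -> (freq bin centers, mean power)."""
    img = image.data - image.data.mean()
    ny, nx = img.shape
    if window == "hann":
        win = np.outer(np.hanning(ny), np.hanning(nx))
        img = img * win
    elif window not in (None, "none"):
        raise ParameterError(f"unknown window {window!r}")
    power = np.abs(np.fft.rfft2(img)) ** 2
    fy = np.fft.fftfreq(ny, d=image.pixel_size)
    fx = np.fft.rfftfreq(nx, d=image.pixel_size)
    fr = np.hypot(fy[:, None], fx[None, :])
    df = 1.0 / (min(ny, nx) * image.pixel_size)  # radial bin width
    nbins = int(fr.max() / df) + 1
    idx = np.minimum(np.rint(fr / df).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    prof = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    freqs = np.arange(nbins) * df  # bin i collects |f - i*df| < df/2
    return freqs, prof, df


def fft_row_spacing(
    image: CalibratedImage,
    window: str = "hann",
    min_prominence: float = 10.0,
    max_spacing: Optional[float] = None,
) -> SpacingEstimate:
    """Dominant lattice row spacing of a quasi-periodic image, in nm.

    ``min_prominence`` is the required ratio of the peak radial power to
    the median radial power outside the DC guard band. Raises
    :class:`NoPeriodicityError` when no such peak exists (e.g. a uniform
    or pure-noise image).
    """
    if np.ptp(image.data) == 0:
        raise NoPeriodicityError("image is uniform")
    freqs, prof, df = _radial_power(image, window=window)
    lo = DC_GUARD_BINS
    if max_spacing is not None:
        lo = max(lo, int(1.0 / (max_spacing * df)))
    search = prof[lo:]
    if search.size < 3 or not np.any(search > 0):
        raise NoPeriodicityError("empty power spectrum outside guard band")
    floor = float(np.median(search))
    i = int(np.argmax(search)) + lo
    peak = float(prof[i])
    if floor <= 0 or peak < min_prominence * floor:
        raise NoPeriodicityError(
            f"no spectral peak above prominence threshold (peak/median = "
            f"{peak / floor if floor > 0 else math.inf:.2f})"
        )
    # parabolic sub-bin refinement on log power
    f_peak = freqs[i]
    if 0 < i < prof.size - 1 and prof[i - 1] > 0 and prof[i + 1] > 0:
        y0, y1, y2 = np.log(prof[i - 1 : i + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            f_peak = freqs[i] + 0.5 * (y0 - y2) / denom * df
    spacing = 1.0 / f_peak
    return SpacingEstimate(
        spacing=float(spacing),
        uncertainty=float(spacing ** 2 * df),
        frequency=float(f_peak),
        snr=peak / floor,
    )


@dataclass
class ProfileSegmentation:
    """Light/dark run lengths of a thresholded 1D gray profile."""

    light_lengths: List[float]  # nm, above-threshold runs
    dark_lengths: List[float]  # nm
    period: float  # nm, mean adjacent light+dark pair
    threshold: float

    def to_dict(self) -> dict:
        return {
            "light_nm": list(self.light_lengths),
            "dark_nm": list(self.dark_lengths),
            "period_nm": self.period,
            "threshold": self.threshold,
        }


def profile_segments(
    profile: np.ndarray,
    pixel_size: float,
    background_level: Optional[float] = None,
) -> ProfileSegmentation:
    """Segment a calibrated gray-value profile at a background level.

    Runs touching the profile boundary are discarded as partial. The
    period is the mean length of adjacent (light, dark) pairs. Default
    ``background_level`` is the profile median.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise MalformedInputError("profile must be 1D with >= 8 samples")
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    if background_level is None:
        background_level = float(np.median(y))

    above = y > background_level
    n_crossings = int(np.sum(above[1:] != above[:-1]))
    if n_crossings < 4:
        raise InsufficientProfileError(
            f"profile crosses the background level only {n_crossings} times (need >= 4)"
        )

    # run-length encode, discarding the two boundary (partial) runs
    change = np.flatnonzero(above[1:] != above[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [y.size]])
    runs = [(bool(above[s]), (e - s) * pixel_size) for s, e in zip(starts, ends)]
    runs = runs[1:-1]

    light = [ln for is_light, ln in runs if is_light]
    dark = [ln for is_light, ln in runs if not is_light]
    if not light or not dark:
        raise InsufficientProfileError("no complete light/dark runs inside profile")

    pairs = [runs[i][1] + runs[i + 1][1] for i in range(len(runs) - 1)]
    if len(pairs) < 2:
        raise InsufficientProfileError("fewer than 2 complete periods in profile")
    period = float(np.mean(pairs))
    return ProfileSegmentation(
        light_lengths=light,
        dark_lengths=dark,
        period=period,
        threshold=float(background_level),
    )


def planar_to_spatial(distance: float) -> float:
    """Convert a 2D projected row spacing to the 3D distance (x 2/sqrt(3))."""
    if distance <= 0:
        raise ParameterError("distance must be positive")
    return distance * PLANAR_TO_SPATIAL_FACTOR
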