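"""Hue spectra: saturation-weighted 360-bin hue histograms.

A hue spectrum is computed from an RGB image by keeping the pixels whose
normalized saturation strictly exceeds a threshold (default 0.05, which
removes white/gray/black backgrounds without segmentation), rounding their
hue to the nearest integer degree, folding degree 0 into 360, and summing
the normalized saturation of the kept pixels per degree bin.  The 360
sums are divided by the number of kept pixels, which makes spectra
comparable among images of different size.

Bins are labelled by degree 1..360.  Internally ``values[i]`` holds the bin
for degree ``i + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .color import rgb_to_hue_sat

DEFAULT_THRESHOLD = 0.05

__all__ = [
    "DEFAULT_THRESHOLD",
    "HueSpectrum",
    "SpectrumPeak",
    "compute_hue_spectrum",
    "average_spectra",
    "crop_spectrum",
    "find_peaks",
]


@dataclass(frozen=True)
class HueSpectrum:
    """A 360-bin saturation-weighted hue histogram plus its metadata.

    Attributes
    ----------
    values
        360 non-negative reals; ``values[i]`` is the bin for hue degree
        ``i + 1`` (degree 0 is folded into 360).
    n_included
        Number of pixels whose saturation exceeded the threshold (a real
        when the spectrum is an aggregate of several images).
    threshold_used
        Saturation threshold applied during computation.
    total_pixels
        Total pixel count of the source image(s).
    normalization
        ``"included"`` (divide by the above-threshold count; the reference
        definition) or ``"total"`` (divide by the total pixel count).
    crop_range
        ``(lo, hi)`` degree range if the spectrum was cropped, else None.
    aggregate
        True when this spectrum is an average over several spectra.
    """

    values: np.ndarray
    n_included: float
    threshold_used: float
    total_pixels: int
    normalization: str = "included"
    crop_range: tuple[int, int] | None = None
    aggregate: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (360,):
            raise ValueError(f"spectrum must have exactly 360 bins, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("spectrum bins must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def degrees(self) -> np.ndarray:
        """Degree labels 1..360 aligned with :attr:`values`."""
        return np.arange(1, 361)

    def value_at(self, degree: int) -> float:
        """Bin value at an integer hue degree in 1..360 (0 accepted as 360)."""
        d = 360 if degree == 0 else int(degree)
        if not 1 <= d <= 360:
            raise ValueError(f"degree out of range: {degree}")
        return float(self.values[d - 1])


@dataclass(frozen=True)
class SpectrumPeak:
    """A local maximum of a spectrum: degree location, height and FWHM width."""

    location: int
    height: float
    width: float


def round_half_away(h: np.ndarray) -> np.ndarray:
    """Round non-negative values half away from zero (the reference
    environment's double -> unsigned integer conversion)."""
    return np.floor(np.asarray(h, dtype=np.float64) + 0.5).astype(np.int64)


def compute_hue_spectrum(
    image: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    normalization: str = "included",
) -> HueSpectrum:
    """Compute the saturation-weighted hue histogram of an RGB image.

    Pixels with saturation strictly greater than ``threshold`` are kept;
    each adds its normalized saturation to the bin of its rounded hue
    degree (0 folded to 360).  With fewer than two kept pixels the spectrum
    is all-zero (not an error) and ``n_included`` records the count.

    Parameters
    ----------
    image
        ``(H, W, 3)`` RGB array.
    threshold
        Saturation threshold in [0, 1); default 0.05.
    normalization
        ``"included"`` divides bins by the kept-pixel count (reference
        behavior); ``"total"`` divides by the total pixel count.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if normalization not in ("included", "total"):
        raise ValueError(f"unknown normalization {normalization!r}")
    hue, sat = rgb_to_hue_sat(image)
    mask = sat > threshold
    n = int(np.count_nonzero(mask))
    total = int(sat.size)
    values = np.zeros(360)
    if n > 1:
        fc = round_half_away(hue[mask])
        fc[fc == 0] = 360
        sums = np.bincount(fc - 1, weights=sat[mask], minlength=360)
        divisor = n if normalization == "included" else total
        values = sums / divisor
    return HueSpectrum(
        values=values,
        n_included=n,
        threshold_used=float(threshold),
        total_pixels=total,
        normalization=normalization,
    )


def average_spectra(spectra: list[HueSpectrum]) -> HueSpectrum:
    """Element-wise arithmetic mean of spectra sharing one threshold.

    The result is flagged as an aggregate; ``n_included`` becomes the mean
    included-pixel count.  Mixed thresholds or normalizations are an error
    because their bins are not commensurable.
    """
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    thresholds = {s.threshold_used for s in spectra}
    if len(thresholds) > 1:
        raise ValueError(f"mixed thresholds in average: {sorted(thresholds)}")
    norms = {s.normalization for s in spectra}
    if len(norms) > 1:
        raise ValueError(f"mixed normalization modes in average: {sorted(norms)}")
    values = np.mean([s.values for s in spectra], axis=0)
    return HueSpectrum(
        values=values,
        n_included=float(np.mean([s.n_included for s in spectra])),
        threshold_used=spectra[0].threshold_used,
        total_pixels=int(sum(s.total_pixels for s in spectra)),
        normalization=spectra[0].normalization,
        aggregate=True,
    )


def range_mask(lo: int, hi: int) -> np.ndarray:
    """Boolean membership of degrees 1..360 in the (possibly wrapped) range.

    ``lo <= hi`` is the ordinary closed interval; ``lo > hi`` wraps through
    360/1 (red straddles the fold, so [330, 30] is a legitimate range).
    """
    lo, hi = int(lo), int(hi)
    if not (1 <= lo <= 360 and 1 <= hi <= 360):
        raise ValueError(f"degrees must be in 1..360, got [{lo}, {hi}]")
    deg = np.arange(1, 361)
    if lo <= hi:
        return (deg >= lo) & (deg <= hi)
    return (deg >= lo) | (deg <= hi)


def crop_spectrum(spectrum: HueSpectrum, lo: int, hi: int) -> HueSpectrum:
    """Zero out bins outside a degree range, keeping originals inside.

    Wrapped ranges (``lo > hi``) are honored.  The applied range is
    recorded in :attr:`HueSpectrum.crop_range`.
    """
    mask = range_mask(lo, hi)
    return replace(spectrum, values=np.where(mask, spectrum.values, 0.0), crop_range=(int(lo), int(hi)))


def _half_crossing(values: np.ndarray, start: int, half: float, step: int) -> float:
    """Distance (bins, fractional) from ``start`` to the half-height
    crossing walking circularly in direction ``step`` (+1/-1).

    Capped at 180 if the flank never drops to half height.
    """
    n = values.size
    prev = values[start]
    for d in range(1, n // 2 + 1):
        cur = values[(start + step * d) % n]
        if cur <= half:
            return (d - 1) + (prev - half) / (prev - cur)
        prev = cur
    return n / 2.0


def find_peaks(spectrum: HueSpectrum, min_height: float = 0.0) -> list[SpectrumPeak]:
    """Local maxima of a spectrum with circular adjacency (360 next to 1).

    A plateau (run of equal values) counts once, located at the lowest
    degree it contains.  Width is the full width at half maximum obtained
    by linear interpolation on each flank, also circular.  Peaks whose
    height is not strictly above ``min_height`` are dropped.
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    v = spectrum.values
    n = v.size
    peaks: list[SpectrumPeak] = []
    # plateau starts: strictly rising edge from the previous bin (circular)
    for s in range(n):
        if not v[s] > v[(s - 1) % n]:
            continue
        e = s
        while v[(e + 1) % n] == v[s]:
            e = (e + 1) % n
            if e == s:  # safety: cannot happen after a strict rise
                break
        if v[(e + 1) % n] >= v[s]:
            continue  # rising shoulder, not a summit
        height = float(v[s])
        if not height > min_height or height <= 0:
            continue
        plateau = [s]
        k = s
        while k != e:
            k = (k + 1) % n
            plateau.append(k)
        location = min(p + 1 for p in plateau)
        half = height / 2.0
        left = _half_crossing(v, s, half, -1)
        right = _half_crossing(v, e, half, +1)
        plateau_span = (e - s) % n
        width = float(left + right + plateau_span)
        peaks.append(SpectrumPeak(location=location, height=height, width=width))
    peaks.sort(key=lambda p: p.location)
    return peaks
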