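"""RGB to chromatic-plane projection, hue angle and saturation.

The 24-bit RGB cube is projected onto the plane orthogonal to the neutral
(gray) axis:

    x = R - (G + B) / 2
    y = (sqrt(3) / 2) * (G - B)

Hue is the angle of (x, y) in degrees, corrected into [0, 360); saturation
is the Euclidean distance from the neutral axis normalized by 255, so it
lies in [0, 1] with the six chromatic cube corners (pure red, green, blue,
yellow, magenta, cyan) at exactly 1 and every gray at exactly 0.

Lightness/value is deliberately not computed: hue spectra ignore it.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

__all__ = [
    "NonColorImageError",
    "rgb_to_chroma",
    "chroma_to_hue",
    "chroma_to_saturation",
    "rgb_to_hue_sat",
    "load_image",
]


class NonColorImageError(ValueError):
    """Raised when an input is not a 3-channel (R, G, B) color image."""


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise NonColorImageError(
            f"Non-color image matrix: expected height x width x 3 RGB, got shape {arr.shape}"
        )
    return arr


def rgb_to_chroma(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project RGB pixels onto the chromatic plane.

    Parameters
    ----------
    image
        ``(H, W, 3)`` array of channel intensities (any integer or float
        dtype; integers are widened to double before subtraction).

    Returns
    -------
    (x, y)
        Per-pixel chromatic-plane coordinates in intensity units.  For any
        valid 8-bit input ``x**2 + y**2 <= 255**2`` (the RGB cube projects
        onto a hexagon of circumradius 255).
    """
    arr = _validate_rgb(image)
    r = arr[..., 0].astype(np.float64)
    g = arr[..., 1].astype(np.float64)
    b = arr[..., 2].astype(np.float64)
    x = r - g / 2.0 - b / 2.0
    y = (g - b) * (np.sqrt(3.0) / 2.0)
    return x, y


def chroma_to_hue(x, y):
    """Hue angle in degrees in [0, 360) from chromatic-plane coordinates.

    Uses the two-argument arctangent (no division, so the origin is well
    defined and maps to 0); negative angles are corrected by +360.
    """
    h = np.degrees(np.arctan2(y, x))
    h = np.where(h < 0, h + 360.0, h)
    return h[()] if np.ndim(h) == 0 else h


def chroma_to_saturation(x, y):
    """Normalized saturation in [0, 1]: Euclidean chroma distance / 255."""
    s = np.sqrt(np.square(np.asarray(x, dtype=np.float64)) + np.square(np.asarray(y, dtype=np.float64))) / 255.0
    return s[()] if np.ndim(s) == 0 else s


def rgb_to_hue_sat(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel hue (degrees, [0, 360)) and normalized saturation ([0, 1]).

    Single-pass composition of :func:`rgb_to_chroma`,
    :func:`chroma_to_hue` and :func:`chroma_to_saturation`.
    """
    x, y = rgb_to_chroma(image)
    return chroma_to_hue(x, y), chroma_to_saturation(x, y)


def load_image(path: str | Path, *, rescale_16bit: bool = False) -> np.ndarray:
    """Decode a PNG/JPEG/TIFF file into an 8-bit RGB array.

    Alpha channels are stripped with a warning.  Grayscale images raise
    :class:`NonColorImageError`.  16-bit/channel images are rejected unless
    ``rescale_16bit=True``, in which case they are scaled onto 0-255
    (an explicit caller choice, never silent).
    """
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn(f"{path}: alpha channel stripped", stacklevel=2)
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise NonColorImageError(f"{path}: non-color image (shape {arr.shape})")
    if arr.dtype == np.uint16:
        if not rescale_16bit:
            raise NonColorImageError(
                f"{path}: 16-bit/channel image; pass rescale_16bit=True to scale onto 0-255"
            )
        arr = np.round(arr.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    if arr.dtype != np.uint8:
        raise NonColorImageError(f"{path}: unsupported channel dtype {arr.dtype}")
    return arr
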