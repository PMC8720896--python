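"""Polar Qualification System (PQS) compression of hue spectra.

The spectrum is drawn as a polar figure — vertex i at radius V_i and angle
i*alpha with alpha = 1 degree — and compressed into the gravity point of
that figure by triangular decomposition: each pair of consecutive vertices
spans a triangle with the origin of area (1/2) V_i V_{i+1} sin(alpha),
whose centroid is the mean of its vertices.  The gravity point is the
area-weighted mean of the triangle centroids:

    T     = 1/2 * sum_i V_i V_{i+1} sin(alpha)
    PQS_x = 1/(6T) * sum_i [V_i cos(i a) + V_{i+1} cos((i+1) a)] V_i V_{i+1} sin(a)
    PQS_y = 1/(6T) * sum_i [V_i sin(i a) + V_{i+1} sin((i+1) a)] V_i V_{i+1} sin(a)

For the full spectrum the fan is closed cyclically (pair 360 -> 1), which
makes the point covariant under rotation of the hue circle.  On a cropped
range the fan is left open: only consecutive pairs inside the range
contribute, with alpha unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import HueSpectrum, range_mask

ALPHA = 2.0 * np.pi / 360.0  # 1 degree, the angle between consecutive bins

__all__ = ["ALPHA", "PQSPoint", "UndefinedPQSError", "pqs_point", "pqs_point_in_range"]


class UndefinedPQSError(ValueError):
    """Raised when the polar figure has zero area, so no gravity point exists."""


@dataclass(frozen=True)
class PQSPoint:
    """Gravity point of a spectrum's polar figure.

    ``total_area`` is the summed triangle area T; ``bin_angle`` the angle
    between consecutive bins (1 degree in radians).
    """

    x: float
    y: float
    total_area: float
    bin_angle: float = ALPHA


def _vertices(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    angles = np.arange(1, 361) * ALPHA
    return values * np.cos(angles), values * np.sin(angles)


def _gravity(vx: np.ndarray, vy: np.ndarray, i_first: np.ndarray, i_second: np.ndarray) -> PQSPoint:
    """Gravity point over the triangles spanned by vertex index pairs."""
    x1, y1 = vx[i_first], vy[i_first]
    x2, y2 = vx[i_second], vy[i_second]
    # twice the signed triangle area; equals V_i V_{i+1} sin(alpha) here
    cross = x1 * y2 - x2 * y1
    t = 0.5 * float(np.sum(cross))
    if t == 0.0:
        raise UndefinedPQSError(
            "polar figure has zero area (no two consecutive non-zero bins); gravity point undefined"
        )
    px = float(np.sum((x1 + x2) * cross)) / (6.0 * t)
    py = float(np.sum((y1 + y2) * cross)) / (6.0 * t)
    return PQSPoint(x=px, y=py, total_area=t)


def pqs_point(spectrum: HueSpectrum) -> PQSPoint:
    """Gravity point of the full polar figure (cyclic closure 360 -> 1).

    Raises
    ------
    UndefinedPQSError
        If every triangle degenerates (no two consecutive non-zero bins).
    """
    vx, vy = _vertices(spectrum.values)
    i = np.arange(360)
    return _gravity(vx, vy, i, (i + 1) % 360)


def pqs_point_in_range(spectrum: HueSpectrum, lo: int, hi: int) -> PQSPoint:
    """Gravity point restricted to a (possibly wrapped) degree range.

    Only consecutive bin pairs whose both members lie inside the range
    contribute (open fan: no closure through the excluded arc).  The bin
    angle stays 1 degree; the cropped range is not rescaled onto the full
    circle.  The full range [1, 360] reduces exactly to :func:`pqs_point`.
    """
    mask = range_mask(lo, hi)
    if mask.all():
        return pqs_point(spectrum)
    vx, vy = _vertices(spectrum.values)
    i = np.arange(360)
    j = (i + 1) % 360
    keep = mask[i] & mask[j]
    return _gravity(vx, vy, i[keep], j[keep])
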