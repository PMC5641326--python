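"""Colour-space transforms for 8-bit RGB canopy images.

Implements the three colour models used for RGB vegetation indices:

* **HSI** (hue / saturation / intensity) — the classic cylindrical model
  with intensity defined as the *mean* of the normalised channels and hue
  from the arccos chromaticity formula.  This is the model in which the
  green-area classifiers operate (hue in degrees, red = 0°, green = 120°,
  blue = 240°).
* **CIE-Lab** and **CIE-Luv** — perceptually motivated spaces reached via
  sRGB gamma expansion and the D65 white point.  L (lightness, 0–100) is
  shared; a*/b* and u*/v* are the red–green and yellow–blue chroma axes.

All functions are vectorised over arbitrary leading dimensions: an
``(H, W, 3)`` image maps to ``(H, W)`` component planes; a single pixel
``(3,)`` maps to scalars.

The source space is assumed to be sRGB with the D65 white point — the
working space consumer JPEG cameras encode — since plot photographs carry
no ICC information.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rgb_to_hsi",
    "rgb_to_cielab",
    "rgb_to_cieluv",
    "srgb_to_linear",
    "rgb_to_xyz",
]

# D65 reference white (2° observer), XYZ scaled so that Y_n = 1.
_D65 = np.array([0.95047, 1.0, 1.08883])

def _srgb_matrix() -> np.ndarray:
    """sRGB (linear) -> XYZ from the primaries' chromaticities, scaled so
    that R=G=B maps *exactly* onto the D65 white axis (greys then land on
    the achromatic axis to floating-point precision)."""
    xy = ((0.64, 0.33), (0.30, 0.60), (0.15, 0.06))
    M = np.empty((3, 3))
    for i, (x, y) in enumerate(xy):
        M[:, i] = (x / y, 1.0, (1.0 - x - y) / y)
    return M * np.linalg.solve(M, _D65)


_M_RGB2XYZ = _srgb_matrix()

# CIE L* kink point: (6/29)^3 and the linear-segment slope.
_EPS = 216.0 / 24389.0
_KAPPA = 24389.0 / 27.0


def _as_float01(rgb: np.ndarray) -> np.ndarray:
    """Normalise 8-bit (or already-unit) RGB to float in [0, 1]."""
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of size 3, got shape {arr.shape}")
    if np.issubdtype(np.asarray(rgb).dtype, np.integer) or arr.max(initial=0.0) > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def rgb_to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit RGB to (hue°, saturation, intensity).

    Intensity is ``(R+G+B)/3`` on normalised channels, saturation is
    ``1 − min(R,G,B)/I`` and hue is the arccos chromaticity angle in
    degrees with red at 0°, green at 120° and blue at 240°.  Achromatic
    pixels (zero chroma) get hue 0° and saturation 0 by convention, so the
    transform is total: finite output for every valid pixel.
    """
    arr = _as_float01(rgb)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]

    intensity = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(intensity > 0.0, 1.0 - mn / np.where(intensity > 0, intensity, 1.0), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den < 1e-12
    cosang = np.where(achromatic, 1.0, num / np.where(achromatic, 1.0, den))
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(achromatic, 0.0, hue) % 360.0

    if arr.ndim == 1:
        return float(hue), float(saturation), float(intensity)
    return hue, saturation, intensity


def srgb_to_linear(channel: np.ndarray) -> np.ndarray:
    """Invert the sRGB piecewise gamma (IEC 61966-2-1) on unit-range values."""
    c = np.asarray(channel, dtype=np.float64)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """8-bit sRGB -> CIE XYZ (D65, Y in [0, 1])."""
    lin = srgb_to_linear(_as_float01(rgb))
    return lin @ _M_RGB2XYZ.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def rgb_to_cielab(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit sRGB to CIE-Lab (L in [0, 100]; a*, b* chroma axes).

    White (255,255,255) maps to L=100, a*=b*=0; any grey maps onto the
    achromatic axis a*=b*=0.
    """
    xyz = rgb_to_xyz(rgb) / _D65
    fx, fy, fz = _lab_f(xyz[..., 0]), _lab_f(xyz[..., 1]), _lab_f(xyz[..., 2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    if np.asarray(rgb).ndim == 1:
        return float(L), float(a), float(b)
    return L, a, b


def rgb_to_cieluv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit sRGB to CIE-Luv (L in [0, 100]; u*, v* chroma axes).

    Uses the 1976 u'v' chromaticity coordinates relative to D65; white and
    all greys map to u*=v*=0.  Black (Y=0) is returned as L=u*=v*=0.
    """
    xyz = rgb_to_xyz(rgb)
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]

    yr = Y / _D65[1]
    L = np.where(yr > _EPS, 116.0 * np.cbrt(yr) - 16.0, _KAPPA * yr)

    denom = X + 15.0 * Y + 3.0 * Z
    dn = _D65[0] + 15.0 * _D65[1] + 3.0 * _D65[2]
    un_ref = 4.0 * _D65[0] / dn
    vn_ref = 9.0 * _D65[1] / dn
    safe = denom > 1e-12
    up = np.where(safe, 4.0 * X / np.where(safe, denom, 1.0), un_ref)
    vp = np.where(safe, 9.0 * Y / np.where(safe, denom, 1.0), vn_ref)

    u = 13.0 * L * (up - un_ref)
    v = 13.0 * L * (vp - vn_ref)
    if np.asarray(rgb).ndim == 1:
        return float(L), float(u), float(v)
    return L, u, v
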