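"""Fluorescence color categorization of biopsy sites.

The study's reader called each biopsied area red (PpIX), green (connective
autofluorescence) or dull pink/brown (adipose). Here the call is a
deterministic rule in chromaticity space: the site's median chromaticity is
assigned a dominant wavelength and excitation purity relative to D65, and
banded — red for dominant wavelength >= 600 nm, green for [490, 570) nm,
each requiring a minimum purity ("dull" colors fall through to pink/brown).
The binary +RedFL/-RedFL call used by the diagnostic accuracy tables is
simply ``category == red``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .cmf import dominant_wavelength
from .colorimetry import decode_srgb_to_xyz
from .synthetic import _disc_indices, punch_radius_px
from .types import BiopsyRecord, ParameterError, SpecimenImage

RED_MIN_NM = 600.0
GREEN_BAND_NM = (490.0, 570.0)
DEFAULT_MIN_PURITY = 0.25


@dataclass
class ColorCall:
    """Color category of one site plus the quantities behind the call."""

    category: str  # red | green | pink_brown
    red_positive: bool
    dominant_wavelength_nm: float  # nan when undefined (white point / purple)
    purity: float
    out_of_locus: bool = False  # purple-region chromaticity, flagged

    def validate(self) -> "ColorCall":
        if self.category not in ("red", "green", "pink_brown"):
            raise ParameterError(f"unknown category {self.category!r}")
        if self.red_positive != (self.category == "red"):
            raise ParameterError("red_positive must equal (category == red)")
        return self


def site_chromaticity(image: SpecimenImage, site: BiopsyRecord) -> Tuple[float, float]:
    """Median (x, y) chromaticity over the punch disc.

    The median (per coordinate) is robust to speckle from interspersed
    tissue; pixels with zero tristimulus sum carry no chromaticity and are
    ignored.
    """
    rgb = image.rgb if isinstance(image, SpecimenImage) else np.asarray(image)
    h, w = rgb.shape[:2]
    rpx = punch_radius_px(site.punch_mm, getattr(image, "pixel_size_mm", 1.0))
    if not (rpx <= site.row < h - rpx and rpx <= site.col < w - rpx):
        raise ParameterError("punch disc extends outside the image")
    rr, cc = _disc_indices((h, w), (site.row, site.col), rpx)
    xyz = decode_srgb_to_xyz(rgb[rr, cc][None, :]).xyz[0]
    s = xyz.sum(axis=1)
    ok = s > 0
    if not ok.any():
        raise ParameterError("no pixel in the disc has a defined chromaticity")
    x = xyz[ok, 0] / s[ok]
    y = xyz[ok, 1] / s[ok]
    return float(np.median(x)), float(np.median(y))


def classify_color(p: Tuple[float, float],
                   min_purity: float = DEFAULT_MIN_PURITY) -> ColorCall:
    """Categorize a chromaticity as red, green or pink/brown.

    Band edges resolve to the longer-wavelength band (>= comparisons).
    Chromaticities in the purple region (no spectral dominant wavelength)
    fall through to pink/brown and are flagged.
    """
    x, y = float(p[0]), float(p[1])
    if not (0 <= x <= 1 and 0 <= y <= 1 and x + y <= 1 + 1e-9):
        raise ParameterError(f"invalid chromaticity ({x}, {y})")
    wl, purity, in_gamut = dominant_wavelength((x, y))
    if not in_gamut:
        return ColorCall("pink_brown", False, float("nan"), purity, True).validate()
    category = "pink_brown"
    if not math.isnan(wl) and purity >= min_purity:
        if wl >= RED_MIN_NM:
            category = "red"
        elif GREEN_BAND_NM[0] <= wl < GREEN_BAND_NM[1]:
            category = "green"
    return ColorCall(category, category == "red", wl, purity).validate()


def binarize_call(call: ColorCall) -> bool:
    """+RedFL/-RedFL: positive iff the category is red."""
    call.validate()
    return call.category == "red"


def classify_site(image: SpecimenImage, site: BiopsyRecord,
                  min_purity: float = DEFAULT_MIN_PURITY) -> ColorCall:
    """Chromaticity extraction plus categorization for one biopsy site."""
    return classify_color(site_chromaticity(image, site), min_purity)


def annotate_records(image: SpecimenImage, records,
                     min_purity: float = DEFAULT_MIN_PURITY):
    """Fill the fluorescence call fields of biopsy records in place."""
    for rec in records:
        call = classify_site(image, rec, min_purity)
        rec.call = call.category
        rec.red_positive = call.red_positive
    return records
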