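"""Chromaticity-space tumor-to-normal fluorescence contrast analysis.

Images are decoded from gamma-encoded 8-bit sRGB to CIE XYZ (IEC 61966-2-1
transfer, sRGB primaries, D65 white, white normalized to Y = 1). Mean X, Y,
Z are taken over each region of interest *first* and then projected to (x, y)
chromaticity — i.e. the ROI chromaticity is luminance-weighted — and the
Euclidean distance between the tumor and normal chromaticities is the
contrast score. Group contrasts are compared with one-way ANOVA plus Tukey
HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage.draw import polygon2mask, polygon_perimeter

from .types import (
    TISSUE_CLASSES,
    AnalysisError,
    ChromaticityPair,
    ParameterError,
    SpecimenImage,
    TissueLabelMap,
    TumorBorder,
)

# sRGB (D65) matrices, IEC 61966-2-1.
RGB_TO_XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
XYZ_TO_RGB = np.linalg.inv(RGB_TO_XYZ)

#: Approximate just-noticeable chromaticity difference (MacAdam-scale JND);
#: used only to express a distance in perceptual steps when reporting.
DEFAULT_JND = 0.004


def srgb_decode(values: np.ndarray) -> np.ndarray:
    """Inverse sRGB transfer: encoded [0, 1] -> linear [0, 1]."""
    v = np.asarray(values, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(values: np.ndarray) -> np.ndarray:
    """Forward sRGB transfer: linear [0, 1] -> encoded [0, 1]."""
    v = np.asarray(values, dtype=float)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * np.clip(v, 0, None) ** (1 / 2.4) - 0.055)


def srgb_decode_value(v: float) -> float:
    return float(srgb_decode(np.asarray(v)))


@dataclass
class XYZRaster:
    """Per-pixel CIE XYZ values decoded from a specimen image."""

    xyz: np.ndarray  # (H, W, 3)

    @property
    def X(self) -> np.ndarray:
        return self.xyz[..., 0]

    @property
    def Y(self) -> np.ndarray:
        return self.xyz[..., 1]

    @property
    def Z(self) -> np.ndarray:
        return self.xyz[..., 2]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.xyz.shape[:2]


@dataclass
class ROIMask:
    """Include/exclude pixel masks; the effective ROI is include & ~exclude."""

    include: np.ndarray
    exclude: np.ndarray

    def effective(self) -> np.ndarray:
        if self.include.shape != self.exclude.shape:
            raise ParameterError("include/exclude mask shapes differ")
        return self.include & ~self.exclude


def decode_srgb_to_xyz(image) -> XYZRaster:
    """Decode an 8-bit sRGB image (array or SpecimenImage) to XYZ."""
    rgb = image.rgb if isinstance(image, SpecimenImage) else np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError("expected an (H, W, 3) RGB image")
    if rgb.dtype != np.uint8:
        raise ParameterError("expected 8-bit channel depth")
    lin = srgb_decode(rgb.astype(float) / 255.0)
    return XYZRaster(lin @ RGB_TO_XYZ.T)


def roi_mean_chromaticity(raster: XYZRaster, roi: ROIMask) -> Tuple[float, float]:
    """Mean-XYZ-then-project chromaticity of an ROI.

    Averaging happens in XYZ first; the projection to (x, y) follows. The
    order is part of the contract (luminance-weighted chromaticity).
    """
    mask = roi.effective()
    if mask.shape != raster.shape:
        raise ParameterError("ROI mask shape does not match raster")
    if not mask.any():
        raise AnalysisError("effective ROI is empty")
    mean = raster.xyz[mask].mean(axis=0)
    total = mean.sum()
    if total <= 0:
        raise AnalysisError("chromaticity undefined: mean X+Y+Z is zero")
    return float(mean[0] / total), float(mean[1] / total)


def chromatic_distance(p: Tuple[float, float], q: Tuple[float, float]) -> float:
    """Euclidean distance between two (x, y) chromaticities."""
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def distance_in_jnd(distance: float, jnd: float = DEFAULT_JND) -> float:
    """Express a chromatic distance in approximate just-noticeable steps."""
    if jnd <= 0:
        raise ParameterError("jnd must be positive")
    return distance / jnd


@dataclass
class GroupContrastResult:
    """One-way ANOVA + Tukey HSD over per-group chromatic distances."""

    distances: Dict[str, List[float]]
    means: Dict[str, float]
    sds: Dict[str, float]
    f_statistic: float
    p_value: float
    tukey_p: Dict[Tuple[str, str], float]

    def as_dict(self) -> dict:
        return {
            "means": self.means,
            "sds": self.sds,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "tukey_p": {f"{a}|{b}": p for (a, b), p in self.tukey_p.items()},
            "distances": {k: list(map(float, v)) for k, v in self.distances.items()},
        }


def group_contrast(distances_by_group: Dict[str, List[float]]) -> GroupContrastResult:
    """Compare per-group distances with one-way ANOVA and Tukey HSD.

    Degenerate variance structures that the F statistic cannot express
    (all values identical, or zero within-group variance with distinct
    means) are resolved to their limits: F=0/p=1 and F=inf/p=0
    respectively, with pairwise Tukey p-values of 1 or 0 by mean equality.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in distances_by_group.items()}
    if len(groups) < 2:
        raise AnalysisError("need at least two groups for ANOVA")
    if any(len(v) < 2 for v in groups.values()):
        raise AnalysisError("every group needs at least two values")
    names = list(groups)
    values = [groups[k] for k in names]
    means = {k: float(v.mean()) for k, v in groups.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in groups.items()}

    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    if ss_within <= 0 and ss_between <= 0:
        f_stat, p_val = 0.0, 1.0
        tukey = {(a, b): 1.0 for a, b in combinations(names, 2)}
    elif ss_within <= 0:
        f_stat, p_val = float("inf"), 0.0
        tukey = {(a, b): (1.0 if means[a] == means[b] else 0.0)
                 for a, b in combinations(names, 2)}
    else:
        f_stat, p_val = stats.f_oneway(*values)
        res = stats.tukey_hsd(*values)
        tukey = {(names[i], names[j]): float(res.pvalue[i, j])
                 for i, j in combinations(range(len(names)), 2)}
    return GroupContrastResult(
        {k: list(map(float, v)) for k, v in groups.items()},
        means, sds, float(f_stat), float(p_val), tukey)


# ---------------------------------------------------------------------------
# Specimen-level ROI construction and contrast


def border_inside_mask(border: TumorBorder, shape: Tuple[int, int]) -> np.ndarray:
    """Rasterize the border polygon: even-odd fill with boundary pixels
    counted inside."""
    border.validate()
    if not border.defined:
        raise AnalysisError("specimen has an undefined tumor border")
    poly = np.asarray(border.polygon, dtype=float)
    mask = polygon2mask(shape, poly)
    rr, cc = polygon_perimeter(np.clip(poly[:, 0], 0, shape[0] - 1),
                               np.clip(poly[:, 1], 0, shape[1] - 1), shape=shape)
    mask[rr, cc] = True
    return mask


def specimen_rois(label_map: TissueLabelMap, border: TumorBorder) -> Tuple[ROIMask, ROIMask]:
    """Tumor and normal ROI masks for one specimen.

    Excluded everywhere: background (no tissue), the scale-marker sticker,
    and occult cancer outside the border (histologically confirmed cancer
    does not belong in the normal reference region).
    """
    labels = label_map.labels
    inside = border_inside_mask(border, labels.shape)
    background = labels == TISSUE_CLASSES["background"]
    scale = labels == TISSUE_CLASSES["scale_marker"]
    occult = labels == TISSUE_CLASSES["occult_cancer"]
    occult_zone = ndimage.binary_dilation(occult, iterations=3)
    exclude = background | scale | occult_zone
    tumor_roi = ROIMask(inside, exclude)
    normal_roi = ROIMask(~inside, exclude)
    return tumor_roi, normal_roi


def specimen_contrast(image: SpecimenImage, label_map: TissueLabelMap,
                      border: TumorBorder) -> ChromaticityPair:
    """Tumor-vs-normal chromaticity pair for one specimen image."""
    raster = decode_srgb_to_xyz(image)
    tumor_roi, normal_roi = specimen_rois(label_map, border)
    xy_t = roi_mean_chromaticity(raster, tumor_roi)
    xy_n = roi_mean_chromaticity(raster, normal_roi)
    return ChromaticityPair(xy_t, xy_n, chromatic_distance(xy_t, xy_n))
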