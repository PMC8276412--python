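"""Tissue-composition analysis of biopsy punch discs.

Computes per-biopsy area fractions (percent cancer / connective / adipose of
tissue pixels) and the carcinoma-to-connective ratio from a labeled mask, and
compares red- vs green-classified biopsies with Mann-Whitney tests. Low
ratios are the operational correlate of connective-tissue "masking" of PpIX
fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .synthetic import _disc_indices, punch_radius_px
from .types import (
    CANCER_CODES,
    TISSUE_CLASSES,
    AnalysisError,
    BiopsyRecord,
    TissueLabelMap,
)


@dataclass
class CompositionRecord:
    """Tissue-area fractions within one punch disc (tissue pixels only)."""

    pct_cancer: float
    pct_connective: float
    pct_adipose: float
    ratio_cancer_connective: Optional[float]  # None when no connective pixels
    tissue_pixels: int

    @property
    def ratio_defined(self) -> bool:
        return self.ratio_cancer_connective is not None


def area_fractions(label_map: TissueLabelMap, site: BiopsyRecord) -> CompositionRecord:
    """Area fractions and carcinoma-to-connective ratio for one biopsy disc.

    Percentages are taken over tissue pixels (background and the scale
    sticker excluded). The ratio is cancer pixels / connective pixels,
    undefined (None) when the disc has no connective tissue.
    """
    labels = label_map.validate().labels
    rpx = punch_radius_px(site.punch_mm, label_map.pixel_size_mm)
    pix = labels[_disc_indices(labels.shape, (site.row, site.col), rpx)]
    non_tissue = (TISSUE_CLASSES["background"], TISSUE_CLASSES["scale_marker"])
    tissue = pix[~np.isin(pix, non_tissue)]
    if tissue.size == 0:
        raise AnalysisError("punch disc contains no tissue pixels")
    n_cancer = int(np.isin(tissue, CANCER_CODES).sum())
    n_conn = int((tissue == TISSUE_CLASSES["connective"]).sum())
    n_adip = int((tissue == TISSUE_CLASSES["adipose"]).sum())
    n = tissue.size
    ratio = None if n_conn == 0 else n_cancer / n_conn
    return CompositionRecord(100.0 * n_cancer / n, 100.0 * n_conn / n,
                             100.0 * n_adip / n, ratio, n)


def compare_composition(group_a: Sequence[float],
                        group_b: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U comparison of two composition samples.

    Exact two-sided p for combined n <= 20 without ties; otherwise the
    normal approximation with tie correction (no continuity correction, so
    identical samples give p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if combined.size <= 20 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))
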