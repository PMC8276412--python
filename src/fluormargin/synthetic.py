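"""Synthetic fluorescence specimen generator.

Emulates the gross-specimen slices the imaging study photographed: a
lobulated primary tumor inside a connective/adipose tissue slab, grossly
occult cancer foci outside the demarcated border, benign-proliferative sites
that may express PpIX (false positives), and connective-tissue "masking"
(cancer rendered non-red when the carcinoma-to-connective ratio in the
sampled area is low). Every downstream stage — chromaticity contrast, color
classification, diagnostic accuracy, spectroscopy, composition — runs on
these synthetic specimens with known ground truth.

Color physics: each tissue class emits a parametric spectrum (PpIX peaks at
635/705 nm; connective autofluorescence at 520 nm; broad dull adipose
autofluorescence), which is integrated against the CIE 1931 2-degree CMFs
and encoded through the sRGB/D65 transfer into an 8-bit image, mirroring the
consumer-sensor acquisition path assumed by the downstream RGB-to-XYZ
analysis.

Biopsy pockets are constructed with exact tumor/connective pixel counts
interleaved inside the punch disc, so the carcinoma-to-connective ratio and
the resulting red/non-red appearance of a site are controlled by design
rather than left to per-pixel sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .colorimetry import XYZ_TO_RGB, srgb_decode_value, srgb_encode
from .cmf import spectrum_to_xyz
from .types import (
    CANCER_CODES,
    TISSUE_CLASSES,
    BiopsyRecord,
    EmissionSpectrum,
    ParameterError,
    PlacementError,
    SpecimenImage,
    TissueLabelMap,
    TumorBorder,
)

# ---------------------------------------------------------------------------
# Spectral model constants (arbitrary units on a 0-100 intensity scale).

SPECTRUM_SCALE = 100.0
PPIX_PEAK_NM = 635.0
PPIX_MINOR_PEAK_NM = 705.0
PPIX_MINOR_RATIO = 0.2
PPIX_SIGMA_NM = 12.0
CONNECTIVE_PEAK_NM = 520.0
CONNECTIVE_SIGMA_NM = 30.0
ADIPOSE_PEAK_NM = 600.0
ADIPOSE_SIGMA_NM = 90.0

#: Relative PpIX brightness against the unit-amplitude connective AF. PpIX is
#: spectrally narrow (sigma 12 nm) while the AF components are broad, so a
#: large peak amplitude is needed for the red emission to dominate the
#: tristimulus integral of a cancer pixel the way it visually dominates the
#: clinical images.
PPIX_AMPLITUDE = 3.0
#: Class-conditional autofluorescence weights (connective AF, adipose AF).
_AF_WEIGHTS = {
    TISSUE_CLASSES["tumor"]: (0.10, 0.04),
    TISSUE_CLASSES["occult_cancer"]: (0.10, 0.04),
    TISSUE_CLASSES["benign_proliferative"]: (0.10, 0.04),
    TISSUE_CLASSES["connective"]: (1.00, 0.05),
    TISSUE_CLASSES["adipose"]: (0.03, 0.40),
    TISSUE_CLASSES["scale_marker"]: (0.0, 0.0),
    TISSUE_CLASSES["background"]: (0.0, 0.0),
}
_SCALE_MARKER_FLAT = 1.2

# RNG stream ids fanned out per specimen from the single config seed.
_STREAM_PLAN, _STREAM_MAP, _STREAM_RENDER, _STREAM_BIOPSY, _STREAM_SPECTRUM = range(5)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dose group.

    Defaults encode the trial design being emulated: n = 15 specimens per
    group, outside-border occult-cancer site prevalence ~0.2, roughly a third
    of cancer sites masked by connective tissue, benign-proliferative false
    positives at ~0.3 expressing sites per specimen, and 80% of specimens
    with a clinically definable tumor border.
    """

    dose_group: str = "high"
    n_specimens: int = 15
    g_low: float = 1.0
    g_high: float = 1.0
    occult_focus_rate: float = 2.0
    occult_site_prevalence: float = 0.2
    benign_focus_rate: float = 0.6
    benign_positive_rate: float = 0.5
    masking_rate: float = 0.35
    masking_ratio_threshold: float = 0.20
    masked_ppix_fraction: float = 0.30
    border_defined_prob: float = 0.8
    noise_sd: float = 2.0
    seed: int = 0
    shape: Tuple[int, int] = (144, 192)
    pixel_size_mm: float = 0.5

    @property
    def dose_gain(self) -> float:
        return {"control": 0.0, "low": self.g_low, "high": self.g_high}[self.dose_group]

    def validate(self) -> "SimulationConfig":
        if self.dose_group not in ("control", "low", "high"):
            raise ParameterError(f"unknown dose group {self.dose_group!r}")
        if not (self.g_high >= self.g_low > 0):
            raise ParameterError("dose gains must satisfy g_high >= g_low > 0")
        if self.n_specimens < 1:
            raise ParameterError("n_specimens must be positive")
        for name in ("occult_site_prevalence", "benign_positive_rate",
                     "masking_rate", "border_defined_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.occult_focus_rate < 0 or self.benign_focus_rate < 0:
            raise ParameterError("focus rates must be non-negative")
        if self.masking_ratio_threshold <= 0:
            raise ParameterError("masking_ratio_threshold must be positive")
        if not 0 <= self.masked_ppix_fraction <= 1:
            raise ParameterError("masked_ppix_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be positive")
        if len(self.shape) != 2 or min(self.shape) < 48:
            raise ParameterError("grid must be 2-D and at least 48 pixels on a side")
        return self

    def with_dose(self, dose_group: str) -> "SimulationConfig":
        return replace(self, dose_group=dose_group)


_DOSE_IDX = {"control": 0, "low": 1, "high": 2}


def _rng(config: SimulationConfig, specimen_index: int, stream: int,
         extra: Tuple[int, ...] = ()) -> np.random.Generator:
    # Dose groups are distinct simulated patients, so the group index joins
    # the stream key alongside the specimen index.
    ss = np.random.SeedSequence(entropy=int(config.seed) % (2 ** 31),
                                spawn_key=(int(specimen_index), stream,
                                           _DOSE_IDX[config.dose_group]) + tuple(extra))
    return np.random.default_rng(ss)


def punch_radius_px(punch_mm: float, pixel_size_mm: float) -> int:
    return max(1, int(round(punch_mm / 2.0 / pixel_size_mm)))


def _disc_indices(shape, center, radius) -> Tuple[np.ndarray, np.ndarray]:
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return np.nonzero(mask)


# ---------------------------------------------------------------------------
# Emission spectra


def _gauss(wl, mu, sigma):
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def default_wavelength_grid(step_nm: float = 1.0) -> np.ndarray:
    return np.arange(500.0, 800.0 + 0.5 * step_nm, step_nm)


def ppix_component(wl) -> np.ndarray:
    return _gauss(wl, PPIX_PEAK_NM, PPIX_SIGMA_NM) + PPIX_MINOR_RATIO * _gauss(
        wl, PPIX_MINOR_PEAK_NM, PPIX_SIGMA_NM)


def tissue_emission_spectrum(tissue_class, cancer_cell_fraction: float,
                             dose_gain: float,
                             wavelength_nm: Optional[np.ndarray] = None) -> EmissionSpectrum:
    """Parametric emission spectrum of one tissue class.

    PpIX contributes Gaussian peaks at 635 nm (major) and 705 nm (minor)
    with amplitude proportional to ``dose_gain * cancer_cell_fraction``;
    connective autofluorescence peaks at 520 nm; adipose autofluorescence is
    a broad dull component spanning the green-to-red range.
    """
    if isinstance(tissue_class, str):
        if tissue_class not in TISSUE_CLASSES:
            raise ParameterError(f"unknown tissue class {tissue_class!r}")
        code = TISSUE_CLASSES[tissue_class]
    else:
        code = int(tissue_class)
        if code not in _AF_WEIGHTS:
            raise ParameterError(f"unknown tissue class code {code}")
    if not 0 <= cancer_cell_fraction <= 1:
        raise ParameterError("cancer_cell_fraction must lie in [0, 1]")
    if dose_gain < 0:
        raise ParameterError("dose_gain must be non-negative")
    wl = default_wavelength_grid() if wavelength_nm is None else np.asarray(wavelength_nm, float)

    w_conn, w_adip = _AF_WEIGHTS[code]
    inten = w_conn * _gauss(wl, CONNECTIVE_PEAK_NM, CONNECTIVE_SIGMA_NM)
    inten = inten + w_adip * _gauss(wl, ADIPOSE_PEAK_NM, ADIPOSE_SIGMA_NM)
    if code == TISSUE_CLASSES["scale_marker"]:
        inten = inten + _SCALE_MARKER_FLAT
    if code in CANCER_CODES + (TISSUE_CLASSES["benign_proliferative"],):
        inten = inten + PPIX_AMPLITUDE * dose_gain * cancer_cell_fraction * ppix_component(wl)
    return EmissionSpectrum(wl, SPECTRUM_SCALE * inten).validate()


# ---------------------------------------------------------------------------
# Sampling plan shared by the map generator and the biopsy sampler


@dataclass
class _SitePlan:
    kind: str          # inside | cancer | other
    punch_mm: float
    masked: bool
    share: float       # cancer-pixel share of the punch disc (cancer pockets)


def _draw_share(rng, masked: bool) -> float:
    # Masked pockets: carcinoma-to-connective pixel ratio u/(1-u) below the
    # 0.20 masking threshold. Unmasked pockets: clear cancer-pixel majority.
    return float(rng.uniform(0.06, 0.15)) if masked else float(rng.uniform(0.62, 0.82))


def _sampling_plan(config: SimulationConfig, specimen_index: int) -> List[_SitePlan]:
    rng = _rng(config, specimen_index, _STREAM_PLAN)
    plans = []
    masked = bool(rng.random() < config.masking_rate)
    plans.append(_SitePlan("inside", 4.0, masked, _draw_share(rng, masked)))
    n_out = int(rng.integers(1, 4))
    for _ in range(n_out):
        punch = 2.0 if rng.random() < 0.5 else 4.0
        is_cancer = bool(rng.random() < config.occult_site_prevalence) \
            and config.occult_focus_rate > 0
        masked = bool(rng.random() < config.masking_rate)
        share = _draw_share(rng, masked)
        plans.append(_SitePlan("cancer" if is_cancer else "other", punch, masked, share))
    return plans


# ---------------------------------------------------------------------------
# Label map generation


def _carve_pocket(labels, fraction, rng, center, inner_radius, outer_pad,
                  share, tissue_code, ppix_fraction):
    """Connective-halo pocket with an exact count of cancer-class pixels
    interleaved inside the inner disc."""
    shape = labels.shape
    halo = _disc_indices(shape, center, inner_radius + outer_pad)
    labels[halo] = TISSUE_CLASSES["connective"]
    fraction[halo] = 0.0
    rr, cc = _disc_indices(shape, center, inner_radius)
    n = len(rr)
    k = int(np.clip(round(share * n), 1, max(1, n - 1)))
    order = rng.permutation(n)[:k]
    labels[rr[order], cc[order]] = tissue_code
    fraction[rr[order], cc[order]] = ppix_fraction


def _place_center(rng, free_ok, shape, radius, taken, min_sep, tries=500):
    """Rejection-sample a pocket center; ``free_ok(r, c, radius)`` tests the
    footprint, ``taken`` holds previously used (r, c, radius) triples."""
    for attempt in range(tries):
        r = int(rng.integers(radius + 1, shape[0] - radius - 1))
        c = int(rng.integers(radius + 1, shape[1] - radius - 1))
        if not free_ok(r, c, radius):
            continue
        sep_needed = min_sep if attempt < tries - 50 else 0  # relax at the end
        if all((r - tr) ** 2 + (c - tc) ** 2 >= (radius + trad + sep_needed) ** 2
               for tr, tc, trad in taken):
            return r, c
    return None


def generate_label_map(config: SimulationConfig,
                       specimen_index: int) -> Tuple[TissueLabelMap, TumorBorder]:
    """Generate one specimen's ground-truth tissue map and demarcated border.

    Deterministic for fixed ``(config.seed, specimen_index)``.
    """
    config.validate()
    if specimen_index < 0:
        raise ParameterError("specimen_index must be >= 0")
    rng = _rng(config, specimen_index, _STREAM_MAP)
    plan = _sampling_plan(config, specimen_index)
    h, w = config.shape
    labels = np.zeros((h, w), dtype=np.int8)
    fraction = np.zeros((h, w), dtype=float)

    # Tissue slab: ellipse of connective/adipose partitioned by a smooth field.
    rr, cc = np.ogrid[:h, :w]
    tissue = ((rr - h / 2) / (0.40 * h)) ** 2 + ((cc - w / 2) / (0.44 * w)) ** 2 <= 1.0
    af_field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8)
    af_field /= max(af_field.std(), 1e-12)
    labels[tissue & (af_field >= -0.15)] = TISSUE_CLASSES["connective"]
    labels[tissue & (af_field < -0.15)] = TISSUE_CLASSES["adipose"]

    # Scale-marker sticker in a background corner.
    labels[4:18, 4:18] = TISSUE_CLASSES["scale_marker"]

    # Lobulated primary tumor blob near the slab center.
    tissue_core = ndimage.binary_erosion(tissue, iterations=8)
    bc = (h / 2 + rng.uniform(-8, 8), w / 2 + rng.uniform(-12, 12))
    r0 = rng.uniform(13, 18)
    blob = np.zeros((h, w), dtype=bool)
    lobes = [(bc, r0)]
    for _ in range(int(rng.integers(3, 6))):
        off = rng.uniform(-0.7 * r0, 0.7 * r0, size=2)
        lobes.append(((bc[0] + off[0], bc[1] + off[1]), r0 * rng.uniform(0.4, 0.75)))
    for (lr, lc), lrad in lobes:
        blob |= (rr - lr) ** 2 + (cc - lc) ** 2 <= lrad ** 2
    blob &= tissue_core
    f_tumor = float(rng.uniform(0.85, 1.0))
    labels[blob] = TISSUE_CLASSES["tumor"]
    fraction[blob] = f_tumor
    # Carcinoma-associated fibrosis: green connective mottling interspersed
    # through the red tumor mass (~20% of blob area).
    mottle = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3)
    mottle /= max(mottle.std(), 1e-12)
    speckle = blob & (mottle > 0.8)
    labels[speckle] = TISSUE_CLASSES["connective"]
    fraction[speckle] = 0.0

    # Inside-border biopsy pocket at the deepest point of the blob.
    dist = ndimage.distance_transform_edt(blob)
    spot = np.unravel_index(int(np.argmax(dist)), dist.shape)
    inside_plan = plan[0]
    rp_in = punch_radius_px(inside_plan.punch_mm, config.pixel_size_mm)
    _carve_pocket(labels, fraction, rng, spot, rp_in, 2, inside_plan.share,
                  TISSUE_CLASSES["tumor"],
                  config.masked_ppix_fraction if inside_plan.masked else f_tumor)

    # Demarcated border: contour of the dilated blob.
    inside_mask = ndimage.binary_dilation(blob, iterations=3)
    contours = measure.find_contours(inside_mask.astype(float), 0.5)
    defined = bool(rng.random() < config.border_defined_prob) and bool(contours)
    polygon = np.empty((0, 2))
    if contours:
        polygon = max(contours, key=len)[::3]
    border = TumorBorder(polygon if defined else np.empty((0, 2)), defined).validate()

    # Occult cancer foci strictly outside the border and benign foci.
    exclusion = ndimage.binary_dilation(inside_mask, iterations=8)

    def free_ok(r, c, radius):
        rr_f, cc_f = _disc_indices((h, w), (r, c), radius + 1)
        if exclusion[rr_f, cc_f].any():
            return False
        ok_classes = (TISSUE_CLASSES["connective"], TISSUE_CLASSES["adipose"])
        return bool(np.isin(labels[rr_f, cc_f], ok_classes).all())

    taken: List[Tuple[int, int, int]] = []
    cancer_slots = [p for p in plan if p.kind == "cancer"]
    n_foci = 0
    if config.occult_focus_rate > 0:
        n_foci = max(int(rng.poisson(config.occult_focus_rate)), len(cancer_slots))
    planned_foci: List[Tuple[int, int]] = []
    for i in range(n_foci):
        slot = cancer_slots[i] if i < len(cancer_slots) else None
        if slot is not None:
            inner = punch_radius_px(slot.punch_mm, config.pixel_size_mm)
            share, masked = slot.share, slot.masked
        else:
            inner = int(round(rng.uniform(2.5, 5.0)))
            masked = bool(rng.random() < config.masking_rate)
            share = _draw_share(rng, masked)
        center = _place_center(rng, free_ok, (h, w), inner + 2, taken, min_sep=4)
        if center is None:
            continue
        _carve_pocket(labels, fraction, rng, center, inner, 2, share,
                      TISSUE_CLASSES["occult_cancer"],
                      config.masked_ppix_fraction if masked else float(rng.uniform(0.85, 1.0)))
        taken.append((center[0], center[1], inner + 2))
        if slot is not None:
            planned_foci.append(center)

    benign_foci = []
    for _ in range(int(rng.poisson(config.benign_focus_rate))):
        expressing = bool(rng.random() < config.benign_positive_rate)
        inner = int(round(rng.uniform(4.0, 5.0)))
        share = float(rng.uniform(0.6, 0.8))
        center = _place_center(rng, free_ok, (h, w), inner + 2, taken, min_sep=4)
        if center is None:
            continue
        _carve_pocket(labels, fraction, rng, center, inner, 2, share,
                      TISSUE_CLASSES["benign_proliferative"], 0.8 if expressing else 0.0)
        taken.append((center[0], center[1], inner + 2))
        benign_foci.append({"center": center, "expressing": expressing})

    meta = {
        "specimen_index": int(specimen_index),
        "inside_spot": (int(spot[0]), int(spot[1])),
        "planned_foci": planned_foci,
        "benign_foci": benign_foci,
        "n_occult_foci": len(taken) - len(benign_foci),
        "f_tumor": f_tumor,
    }
    label_map = TissueLabelMap(labels, config.pixel_size_mm, fraction, meta).validate()
    return label_map, border


# ---------------------------------------------------------------------------
# Rendering


def _unique_class_fraction(labels, fraction):
    """Unique (class, cancer_cell_fraction) pairs and the inverse index.

    Pairs are packed into one float key (2*class + fraction, exact in double
    precision since fraction is in [0, 1]) so uniqueness is a cheap 1-D sort.
    """
    keys = 2.0 * labels.astype(float) + np.asarray(fraction, float)
    uniq, inverse = np.unique(keys, return_inverse=True)
    cls = np.floor(uniq / 2.0)
    pairs = np.stack([cls, uniq - 2.0 * cls], axis=1)
    return pairs, inverse.ravel()


def render_fluorescence_image(label_map: TissueLabelMap,
                              config: SimulationConfig) -> SpecimenImage:
    """Render a label map to a gamma-encoded 8-bit sRGB fluorescence image.

    Per pixel: emission spectrum -> CIE XYZ (CMF integration) -> linear sRGB
    (D65) -> exposure normalization (99th-percentile linear value maps to
    code 245) -> sRGB transfer -> additive Gaussian sensor noise ->
    quantization.
    """
    label_map.validate()
    config.validate()
    idx = int(label_map.meta.get("specimen_index", 0))
    gain = config.dose_gain

    pairs, inverse = _unique_class_fraction(label_map.labels.ravel(),
                                            label_map.cancer_cell_fraction.ravel())
    wl = default_wavelength_grid(step_nm=2.0)
    palette = np.zeros((len(pairs), 3))
    for i, (cls, frac) in enumerate(pairs):
        spec = tissue_emission_spectrum(int(cls), float(frac), gain, wl)
        palette[i] = spectrum_to_xyz(spec.wavelength_nm, spec.intensity)
    xyz = palette[inverse].reshape(label_map.labels.shape + (3,))

    lin = np.clip(xyz @ XYZ_TO_RGB.T, 0.0, None)
    q99 = np.percentile(lin, 99)
    target = srgb_decode_value(245.0 / 255.0)
    scale = target / q99 if q99 > 0 else 1.0
    encoded = srgb_encode(np.clip(lin * scale, 0.0, 1.0)) * 255.0
    if config.noise_sd > 0:
        rng = _rng(config, idx, _STREAM_RENDER)
        encoded = encoded + rng.normal(0.0, config.noise_sd, size=encoded.shape)
    rgb = np.clip(np.rint(encoded), 0, 255).astype(np.uint8)
    return SpecimenImage(rgb, label_map.pixel_size_mm, config.dose_group,
                         specimen_id=f"{config.dose_group}-{idx:03d}").validate()


# ---------------------------------------------------------------------------
# Biopsy sampling and point spectroscopy


def sample_biopsies(label_map: TissueLabelMap, border: TumorBorder,
                    config: SimulationConfig) -> List[BiopsyRecord]:
    """Sample 1-4 punch-biopsy sites per specimen with ground-truth labels.

    One site is always taken inside the demarcated tumor border (at the
    pocket the map generator carved); outside sites target occult foci,
    expressing benign foci (the "red areas" the study deliberately biopsied)
    and normal tissue. Sites do not overlap.
    """
    label_map.validate()
    config.validate()
    idx = int(label_map.meta.get("specimen_index", 0))
    plan = _sampling_plan(config, idx)
    rng = _rng(config, idx, _STREAM_BIOPSY)
    h, w = label_map.labels.shape
    specimen_id = f"{config.dose_group}-{idx:03d}"

    spot = label_map.meta.get("inside_spot")
    if spot is None:
        raise PlacementError("label map carries no inside biopsy pocket")
    rp = punch_radius_px(plan[0].punch_mm, config.pixel_size_mm)
    if not (rp <= spot[0] < h - rp and rp <= spot[1] < w - rp):
        raise PlacementError("specimen too small to place the inside punch")

    def make_record(site_id, center, punch_mm, stratum):
        rpx = punch_radius_px(punch_mm, config.pixel_size_mm)
        pix = label_map.labels[_disc_indices((h, w), center, rpx)]
        histology = "pos" if np.isin(pix, CANCER_CODES).any() else "neg"
        prolif = int((pix == TISSUE_CLASSES["benign_proliferative"]).any())
        return BiopsyRecord(specimen_id, site_id, int(center[0]), int(center[1]),
                            punch_mm, stratum, histology, prolif,
                            dose_group=config.dose_group).validate()

    records = [make_record(1, spot, plan[0].punch_mm, "inside")]
    placed = [(spot[0], spot[1], rp)]

    cancer_centers = list(label_map.meta.get("planned_foci", []))
    benign_centers = [b["center"] for b in label_map.meta.get("benign_foci", [])
                      if b["expressing"]]
    site_id = 2
    for slot in plan[1:]:
        rpx = punch_radius_px(slot.punch_mm, config.pixel_size_mm)
        center = None
        if slot.kind == "cancer" and cancer_centers:
            center = cancer_centers.pop(0)
        elif slot.kind == "other" and benign_centers:
            center = benign_centers.pop(0)
        if center is None and slot.kind == "other":
            center = _sample_normal_site(rng, label_map, rpx, placed)
        if center is None:
            continue
        records.append(make_record(site_id, center, slot.punch_mm, "outside"))
        placed.append((center[0], center[1], rpx))
        site_id += 1
    return records


def _sample_normal_site(rng, label_map, rpx, placed, tries=300):
    h, w = label_map.labels.shape
    normal = (TISSUE_CLASSES["connective"], TISSUE_CLASSES["adipose"])
    for _ in range(tries):
        r = int(rng.integers(rpx + 1, h - rpx - 1))
        c = int(rng.integers(rpx + 1, w - rpx - 1))
        pix = label_map.labels[_disc_indices((h, w), (r, c), rpx + 3)]
        if not np.isin(pix, normal).all():
            continue
        if all((r - pr) ** 2 + (c - pc) ** 2 >= (rpx + prad + 2) ** 2
               for pr, pc, prad in placed):
            return (r, c)
    return None


def generate_point_spectrum(site: BiopsyRecord, label_map: TissueLabelMap,
                            config: SimulationConfig) -> EmissionSpectrum:
    """Fiber-probe emission spectrum at a biopsy site.

    Area-weighted mixture of the per-pixel tissue spectra over the punch
    disc, plus Gaussian noise of sd ``noise_sd`` (a.u.), on a 500-800 nm grid
    at 1 nm steps.
    """
    label_map.validate()
    config.validate()
    h, w = label_map.labels.shape
    rpx = punch_radius_px(site.punch_mm, config.pixel_size_mm)
    if not (0 <= site.row < h and 0 <= site.col < w):
        raise ParameterError("biopsy site lies outside the label map")
    rr, cc = _disc_indices((h, w), (site.row, site.col), rpx)
    wl = default_wavelength_grid(step_nm=1.0)
    gain = config.dose_gain

    pairs, inverse = _unique_class_fraction(label_map.labels[rr, cc],
                                            label_map.cancer_cell_fraction[rr, cc])
    counts = np.bincount(inverse, minlength=len(pairs))
    inten = np.zeros_like(wl)
    for (cls, frac), count in zip(pairs, counts):
        inten = inten + count * tissue_emission_spectrum(
            int(cls), float(frac), gain, wl).intensity
    inten /= counts.sum()
    if config.noise_sd > 0:
        rng = _rng(config, int(label_map.meta.get("specimen_index", 0)),
                   _STREAM_SPECTRUM, extra=(int(site.site_id),))
        inten = inten + rng.normal(0.0, config.noise_sd, size=inten.shape)
    return EmissionSpectrum(wl, np.clip(inten, 0.0, None)).validate()


def simulate_specimen(config: SimulationConfig, specimen_index: int):
    """Convenience wrapper: map, border, rendered image and biopsy records."""
    label_map, border = generate_label_map(config, specimen_index)
    image = render_fluorescence_image(label_map, config)
    records = sample_biopsies(label_map, border, config)
    return label_map, border, image, records
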