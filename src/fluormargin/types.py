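"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np


class ParameterError(ValueError):
    """Invalid configuration or operation parameter."""


class AnalysisError(RuntimeError):
    """An analysis precondition is not met (e.g. empty ROI)."""


class PlacementError(RuntimeError):
    """A biopsy punch could not be placed on the specimen."""


class LoadError(ValueError):
    """A data file failed validation on load."""


#: Integer class codes for the per-pixel tissue label grid.
TISSUE_CLASSES = {
    "background": 0,
    "scale_marker": 1,
    "tumor": 2,
    "occult_cancer": 3,
    "benign_proliferative": 4,
    "connective": 5,
    "adipose": 6,
}
CLASS_NAMES = {v: k for k, v in TISSUE_CLASSES.items()}
CANCER_CODES = (TISSUE_CLASSES["tumor"], TISSUE_CLASSES["occult_cancer"])
#: Classes that carry no PpIX and must have zero cancer-cell fraction.
ZERO_FRACTION_CODES = (
    TISSUE_CLASSES["background"],
    TISSUE_CLASSES["scale_marker"],
    TISSUE_CLASSES["connective"],
    TISSUE_CLASSES["adipose"],
)

DOSE_GROUPS = ("control", "low", "high")
STRATA = ("inside", "outside")


@dataclass
class TissueLabelMap:
    """Per-pixel tissue class grid; the simulation/composition ground truth.

    ``cancer_cell_fraction`` is the local PpIX-expressing cell fraction in
    [0, 1]; it is nonzero only for tumor, occult-cancer and (expressing)
    benign-proliferative pixels. ``meta`` carries generator bookkeeping
    (biopsy pocket centers, focus lists) used by the synthetic sampler; it is
    not part of the scientific contract.
    """

    labels: np.ndarray
    pixel_size_mm: float
    cancer_cell_fraction: np.ndarray
    meta: dict = field(default_factory=dict)

    def validate(self) -> "TissueLabelMap":
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ParameterError("label grid must be a non-empty 2-D array")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be positive")
        if self.cancer_cell_fraction.shape != self.labels.shape:
            raise ParameterError("cancer_cell_fraction shape must match labels")
        known = np.isin(self.labels, list(CLASS_NAMES))
        if not known.all():
            raise ParameterError("unknown tissue class code in label grid")
        frac = self.cancer_cell_fraction
        if np.any(frac < 0) or np.any(frac > 1):
            raise ParameterError("cancer_cell_fraction must lie in [0, 1]")
        zero_mask = np.isin(self.labels, ZERO_FRACTION_CODES)
        if np.any(frac[zero_mask] != 0):
            raise ParameterError("cancer_cell_fraction must be 0 for non-PpIX classes")
        return self


@dataclass
class TumorBorder:
    """Clinically demarcated primary tumor border polygon.

    Vertices are (row, col) in the image pixel frame, 0-based, closed
    implicitly (last vertex connects to the first). Specimens with ill-defined
    borders carry ``defined=False`` and an empty vertex list.
    """

    polygon: np.ndarray  # shape (n, 2) of (row, col); empty if undefined
    defined: bool

    def validate(self) -> "TumorBorder":
        poly = np.asarray(self.polygon, dtype=float)
        if self.defined:
            if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
                raise ParameterError("defined border needs >= 3 (row, col) vertices")
        elif poly.size != 0:
            raise ParameterError("undefined border must carry an empty vertex list")
        return self


@dataclass
class SpecimenImage:
    """8-bit RGB fluorescence raster with acquisition metadata."""

    rgb: np.ndarray  # (H, W, 3) uint8
    pixel_size_mm: float
    dose_group: str
    specimen_id: Optional[str] = None

    def validate(self) -> "SpecimenImage":
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ParameterError("specimen image must be (H, W, 3) RGB")
        if self.rgb.dtype != np.uint8:
            raise ParameterError("specimen image must be 8-bit")
        if self.dose_group not in DOSE_GROUPS:
            raise ParameterError(f"unknown dose group {self.dose_group!r}")
        return self


@dataclass
class BiopsyRecord:
    """One punch-biopsy site with its ground-truth histology label."""

    specimen_id: str
    site_id: int
    row: int
    col: int
    punch_mm: float
    stratum: str  # inside | outside
    histology: str  # pos | neg
    proliferative: int  # 0 | 1: benign proliferative change within the punch
    dose_group: str = "high"
    call: Optional[str] = None  # red | green | pink_brown, filled by classification
    red_positive: Optional[bool] = None

    def validate(self) -> "BiopsyRecord":
        if self.stratum not in STRATA:
            raise LoadError(f"unknown stratum {self.stratum!r} for site {self.site_id}")
        if self.histology not in ("pos", "neg"):
            raise LoadError(f"unknown histology {self.histology!r} for site {self.site_id}")
        if self.punch_mm not in (2.0, 4.0):
            raise LoadError(f"punch diameter must be 2 or 4 mm, got {self.punch_mm}")
        if self.dose_group not in DOSE_GROUPS:
            raise LoadError(f"unknown dose group {self.dose_group!r}")
        if self.proliferative not in (0, 1):
            raise LoadError("proliferative flag must be 0 or 1")
        return self


@dataclass
class EmissionSpectrum:
    """Point fluorescence emission spectrum (arbitrary units)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def validate(self) -> "EmissionSpectrum":
        wl = np.asarray(self.wavelength_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or wl.shape != inten.shape:
            raise ParameterError("wavelength/intensity must be matching 1-D grids of length >= 2")
        if np.any(np.diff(wl) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ParameterError("intensities must be non-negative")
        return self


@dataclass
class ChromaticityPair:
    """Tumor vs normal mean chromaticities and their Euclidean separation."""

    xy_tumor: tuple
    xy_normal: tuple
    distance: float

    def as_dict(self) -> dict:
        return {
            "xy_tumor": [float(v) for v in self.xy_tumor],
            "xy_normal": [float(v) for v in self.xy_normal],
            "distance": float(self.distance),
        }


def asdict_shallow(obj) -> dict:
    return asdict(obj)
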