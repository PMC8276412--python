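"""File formats, configuration and report writing.

Plain interoperable formats throughout: YAML config, CSV tables (UTF-8,
comma, header row), JSON reports and border polygons, lossless PNG images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import List, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .synthetic import SimulationConfig
from .types import (
    CLASS_NAMES,
    BiopsyRecord,
    EmissionSpectrum,
    LoadError,
    SpecimenImage,
    TissueLabelMap,
    TumorBorder,
)

REPORT_SCHEMA_VERSION = "1.0"

BIOPSY_COLUMNS = ["specimen_id", "site_id", "row", "col", "punch_mm",
                  "stratum", "histology", "proliferative"]


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from YAML (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise LoadError(f"unknown config keys: {sorted(unknown)}")
    if "shape" in raw:
        raw["shape"] = tuple(raw["shape"])
    return SimulationConfig(**raw).validate()


def save_config(config: SimulationConfig, path) -> None:
    data = {f.name: getattr(config, f.name) for f in fields(SimulationConfig)}
    data["shape"] = list(data["shape"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Images, label maps, borders, spectra


def write_image(image: SpecimenImage, path) -> None:
    iio.imwrite(Path(path), image.rgb)


def read_image(path, pixel_size_mm: float, dose_group: str,
               specimen_id: Optional[str] = None) -> SpecimenImage:
    rgb = np.asarray(iio.imread(Path(path)))
    if rgb.ndim == 3 and rgb.shape[2] == 4:  # drop alpha
        rgb = rgb[..., :3]
    return SpecimenImage(rgb.astype(np.uint8), pixel_size_mm, dose_group,
                         specimen_id=specimen_id).validate()


def write_label_map(label_map: TissueLabelMap, png_path, legend_path) -> None:
    """Single-channel PNG of class codes plus a JSON legend."""
    iio.imwrite(Path(png_path), label_map.labels.astype(np.uint8))
    legend = {
        "classes": {str(code): name for code, name in CLASS_NAMES.items()},
        "pixel_size_mm": label_map.pixel_size_mm,
    }
    Path(legend_path).write_text(json.dumps(legend, indent=2, sort_keys=True))


def write_border(border: TumorBorder, path) -> None:
    data = {"defined": border.defined,
            "polygon": [[float(r), float(c)] for r, c in np.asarray(border.polygon)]}
    Path(path).write_text(json.dumps(data, indent=2))


def read_border(path) -> TumorBorder:
    data = json.loads(Path(path).read_text())
    poly = np.asarray(data["polygon"], dtype=float).reshape(-1, 2)
    return TumorBorder(poly if data["defined"] else np.empty((0, 2)),
                       bool(data["defined"])).validate()


def write_spectrum(spectrum: EmissionSpectrum, path,
                   site_id: Optional[int] = None) -> None:
    df = pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm,
                       "intensity": spectrum.intensity})
    if site_id is not None:
        df["site_id"] = site_id
    df.to_csv(path, index=False)


def read_spectrum(path) -> EmissionSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise LoadError(f"spectrum file missing column {col!r}")
    return EmissionSpectrum(df["wavelength_nm"].to_numpy(float),
                            df["intensity"].to_numpy(float)).validate()


# ---------------------------------------------------------------------------
# Biopsy tables


def write_biopsy_table(records: List[BiopsyRecord], path) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in BIOPSY_COLUMNS}
        row["dose_group"] = r.dose_group
        if r.call is not None:
            row["call"] = r.call
            row["red_positive"] = int(bool(r.red_positive))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_biopsy_table(path) -> List[BiopsyRecord]:
    """Load and validate a biopsy table CSV.

    Strata and histology codes are case-insensitive; unknown codes, missing
    columns and duplicate (specimen_id, site_id) pairs raise a load error
    naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in BIOPSY_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"biopsy table missing columns: {missing}")
    records = []
    seen = set()
    for i, row in df.iterrows():
        key = (str(row["specimen_id"]), int(row["site_id"]))
        if key in seen:
            raise LoadError(f"row {i}: duplicate (specimen_id, site_id) {key}")
        seen.add(key)
        stratum = str(row["stratum"]).strip().lower()
        histology = str(row["histology"]).strip().lower()
        rec = BiopsyRecord(
            specimen_id=str(row["specimen_id"]), site_id=int(row["site_id"]),
            row=int(row["row"]), col=int(row["col"]),
            punch_mm=float(row["punch_mm"]), stratum=stratum,
            histology=histology, proliferative=int(row["proliferative"]),
            dose_group=str(row.get("dose_group", "high")).strip().lower(),
        )
        if "call" in df.columns and not pd.isna(row["call"]):
            rec.call = str(row["call"]).strip().lower()
            rec.red_positive = rec.call == "red"
        try:
            rec.validate()
        except LoadError as err:
            raise LoadError(f"row {i}: {err}") from err
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Study manifest and report


@dataclass
class StudyManifest:
    """Paths and settings binding one pipeline run together."""

    config: SimulationConfig
    seed: int
    out_dir: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None) -> "StudyManifest":
        config = load_config(path)
        return cls(config=config, seed=config.seed if seed is None else seed)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    return obj


def write_report(summaries, contrasts, peaks, compositions, path,
                 config: Optional[SimulationConfig] = None,
                 seed: Optional[int] = None, exclusions=None) -> dict:
    """Assemble the single JSON report document (idempotent for fixed input)."""
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "config": None,
        "diagnostics": [s.as_dict() for s in summaries],
        "contrast": contrasts,
        "peaks": peaks,
        "composition": compositions,
        "exclusions": exclusions or [],
    }
    if config is not None:
        cfg = {f.name: getattr(config, f.name) for f in fields(config)}
        cfg["shape"] = list(cfg["shape"])
        report["config"] = cfg
    report = _to_jsonable(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
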