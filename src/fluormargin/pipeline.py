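"""End-to-end synthetic study orchestration.

Simulate -> contrast -> classify -> diagnose -> compose -> report, with an
exclusion log carrying machine-readable reason codes (e.g. specimens whose
ill-defined borders keep them out of the chromaticity contrast analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .classify import annotate_records
from .colorimetry import group_contrast, specimen_contrast
from .composition import area_fractions
from .diagnostics import summarize_study
from .io import StudyManifest, write_report
from .spectra import smooth_and_detect
from .synthetic import SimulationConfig, generate_point_spectrum, simulate_specimen
from .types import BiopsyRecord

DOSE_ORDER = ("control", "low", "high")


@dataclass
class StudyResult:
    """In-memory results of one full synthetic study run."""

    records: List[BiopsyRecord]
    distances: Dict[str, List[float]]
    contrast: Optional[object]  # GroupContrastResult or None
    summaries: list
    peaks: List[dict]
    compositions: List[dict]
    exclusions: List[dict]


def run_group(config: SimulationConfig, collect_spectra: bool = True):
    """Simulate and analyze all specimens of one dose group."""
    records: List[BiopsyRecord] = []
    distances: List[float] = []
    peaks: List[dict] = []
    compositions: List[dict] = []
    exclusions: List[dict] = []
    for index in range(config.n_specimens):
        label_map, border, image, specimen_records = simulate_specimen(config, index)
        annotate_records(image, specimen_records)
        records.extend(specimen_records)
        if border.defined:
            pair = specimen_contrast(image, label_map, border)
            distances.append(pair.distance)
        else:
            exclusions.append({
                "reason_code": "ill_defined_border",
                "detail": "no demarcated tumor border; specimen excluded from contrast analysis",
                "specimen_id": image.specimen_id,
            })
        for rec in specimen_records:
            comp = area_fractions(label_map, rec)
            compositions.append({
                "specimen_id": rec.specimen_id, "site_id": rec.site_id,
                "stratum": rec.stratum, "histology": rec.histology,
                "call": rec.call, "dose_group": rec.dose_group,
                "pct_cancer": comp.pct_cancer,
                "pct_connective": comp.pct_connective,
                "pct_adipose": comp.pct_adipose,
                "ratio_cancer_connective": comp.ratio_cancer_connective,
            })
            if collect_spectra and rec.stratum == "inside":
                spectrum = generate_point_spectrum(rec, label_map, config)
                peak = smooth_and_detect(spectrum)
                peaks.append({
                    "specimen_id": rec.specimen_id, "site_id": rec.site_id,
                    "dose_group": rec.dose_group, "present": peak.present,
                    "peak_nm": peak.wavelength_nm, "prominence": peak.prominence,
                })
    return records, distances, peaks, compositions, exclusions


def run_study(config: SimulationConfig, doses=DOSE_ORDER,
              collect_spectra: bool = True) -> StudyResult:
    """Run the full multi-group synthetic study."""
    all_records: List[BiopsyRecord] = []
    distances: Dict[str, List[float]] = {}
    peaks: List[dict] = []
    compositions: List[dict] = []
    exclusions: List[dict] = []
    for dose in doses:
        cfg = config.with_dose(dose)
        records, dist, pk, comp, excl = run_group(cfg, collect_spectra)
        all_records.extend(records)
        distances[dose] = dist
        peaks.extend(pk)
        compositions.extend(comp)
        exclusions.extend(excl)
    contrast = None
    if len([d for d in distances.values() if len(d) >= 2]) >= 2:
        contrast = group_contrast({k: v for k, v in distances.items() if len(v) >= 2})
    summaries, log = summarize_study(all_records)
    exclusions.extend(log)
    return StudyResult(all_records, distances, contrast, summaries, peaks,
                       compositions, exclusions)


def run_pipeline(manifest: StudyManifest, report_path=None) -> dict:
    """Manifest-driven run producing the JSON report document."""
    config = manifest.config
    if manifest.seed is not None:
        from dataclasses import replace
        config = replace(config, seed=manifest.seed)
    result = run_study(config)
    contrast = result.contrast.as_dict() if result.contrast is not None else None
    if report_path is None:
        from pathlib import Path
        report_path = Path(manifest.out_dir or ".") / "report.json"
    report = write_report(
        result.summaries, contrast, result.peaks, result.compositions, report_path,
        config=config, seed=config.seed, exclusions=result.exclusions)
    return report
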