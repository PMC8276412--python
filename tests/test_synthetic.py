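"""Generator: label maps, spectra, rendering, biopsy sampling."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import binom

from fluormargin.spectra import detect_ppix_peak, smooth_and_detect
from fluormargin.synthetic import (
    SimulationConfig,
    default_wavelength_grid,
    generate_label_map,
    generate_point_spectrum,
    render_fluorescence_image,
    sample_biopsies,
    tissue_emission_spectrum,
)
from fluormargin.types import (
    CANCER_CODES,
    TISSUE_CLASSES,
    ParameterError,
    TissueLabelMap,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(dose_group="medium").validate()
        with pytest.raises(ParameterError):
            SimulationConfig(g_low=2.0, g_high=1.0).validate()
        with pytest.raises(ParameterError):
            SimulationConfig(masking_rate=1.5).validate()
        with pytest.raises(ParameterError):
            SimulationConfig(masking_ratio_threshold=0.0).validate()

    def test_dose_gain_mapping(self):
        assert SimulationConfig(dose_group="control").dose_gain == 0.0
        assert SimulationConfig(dose_group="low", g_low=0.7, g_high=1.0).dose_gain == 0.7


class TestEmissionSpectra:
    def test_control_tumor_peaks_in_autofluorescence_band(self):
        s = tissue_emission_spectrum("tumor", 1.0, 0.0)
        peak_wl = s.wavelength_nm[np.argmax(s.intensity)]
        assert 500 <= peak_wl <= 570

    def test_dosed_tumor_peaks_at_635(self):
        s = tissue_emission_spectrum("tumor", 1.0, 1.0)
        peak_wl = s.wavelength_nm[np.argmax(s.intensity)]
        assert peak_wl == pytest.approx(635, abs=2)

    def test_connective_peaks_at_520(self):
        for gain in (0.0, 1.0):
            s = tissue_emission_spectrum("connective", 0.0, gain)
            assert s.wavelength_nm[np.argmax(s.intensity)] == pytest.approx(520, abs=2)

    def test_unknown_class_rejected(self):
        with pytest.raises(ParameterError):
            tissue_emission_spectrum("stroma", 0.0, 1.0)
        with pytest.raises(ParameterError):
            tissue_emission_spectrum("tumor", 1.5, 1.0)


class TestLabelMap:
    def test_zero_occult_rate_yields_no_occult_pixels(self):
        cfg = SimulationConfig(occult_focus_rate=0.0, seed=3)
        for index in range(4):
            lm, _ = generate_label_map(cfg, index)
            assert not (lm.labels == TISSUE_CLASSES["occult_cancer"]).any()

    def test_determinism(self, default_config):
        lm1, b1 = generate_label_map(default_config, 2)
        lm2, b2 = generate_label_map(default_config, 2)
        assert np.array_equal(lm1.labels, lm2.labels)
        assert np.array_equal(lm1.cancer_cell_fraction, lm2.cancer_cell_fraction)
        assert b1.defined == b2.defined
        assert np.array_equal(b1.polygon, b2.polygon)

    def test_structure(self, specimen):
        lm, border, _, _ = specimen
        assert (lm.labels == TISSUE_CLASSES["tumor"]).any()
        assert (lm.labels == TISSUE_CLASSES["scale_marker"]).any()
        lm.validate()  # class/fraction invariants
        if border.defined:
            assert border.polygon.shape[0] >= 3

    def test_occult_focus_count_is_poisson_with_configured_rate(self):
        # Oracle: mean of Poisson(rate) over m specimens within 3 SE.
        # (Masked foci scatter into sparse pixel sets, so the focus count is
        # taken from the generator's bookkeeping, sanity-checked per map.)
        cfg = SimulationConfig(seed=7)
        m = 100
        counts = []
        for index in range(m):
            lm, _ = generate_label_map(cfg, index)
            n = lm.meta["n_occult_foci"]
            occult = lm.labels == TISSUE_CLASSES["occult_cancer"]
            assert (n == 0) == (not occult.any())
            counts.append(n)
        mean = np.mean(counts)
        se = np.sqrt(cfg.occult_focus_rate / m)
        assert abs(mean - cfg.occult_focus_rate) <= 3 * se

    def test_invalid_arguments(self, default_config):
        with pytest.raises(ParameterError):
            generate_label_map(default_config, -1)


class TestRendering:
    def test_noiseless_render_is_deterministic(self, default_config):
        from dataclasses import replace
        cfg = replace(default_config, noise_sd=0.0)
        lm, _ = generate_label_map(cfg, 1)
        img1 = render_fluorescence_image(lm, cfg)
        img2 = render_fluorescence_image(lm, cfg)
        assert np.array_equal(img1.rgb, img2.rgb)

    def test_noisy_render_is_seed_deterministic(self, default_config):
        lm, _ = generate_label_map(default_config, 1)
        img1 = render_fluorescence_image(lm, default_config)
        img2 = render_fluorescence_image(lm, default_config)
        assert np.array_equal(img1.rgb, img2.rgb)

    def test_red_green_ratio_increases_with_dose(self, default_config):
        # Same label map rendered with and without PpIX gain.
        lm, _ = generate_label_map(default_config, 0)
        tumor = np.isin(lm.labels, CANCER_CODES) & (lm.cancer_cell_fraction > 0.5)
        img_hi = render_fluorescence_image(lm, default_config)
        img_0 = render_fluorescence_image(lm, default_config.with_dose("control"))
        def ratio(img):
            rgb = img.rgb.astype(float)
            return rgb[..., 0][tumor].mean() / max(rgb[..., 1][tumor].mean(), 1e-9)
        assert ratio(img_hi) > ratio(img_0)

    def test_tumor_pixels_redder_than_connective(self, specimen):
        # Class-conditional chromaticity separation under PpIX gain.
        from fluormargin.classify import classify_color
        from fluormargin.colorimetry import decode_srgb_to_xyz
        lm, _, img, _ = specimen
        xyz = decode_srgb_to_xyz(img).xyz
        def median_xy(mask):
            v = xyz[mask]
            s = v.sum(1)
            return np.median(v[:, 0] / s), np.median(v[:, 1] / s)
        tumor = (lm.labels == TISSUE_CLASSES["tumor"]) & (lm.cancer_cell_fraction > 0.5)
        conn = lm.labels == TISSUE_CLASSES["connective"]
        assert classify_color(median_xy(tumor)).category == "red"
        assert classify_color(median_xy(conn)).category == "green"


class TestBiopsySampling:
    def test_site_count_and_inside_site(self, default_config):
        for index in range(6):
            lm, border = generate_label_map(default_config, index)
            records = sample_biopsies(lm, border, default_config)
            assert 1 <= len(records) <= 4
            assert sum(r.stratum == "inside" for r in records) == 1

    def test_sites_do_not_overlap(self, default_config):
        from fluormargin.synthetic import punch_radius_px
        for index in range(6):
            lm, border = generate_label_map(default_config, index)
            records = sample_biopsies(lm, border, default_config)
            for i, a in enumerate(records):
                for b in records[i + 1:]:
                    ra = punch_radius_px(a.punch_mm, lm.pixel_size_mm)
                    rb = punch_radius_px(b.punch_mm, lm.pixel_size_mm)
                    d = np.hypot(a.row - b.row, a.col - b.col)
                    assert d >= ra + rb

    def test_all_adipose_disc_is_histology_negative(self):
        cfg = SimulationConfig(seed=0)
        labels = np.full(cfg.shape, TISSUE_CLASSES["adipose"], dtype=np.int8)
        lm = TissueLabelMap(labels, cfg.pixel_size_mm, np.zeros(cfg.shape),
                            meta={"specimen_index": 0, "inside_spot": (60, 60),
                                  "planned_foci": [], "benign_foci": []})
        from fluormargin.types import TumorBorder
        records = sample_biopsies(lm, TumorBorder(np.empty((0, 2)), False), cfg)
        assert all(r.histology == "neg" for r in records)

    def test_outside_site_prevalence_matches_configuration(self):
        # Prevalence control: over many specimens the fraction of
        # outside-border sites that are cancer-positive stays within the
        # binomial 95% band of the configured prevalence.
        cfg = SimulationConfig(seed=13)
        pos = total = 0
        for index in range(200):
            lm, border = generate_label_map(cfg, index)
            for rec in sample_biopsies(lm, border, cfg):
                if rec.stratum == "outside":
                    total += 1
                    pos += rec.histology == "pos"
        p = cfg.occult_site_prevalence
        lo = binom.ppf(0.025, total, p)
        hi = binom.ppf(0.975, total, p)
        assert lo <= pos <= hi, (pos, total)


class TestPointSpectra:
    def test_noiseless_spectrum_equals_mixture(self, default_config):
        from dataclasses import replace
        from fluormargin.synthetic import _disc_indices, punch_radius_px
        cfg = replace(default_config, noise_sd=0.0)
        lm, border = generate_label_map(cfg, 0)
        rec = sample_biopsies(lm, border, cfg)[0]
        got = generate_point_spectrum(rec, lm, cfg)
        rpx = punch_radius_px(rec.punch_mm, lm.pixel_size_mm)
        rr, cc = _disc_indices(lm.labels.shape, (rec.row, rec.col), rpx)
        expected = np.zeros_like(got.intensity)
        for r, c in zip(rr, cc):
            s = tissue_emission_spectrum(int(lm.labels[r, c]),
                                         float(lm.cancer_cell_fraction[r, c]),
                                         cfg.dose_gain, got.wavelength_nm)
            expected += s.intensity
        expected /= len(rr)
        assert np.allclose(got.intensity, expected, atol=1e-9)

    def test_cancer_site_peak_detected_end_to_end(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, masking_rate=0.0)
            lm, border = generate_label_map(cfg, 0)
            rec = sample_biopsies(lm, border, cfg)[0]
            assert rec.histology == "pos"
            peak = smooth_and_detect(generate_point_spectrum(rec, lm, cfg))
            if peak.present and 625 <= peak.wavelength_nm <= 645:
                hits += 1
        assert hits == 10

    def test_control_site_has_no_ppix_peak(self):
        cfg = SimulationConfig(dose_group="control", seed=4, noise_sd=0.0)
        lm, border = generate_label_map(cfg, 0)
        rec = sample_biopsies(lm, border, cfg)[0]
        peak = detect_ppix_peak(generate_point_spectrum(rec, lm, cfg))
        assert not peak.present
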