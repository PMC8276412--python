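# Methods

## Overview

The package implements the quantitative pipeline of a fluorescence-guided
breast surgery imaging study: synthetic specimen simulation, CIE chromaticity
contrast scoring, fluorescence color classification, diagnostic accuracy
statistics, point-spectroscopy peak detection, and tissue-composition
analysis. The clinical images and biopsies of such a study are not publicly
deposited, so the simulation module is a first-class component: it generates
specimens with the statistical structure the downstream analyses assume, and
every pipeline stage is exercised end-to-end against known ground truth.

## Spectral and color model

Each tissue class emits a parametric spectrum on a 500–800 nm grid
(arbitrary units, scale 100):

| component | shape | default |
|---|---|---|
| PpIX | Gaussians at 635 nm (major) and 705 nm (minor, ratio 0.2), σ = 12 nm | amplitude 3.0 × dose_gain × cancer_cell_fraction |
| connective AF | Gaussian at 520 nm, σ = 30 nm | weight 1.0 (connective), 0.10 (cancer), 0.05 (adipose) |
| adipose AF | broad Gaussian at 600 nm, σ = 90 nm | weight 0.40 (adipose), 0.04 (cancer), 0.05 (connective) |

The study reports peak positions (635 nm PpIX; green connective AF;
broad dull adipose AF), not line shapes; the Gaussian widths and weights are
package choices. The PpIX amplitude is large relative to the AF weights
because PpIX is spectrally narrow while the AF components are broad: the
weight ratio is calibrated so that a cancer pixel's *tristimulus integral*
is red-dominated (dominant wavelength > 605 nm), matching the bright-red
visual appearance described for dosed tumors. The cancer-class AF mix is
chosen so that with zero dose gain (control), tumor tissue is
chromatically close to the normal connective/adipose background (mean
tumor-to-normal distance ≈ 0.03, the magnitude the study reports for
controls).

Rendering integrates each pixel's spectrum against the CIE 1931 2° observer
and encodes through linear sRGB (D65) with the IEC 61966-2-1 transfer, with
exposure normalized so the 99th-percentile linear value maps to code 245,
plus additive Gaussian sensor noise (sd 2.0 digital numbers) before 8-bit
quantization. The CMFs use the standard piecewise-Gaussian analytic fit;
its spectral locus is used for dominant-wavelength/purity computation
(truncated at 645 nm where the fit folds back; 8-bit sRGB chromaticities
have dominant wavelengths below that or fall on the purple line). Note that
narrow emission spectra confined to 500–800 nm lie outside the sRGB gamut
(they carry almost no blue tristimulus); the renderer clips negative linear
RGB at zero, exactly as a real sRGB camera clips saturated colors. The
render→decode chromaticity round trip is therefore exact (to quantization)
only for in-gamut spectra, and the green/red colors in rendered images are
the gamut-clipped projections of the model spectra.

## Synthetic specimens

Grid 144×192 at 0.5 mm/pixel (a 72×96 mm gross slice). A tissue ellipse is
partitioned into connective vs adipose by a smoothed Gaussian field (~56%
connective); a white scale sticker sits in a background corner. The primary
tumor is a union of overlapping discs (lobulated, radius ~7–9 mm) with ~20%
interspersed connective mottling (carcinoma-associated fibrosis). The
demarcated border is the contour of the dilated tumor mask; with probability
0.2 the border is "ill-defined" (undefined polygon) and the specimen is
excluded from contrast analysis, mirroring the study's 8/45 exclusions.

Biopsy sites (1 inside the border + 1–3 outside, punch 2 or 4 mm,
non-overlapping) are sampled jointly with the map through a shared
per-specimen plan stream, so that:

- each outside site is cancer-targeted with probability 0.2 (the
  outside-border prevalence the trial observed, ~6/31 and 7/27); occult
  focus count stays Poisson(2.0) apart from a small max(·, needed)
  correction;
- every biopsy "pocket" is constructed with an exact count of cancer-class
  pixels interleaved among connective pixels inside the punch disc. Unmasked
  pockets draw a cancer-pixel share in 0.62–0.82; **masked** pockets (drawn
  with probability 0.35, the study's false-negative fraction among cancer
  sites) draw 0.06–0.15, putting the carcinoma-to-connective area ratio
  below the 0.20 masking threshold, and their PpIX-expressing cell fraction
  is attenuated to 0.30. Exact counts make the median-chromaticity site call
  deterministic given the pocket type, which is what lets classifier
  parameter recovery be checked against exact binomial bounds.
- benign-proliferative foci (Poisson 0.6/specimen) express PpIX with
  probability 0.5; expressing foci appear red and attract outside biopsies
  (the trial targeted red areas), producing false positives at roughly the
  trial's rate (9 FPs over 30 dosed specimens, 5 with proliferative change).

Dose gains are g_control = 0 and g_low = g_high = 1: the study found no
significant accuracy or contrast difference between 15 and 30 mg/kg, so
equal gains are the calibrated default, not a claim about pharmacokinetics.
All randomness derives from a single seed fanned out per (specimen index,
stream, dose group), so every output is bit-reproducible.

## Analysis stages

**Chromaticity contrast.** Images are decoded 8-bit sRGB → linear → XYZ
(white Y = 1). ROI chromaticity is mean-XYZ-then-project
(luminance-weighted), not the mean of per-pixel chromaticities — the order
matters and is fixed. Excluded everywhere: background, the scale sticker,
and a dilated zone around occult cancer outside the border. The tumor ROI is
the rasterized border polygon (even-odd fill, boundary pixels inside).
Contrast = Euclidean distance between tumor and normal (x, y); groups are
compared with one-way ANOVA + Tukey HSD. Degenerate variance structures
(all-equal values; zero within-group variance) are resolved to their limits
(F = 0, p = 1; F = ∞, p = 0) rather than NaN. A configurable
just-noticeable-difference scalar (default 0.004) expresses distances in
perceptual steps for reporting only.

**Color classification.** A site's chromaticity is the per-coordinate median
over the punch disc (robust to speckle). The call is banded by dominant
wavelength relative to D65: red ≥ 600 nm, green in [490, 570) nm, each
requiring excitation purity ≥ 0.25 ("dull" colors and the purple region fall
through to pink/brown). The study's calls were visual; the bands and purity
floor are explicit, tunable stand-ins. +RedFL ≡ category red.

**Diagnostic accuracy.** TP = red ∧ cancer-positive, etc.; strata
inside/outside/overall per dose group. Clopper-Pearson intervals come from
Beta quantiles (closed forms (α/2)^(1/n) at x = n and 1 − (α/2)^(1/n) at
x = 0 hold to 1e-10). DOR uses z = Φ⁻¹(0.975) = 1.959964; any zero cell
yields "not applicable" (as the published tables print N/A), with an
optional Haldane 0.5 correction behind an explicit flag. Reporting rules:
NPV is suppressed inside the border (healthy-tissue prevalence there is near
zero); the control group is excluded from accuracy reporting. Percentages
print at one decimal with round-half-away-from-zero. In-situ-only disease
counts as cancer-positive.

**Spectroscopy.** Savitzky-Golay smoothing (window 15 samples, order 3;
moving average available) with negatives clamped; the PpIX peak is the most
prominent local maximum in 625–645 nm with prominence ≥ 3 a.u. The study
says only "smoothed" and gives no peak criterion; these are package
defaults. Absolute PpIX quantification is out of scope.

**Composition.** Area fractions are computed over tissue pixels only
(background/scale excluded); the carcinoma-to-connective ratio is undefined
(flagged, not zero) when the disc has no connective pixels. Red vs non-red
groups are compared with Mann-Whitney U — exact for combined n ≤ 20 without
ties, otherwise the tie-corrected normal approximation without continuity
correction (so identical samples give p = 1).

## Published-count reproduction and two inconsistencies

The trial's printed 2×2 counts (`fluormargin.studydata`) are inputs from
which all published accuracy measures are recomputed. Two printed cells are
inconsistent with their own counts:

1. **Pooled low-dose DOR**: printed 13.6 (3.0–62.0), but the printed counts
   (TP=13, FP=4, FN=7, TN=22) give 10.2 (2.5–41.7). The printed value
   corresponds exactly to FP=3 (13·22/(3·7) = 13.62, CI 2.99–62.04), so that
   cell was evidently computed from a table with FP=3 while the same
   column's PPV (76.5% = 13/17) used FP=4. The count-derived value is
   pinned.
2. **High-dose inside PPV CI**: printed lower bound 73.5%, but TP=10, FP=0
   gives (0.025)^(1/10) = 69.2%. The printed 73.5% equals (0.025)^(1/12),
   i.e. n=12. The count-derived bound is pinned.

The per-dose split (3/2) of the five proliferative false positives is not
printed; it is inferred from the published 89%/70% abnormal-tissue PPVs.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analyses rely on:
prevalence stratification, masking-driven false negatives tied to low
carcinoma-to-connective ratios, benign-proliferative false positives,
dose-independent contrast, ill-defined-border exclusions, and spectra whose
635 nm peak appears only under dose. Passing tests therefore demonstrate the
*methods* are correct and well-calibrated, not that the package reproduces
clinical effect sizes: synthetic chromatic distances (≈0.17 for dosed groups
vs ≈0.03 control) are larger than the published 0.09–0.10 because rendered
tumors are cleaner and ROIs noise-free; the synthetic ratio medians (≈2.5
red vs ≈0.11 non-red) are more separated than the published 0.49 vs 0.20.
Orderings and significance patterns, not magnitudes, are the assertable
properties. Not modeled: physically accurate light transport, depth-resolved
fluorescence (sub-surface lesions), camera-specific spectral response, JPEG
compression (images are written lossless; a JPEG-ingest path exists), and
the histology-slide tissue classifier (label masks are consumed as ground
truth).

## Problem sizes and numerics

Default suite and acceptance sizes: 15 specimens/group for contrast
(10 seeds in the property check), ≥500 biopsies for classifier recovery,
≥100 biopsies per arm over 20 seeds for the composition direction check,
2000 draws for interval coverage. These sizes give the statistical power the
checks need while keeping a full run to a few minutes on one core.
Tie-breaks and degenerate inputs are handled explicitly: chromaticities with
zero tristimulus sum are excluded from site medians (all-zero discs raise),
band edges resolve to the longer-wavelength band, zero contingency cells
suppress the DOR rather than being corrected, and empty ROIs or
zero-denominator proportions raise or flag rather than returning NaN.
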