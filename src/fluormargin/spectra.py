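"""Point-spectroscopy smoothing and PpIX 635 nm peak detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .types import EmissionSpectrum, ParameterError

DEFAULT_WINDOW = 15
DEFAULT_ORDER = 3
PPIX_SEARCH_WINDOW_NM = (625.0, 645.0)
DEFAULT_MIN_PROMINENCE = 3.0  # a.u. on the generator's 0-100 intensity scale


@dataclass
class PeakResult:
    """Outcome of searching for the PpIX emission peak."""

    present: bool
    wavelength_nm: Optional[float]
    prominence: float

    def validate(self) -> "PeakResult":
        if self.present != (self.wavelength_nm is not None):
            raise ParameterError("wavelength must be defined iff a peak is present")
        if self.prominence < 0:
            raise ParameterError("prominence must be non-negative")
        return self


def smooth_spectrum(s: EmissionSpectrum, window: int = DEFAULT_WINDOW,
                    order: int = DEFAULT_ORDER, method: str = "savgol") -> EmissionSpectrum:
    """Smooth a spectrum (Savitzky-Golay by default, moving average optional).

    Negative filter outputs are clamped to zero; the wavelength grid is
    unchanged.
    """
    s.validate()
    n = len(s.intensity)
    if window % 2 == 0 or window <= order or window > n:
        raise ParameterError("window must be odd, greater than order, and <= spectrum length")
    if method == "savgol":
        out = savgol_filter(s.intensity, window, order)
    elif method == "moving_average":
        out = np.convolve(s.intensity, np.ones(window) / window, mode="same")
    else:
        raise ParameterError(f"unknown smoothing method {method!r}")
    return EmissionSpectrum(s.wavelength_nm, np.clip(out, 0.0, None)).validate()


def detect_ppix_peak(s: EmissionSpectrum,
                     window_nm: Tuple[float, float] = PPIX_SEARCH_WINDOW_NM,
                     min_prominence: float = DEFAULT_MIN_PROMINENCE) -> PeakResult:
    """Find the most prominent local maximum inside the PpIX search window.

    A peak must be a local maximum of the full spectrum whose position falls
    inside ``window_nm`` and whose prominence is at least ``min_prominence``.
    """
    s.validate()
    wl = np.asarray(s.wavelength_nm, dtype=float)
    lo, hi = window_nm
    if lo >= hi or lo < wl[0] or hi > wl[-1]:
        raise ParameterError("search window must be ordered and inside the spectrum support")
    idx, props = find_peaks(s.intensity, prominence=min_prominence)
    in_window = idx[(wl[idx] >= lo) & (wl[idx] <= hi)]
    if in_window.size == 0:
        return PeakResult(False, None, 0.0).validate()
    proms = props["prominences"][np.isin(idx, in_window)]
    best = int(np.argmax(proms))
    return PeakResult(True, float(wl[in_window[best]]), float(proms[best])).validate()


def smooth_and_detect(s: EmissionSpectrum, window: int = DEFAULT_WINDOW,
                      order: int = DEFAULT_ORDER,
                      window_nm: Tuple[float, float] = PPIX_SEARCH_WINDOW_NM,
                      min_prominence: float = DEFAULT_MIN_PROMINENCE) -> PeakResult:
    """The standard pipeline: Savitzky-Golay smoothing, then peak detection."""
    return detect_ppix_peak(smooth_spectrum(s, window, order), window_nm, min_prominence)
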