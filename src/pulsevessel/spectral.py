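"""Spectral verification of a segmentation.

A correct vessel segmentation concentrates cardiac-locked signal: the
amplitude spectrum of the segmentation's mean time series shows a larger
cardiac-band line than the over-inclusive general ROI it was refined
from.  When the heart rate exceeds the temporal Nyquist frequency the
cardiac line aliases; the folded frequency is used and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardiac import PeakSeries
from .errors import EmptyRegionError, PulseVesselError
from .io import Bold4D, Mask3D

__all__ = [
    "SpectrumReport",
    "nyquist_freq",
    "cardiac_freq",
    "alias_frequency",
    "roi_spectrum",
]

# half-width of the window searched for the cardiac line, Hz
CARDIAC_SEARCH_HALFWIDTH = 0.1


@dataclass
class SpectrumReport:
    """One-sided amplitude spectrum of an ROI-mean series."""

    freqs: np.ndarray
    amplitude: np.ndarray
    cardiac_freq: float
    cardiac_freq_folded: float
    aliased: bool
    cardiac_amplitude: float
    nyquist: float
    mean_series: np.ndarray


def nyquist_freq(tr: float) -> float:
    """Temporal Nyquist frequency 1/(2·TR) in Hz."""
    if not tr > 0:
        raise PulseVesselError("tr must be positive")
    return 1.0 / (2.0 * tr)


def cardiac_freq(mean_hr: float) -> float:
    """Cardiac frequency in Hz from a heart rate in beats per minute."""
    if not mean_hr > 0:
        raise PulseVesselError("heart rate must be positive")
    return mean_hr / 60.0


def alias_frequency(f: float, nyq: float) -> float:
    """Fold a frequency into [0, nyquist] by reflection at the sampling grid."""
    fs = 2.0 * nyq
    f = abs(f) % fs
    return fs - f if f > nyq else f


def roi_spectrum(bold: Bold4D, mask: Mask3D, peaks: PeakSeries) -> SpectrumReport:
    """Amplitude spectrum of the mean time series over an ROI.

    The ROI-mean series is demeaned and transformed with a one-sided
    amplitude normalization (a unit-amplitude sinusoid on the frequency
    grid yields amplitude 1).  The cardiac amplitude is the maximum
    amplitude within ±0.1 Hz of the (possibly aliased) cardiac frequency.
    """
    mask.check_grid(bold)
    if mask.n_voxels == 0:
        raise EmptyRegionError("cannot compute a spectrum of an empty ROI")
    series = bold.data[mask.data].mean(axis=0)
    series = series - series.mean()
    n = series.size
    coeffs = np.fft.rfft(series)
    freqs = np.fft.rfftfreq(n, d=bold.tr)
    amplitude = np.abs(coeffs) * 2.0 / n
    amplitude[0] /= 2.0
    if n % 2 == 0:
        amplitude[-1] /= 2.0

    nyq = nyquist_freq(bold.tr)
    f_c = cardiac_freq(peaks.mean_hr)
    f_fold = alias_frequency(f_c, nyq)
    aliased = f_c > nyq
    window = np.abs(freqs - f_fold) <= CARDIAC_SEARCH_HALFWIDTH
    if not window.any():
        window = np.zeros_like(freqs, dtype=bool)
        window[np.argmin(np.abs(freqs - f_fold))] = True
    return SpectrumReport(
        freqs=freqs,
        amplitude=amplitude,
        cardiac_freq=f_c,
        cardiac_freq_folded=f_fold,
        aliased=aliased,
        cardiac_amplitude=float(amplitude[window].max()),
        nyquist=nyq,
        mean_series=series,
    )
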