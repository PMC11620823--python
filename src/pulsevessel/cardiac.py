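"""Retrospective cardiac alignment.

The plethysmogram provides the cardiac reference: systolic peaks are
detected, every fMRI timepoint is mapped to a cardiac phase — its position
within the surrounding RR interval, expressed as a fraction in [0, 1) —
and per-voxel signals are averaged within equal phase bins to form the
cardiac waveform that the segmentation correlates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import PulseVesselError
from .io import PhysioTrace

__all__ = [
    "PeakSeries",
    "PhaseAssignment",
    "CardiacWaveform",
    "detect_peaks",
    "assign_phase",
    "bin_waveform",
    "phase_bin_indices",
    "fill_empty_bins",
    "DEFAULT_N_BINS",
    "MAX_INTERPOLATED_FRACTION",
]

DEFAULT_N_BINS = 20
# waveforms with more than this fraction of interpolated (originally empty)
# bins are rejected as templates
MAX_INTERPOLATED_FRACTION = 0.25

# physiologically plausible RR interval range, seconds (30-200 bpm)
_RR_MIN = 0.3
_RR_MAX = 2.0


@dataclass
class PeakSeries:
    """Systolic peak times (s) and the mean heart rate they imply."""

    peak_times: np.ndarray
    mean_hr: float

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size < 3:
            raise PulseVesselError("insufficient peaks: need at least 3")
        if np.any(np.diff(self.peak_times) <= 0):
            raise PulseVesselError("peak times must be strictly increasing")


@dataclass
class PhaseAssignment:
    """Cardiac phase per timepoint.

    ``phases`` holds one value in [0, 1) per timepoint (any array shape);
    ``valid`` is False for timepoints outside the first/last peak or
    inside an implausibly long or short RR interval — those samples are
    excluded from every downstream statistic.
    """

    phases: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phases.shape != self.valid.shape:
            raise PulseVesselError("phases and valid must share a shape")


@dataclass
class CardiacWaveform:
    """Phase-binned mean signal over one cardiac cycle.

    The ``n_bins`` bins partition [0, 1) into equal half-open intervals.
    Bins with no samples are filled by circular linear interpolation and
    recorded in ``interpolated``.
    """

    n_bins: int
    bin_means: np.ndarray
    bin_counts: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if self.bin_means.shape != (self.n_bins,) or self.bin_counts.shape != (self.n_bins,):
            raise PulseVesselError("bin arrays must have length n_bins")
        if self.interpolated is None:
            self.interpolated = self.bin_counts == 0
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    @property
    def interpolated_fraction(self) -> float:
        return float(self.interpolated.mean())

    def usable_as_template(self) -> bool:
        return self.interpolated_fraction <= MAX_INTERPOLATED_FRACTION


def detect_peaks(
    trace: PhysioTrace,
    min_separation_s: float = _RR_MIN,
    prominence_factor: float = 0.5,
) -> PeakSeries:
    """Locate systolic peaks in a plethysmogram.

    The trace is band-passed to 0.5-3 Hz (zero phase), candidate local
    maxima at least ``min_separation_s`` apart are collected, and peaks
    whose prominence falls below ``prominence_factor`` times the median
    pulse amplitude are discarded.  Gaps longer than the plausible RR
    range are re-searched among the discarded candidates so a run of weak
    pulses does not produce a spurious multi-second beat.
    """
    fs = trace.fs
    nyq = fs / 2.0
    high = min(3.0, 0.9 * nyq)
    sos = sps.butter(2, [0.5, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, trace.samples - trace.samples.mean())
    min_dist = max(1, int(round(min_separation_s * fs)))
    candidates, props = sps.find_peaks(x, distance=min_dist, prominence=0.0)
    if candidates.size < 3:
        raise PulseVesselError("insufficient peaks: flat or aperiodic trace")
    prominences = props["prominences"]
    # candidates include sub-pulse features (dicrotic bumps), so the pulse
    # amplitude is estimated as the median of the upper half of candidate
    # prominences — the 75th percentile overall
    median_amp = float(np.percentile(prominences, 75))
    keep = prominences >= prominence_factor * median_amp
    peaks = candidates[keep]
    if peaks.size < 3:
        raise PulseVesselError("insufficient peaks after prominence filtering")
    # recover candidates inside implausibly long gaps
    peaks = list(peaks)
    changed = True
    while changed:
        changed = False
        gaps = np.diff(peaks) / fs
        for i in np.nonzero(gaps > _RR_MAX)[0]:
            lo, hi = peaks[i], peaks[i + 1]
            inside = [
                (p, pr)
                for p, pr in zip(candidates, prominences)
                if lo + min_dist <= p <= hi - min_dist
            ]
            if inside:
                best = max(inside, key=lambda t: t[1])[0]
                peaks.append(best)
                peaks.sort()
                changed = True
                break
    peaks = np.asarray(peaks)
    peak_times = trace.t0 + peaks / fs
    rr = np.diff(peak_times)
    plausible = (rr >= _RR_MIN) & (rr <= _RR_MAX)
    if plausible.sum() < 2:
        raise PulseVesselError("insufficient plausible RR intervals")
    mean_hr = 60.0 / float(np.mean(rr[plausible]))
    return PeakSeries(peak_times=peak_times, mean_hr=mean_hr)


def assign_phase(acq_times: np.ndarray, peaks: PeakSeries) -> PhaseAssignment:
    """Map acquisition times to cardiac phases.

    For a time t between consecutive peaks p_k and p_{k+1} the phase is
    the linear RR-interval fraction (t - p_k) / (p_{k+1} - p_k), so the
    alignment tracks the cardiac cycle through heart-rate changes.
    Timepoints before the first or after the last peak, or inside an RR
    interval outside [0.3, 2.0] s, are marked invalid.
    """
    t = np.asarray(acq_times, dtype=float)
    p = peaks.peak_times
    idx = np.searchsorted(p, t, side="right") - 1
    inside = (idx >= 0) & (idx < p.size - 1)
    idx_c = np.clip(idx, 0, p.size - 2)
    rr = p[idx_c + 1] - p[idx_c]
    phases = np.where(inside, (t - p[idx_c]) / rr, 0.0)
    valid = inside & (rr >= _RR_MIN) & (rr <= _RR_MAX)
    phases = np.mod(phases, 1.0)
    return PhaseAssignment(phases=phases, valid=valid)


def phase_bin_indices(phases: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index in [0, n_bins) for each phase; bins are [j/n, (j+1)/n)."""
    return np.minimum((np.asarray(phases) * n_bins).astype(np.intp), n_bins - 1)


def fill_empty_bins(bin_means: np.ndarray, empty: np.ndarray) -> np.ndarray:
    """Fill empty bins by circular linear interpolation between neighbours.

    Operates on the last axis; ``empty`` is a boolean mask of the same
    shape.  All-empty rows raise.
    """
    means = np.array(bin_means, dtype=float)
    empty = np.asarray(empty, dtype=bool)
    if means.ndim == 1:
        return _fill_1d(means, empty)
    flat = means.reshape(-1, means.shape[-1])
    eflat = empty.reshape(-1, empty.shape[-1])
    rows = np.nonzero(eflat.any(axis=1))[0]
    for r in rows:
        flat[r] = _fill_1d(flat[r], eflat[r])
    return flat.reshape(means.shape)


def _fill_1d(means: np.ndarray, empty: np.ndarray) -> np.ndarray:
    n = means.size
    if empty.all():
        raise PulseVesselError("all phase bins are empty")
    if not empty.any():
        return means
    good = np.nonzero(~empty)[0]
    # circular interpolation: unwrap bin index onto an extended axis
    xp = np.concatenate([good, good + n])
    fp = np.concatenate([means[good], means[good]])
    bad = np.nonzero(empty)[0]
    query = np.where(bad < good[0], bad + n, bad)
    means = means.copy()
    means[bad] = np.interp(query, xp, fp)
    return means


def bin_waveform(
    signal: np.ndarray,
    phases: PhaseAssignment,
    n_bins: int = DEFAULT_N_BINS,
) -> CardiacWaveform:
    """Phase-bin a per-timepoint signal into a cardiac waveform.

    Only valid timepoints contribute.  bin_means[j] is the mean of the
    signal over timepoints with phase in [j/n, (j+1)/n); empty bins are
    filled by circular linear interpolation and flagged.
    """
    sig = np.asarray(signal, dtype=float).ravel()
    ph = phases.phases.ravel()
    valid = phases.valid.ravel()
    if sig.shape != ph.shape:
        raise PulseVesselError("signal and phases must align")
    sig, ph = sig[valid], ph[valid]
    if sig.size == 0:
        raise PulseVesselError("no valid samples to bin")
    idx = phase_bin_indices(ph, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sig, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    empty = counts == 0
    means = fill_empty_bins(np.where(empty, 0.0, means), empty)
    return CardiacWaveform(
        n_bins=n_bins, bin_means=means, bin_counts=counts, interpolated=empty
    )
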