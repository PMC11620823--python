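"""Synthetic pulsatile phantom.

Generates a complete, fully specified test bed for the pipeline: a 4D
BOLD-like series in which tube-shaped "vessel" voxels carry a cardiac
waveform phase-locked to a synthetic finger-plethysmography trace with a
drifting, jittering heart rate, embedded in white noise and slow drift; a
brain mask; ground-truth vessel masks; and deliberately over-inclusive
general ROIs built by dilating the truth.  The geometry is schematic, not
anatomical: an arterial ring near the grid centre (a stand-in for the
Circle of Willis) and a single sagittal tube along the top of the brain
for the superior sagittal sinus.

Everything is deterministic given the seed: the same configuration
produces a bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cardiac import CardiacWaveform
from .errors import PulseVesselError
from .io import Bold4D, Mask3D, PhysioTrace

__all__ = [
    "TubeSegment",
    "PhantomConfig",
    "PhantomBundle",
    "generate_phantom",
    "generator_waveform_shape",
    "dilate_mask",
    "binarize_probability",
    "default_config",
]


@dataclass(frozen=True)
class TubeSegment:
    """A straight cylindrical vessel segment in voxel coordinates."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    target: str  # "artery" | "sss"


def _default_geometry() -> tuple[TubeSegment, ...]:
    # arterial ring (schematic Circle of Willis) in the z=14 plane and a
    # sagittal sinus tube along the top of the brain
    ring = [
        ((10, 10, 14), (22, 10, 14)),
        ((22, 10, 14), (22, 22, 14)),
        ((22, 22, 14), (10, 22, 14)),
        ((10, 22, 14), (10, 10, 14)),
    ]
    tubes = [TubeSegment(a, b, 1.0, "artery") for a, b in ring]
    tubes.append(TubeSegment((16, 8, 27), (16, 24, 27), 1.0, "sss"))
    return tuple(tubes)


@dataclass
class PhantomConfig:
    """Phantom acquisition and signal parameters.

    Defaults describe the standard test conditions: a 32³ grid of 2.5 mm
    voxels, 450 volumes at TR 0.5 s, heart rate 66 bpm with 3 bpm
    beat-to-beat jitter and a slow ±2 bpm drift, and a pulsatility
    amplitude twice the white-noise standard deviation.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_dims: tuple[float, float, float] = (2.5, 2.5, 2.5)
    tr: float = 0.5
    n_volumes: int = 450
    mean_hr: float = 66.0
    hr_jitter_sd: float = 3.0
    hr_drift_amplitude: float = 2.0
    hr_drift_period_s: float = 60.0
    vessels: tuple[TubeSegment, ...] = field(default_factory=_default_geometry)
    pulsatility_amplitude: float = 2.0
    noise_sd: float = 1.0
    lowfreq_drift_amplitude: float = 0.5
    baseline: float = 100.0
    roi_dilation: int = 2
    partial_volume_shell: bool = False
    slice_timing: bool = True
    ppg_fs: float = 100.0
    ppg_noise_sd: float = 0.01
    trim_volumes: int = 10  # volumes the pipeline is expected to discard
    seed: int = 7

    def __post_init__(self) -> None:
        if self.pulsatility_amplitude < 0:
            raise PulseVesselError("pulsatility_amplitude must be >= 0")
        if not self.noise_sd > 0:
            raise PulseVesselError("noise_sd must be positive")
        if self.roi_dilation < 1:
            raise PulseVesselError("roi_dilation must be >= 1")


@dataclass
class PhantomBundle:
    """All inputs the pipeline needs, plus the generating ground truth."""

    bold: Bold4D
    physio: PhysioTrace
    brain_mask: Mask3D
    truth_artery: Mask3D
    truth_sss: Mask3D
    general_artery_roi: Mask3D
    general_sss_roi: Mask3D
    generator_waveform: CardiacWaveform
    true_peak_times: np.ndarray  # systolic times, s, relative to retained origin
    config: PhantomConfig


def default_config(**overrides) -> PhantomConfig:
    """The standard phantom configuration, with optional field overrides."""
    return replace(PhantomConfig(), **overrides) if overrides else PhantomConfig()


def generator_waveform_shape(phase: np.ndarray) -> np.ndarray:
    """The ground-truth cardiac waveform as a function of phase in [0, 1).

    A sharp systolic peak near phase 0.15 and a smaller dicrotic bump near
    0.5 — deliberately non-sinusoidal and phase-asymmetric so phase
    binning, not just frequency content, is exercised.  Zero-mean over the
    cycle, peak absolute value 1.
    """
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    w = np.exp(-0.5 * ((p - 0.15) / 0.05) ** 2) + 0.35 * np.exp(
        -0.5 * ((p - 0.5) / 0.08) ** 2
    )
    # analytic-grid demean/normalization constants keep the shape identical
    # no matter what phases it is evaluated at
    grid = (np.arange(4096) + 0.5) / 4096
    wg = np.exp(-0.5 * ((grid - 0.15) / 0.05) ** 2) + 0.35 * np.exp(
        -0.5 * ((grid - 0.5) / 0.08) ** 2
    )
    mean = wg.mean()
    scale = np.max(np.abs(wg - mean))
    return (w - mean) / scale


def _ppg_pulse(phase: np.ndarray) -> np.ndarray:
    """Stereotyped plethysmogram pulse: fast systolic rise, slow decay.

    The systolic maximum sits at phase 0.2 of the beat, which is the
    landmark the true peak times refer to.
    """
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    return np.exp(-0.5 * ((p - 0.2) / 0.07) ** 2) + 0.3 * np.exp(
        -0.5 * ((p - 0.55) / 0.12) ** 2
    )


def dilate_mask(mask: Mask3D, size: int = 3) -> Mask3D:
    """Morphological dilation with a cubic size³ structuring element."""
    if size < 1 or size % 2 == 0:
        raise PulseVesselError("dilation kernel size must be odd and >= 1")
    if size == 1:
        return Mask3D(data=mask.data.copy(), label=mask.label)
    out = ndimage.binary_dilation(mask.data, structure=np.ones((size,) * 3, dtype=bool))
    return Mask3D(data=out, label=mask.label)


def binarize_probability(prob_map: np.ndarray, threshold: float = 0.005) -> Mask3D:
    """Binarize a probability map at a strict ``> threshold`` cut."""
    prob = np.asarray(prob_map, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise PulseVesselError("probability map values must lie in [0, 1]")
    return Mask3D(data=prob > threshold, label="general_artery")


def _rasterize_tubes(
    tubes: list[TubeSegment], shape: tuple[int, int, int], extra_radius: float = 0.0
) -> np.ndarray:
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )
    out = np.zeros(shape, dtype=bool)
    for tube in tubes:
        a = np.asarray(tube.start, dtype=float)
        b = np.asarray(tube.end, dtype=float)
        if np.any(a < 0) or np.any(b < 0) or np.any(a >= shape) or np.any(b >= shape):
            raise PulseVesselError(f"tube {tube} lies outside the grid {shape}")
        ab = b - a
        denom = float(ab @ ab)
        rel = grid - a
        t = np.clip((rel @ ab) / denom if denom > 0 else 0.0, 0.0, 1.0)
        closest = a + t[..., None] * ab
        dist = np.linalg.norm(grid - closest, axis=-1)
        out |= dist <= tube.radius + extra_radius
    return out


def _beat_times(config: PhantomConfig, rng: np.random.Generator, span: float) -> np.ndarray:
    """Beat onset times covering [-2, span] s (scan clock), drifting HR."""
    times = [-2.0]
    while times[-1] < span:
        t = times[-1]
        hr = (
            config.mean_hr
            + config.hr_drift_amplitude
            * np.sin(2.0 * np.pi * t / config.hr_drift_period_s)
            + rng.normal(0.0, config.hr_jitter_sd)
        )
        rr = float(np.clip(60.0 / max(hr, 1e-6), 0.3, 2.0))
        times.append(t + rr)
    return np.asarray(times)


def _phase_at(times: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Linear-fraction phase of ``times`` within the ``anchors`` intervals."""
    idx = np.clip(np.searchsorted(anchors, times, side="right") - 1, 0, anchors.size - 2)
    rr = anchors[idx + 1] - anchors[idx]
    return np.mod((times - anchors[idx]) / rr, 1.0)


def generate_phantom(config: PhantomConfig | None = None) -> PhantomBundle:
    """Build the phantom bundle described by ``config`` (deterministic)."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape
    n_t = config.n_volumes
    tr = config.tr
    scan_len = n_t * tr

    # --- cardiac timing ---------------------------------------------------
    beats = _beat_times(config, rng, scan_len + 2.0)
    # systolic (plethysmogram peak) times: phase 0.2 into each beat
    systole = beats[:-1] + 0.2 * np.diff(beats)

    # --- plethysmogram ----------------------------------------------------
    # trace covers the retained scan plus margins; t0 is expressed relative
    # to the first retained volume (pipeline trims `trim_volumes` volumes)
    retained_origin = config.trim_volumes * tr
    t0 = -(retained_origin + 1.0)  # trace starts 1 s before the scan... in retained clock
    ppg_start_scan = retained_origin + t0  # = -1 s in scan clock
    n_samp = int(round((scan_len + 2.0 - ppg_start_scan) * config.ppg_fs))
    ppg_times = ppg_start_scan + np.arange(n_samp) / config.ppg_fs
    ppg = _ppg_pulse(_phase_at(ppg_times, beats))
    ppg = ppg + rng.normal(0.0, config.ppg_noise_sd, size=ppg.shape)
    physio = PhysioTrace(samples=ppg, fs=config.ppg_fs, t0=t0)

    # --- geometry ---------------------------------------------------------
    artery_tubes = [t for t in config.vessels if t.target == "artery"]
    sss_tubes = [t for t in config.vessels if t.target == "sss"]
    truth_artery = _rasterize_tubes(artery_tubes, config.shape)
    truth_sss = _rasterize_tubes(sss_tubes, config.shape)

    center = (np.asarray(config.shape) - 1) / 2.0
    coords = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in config.shape], indexing="ij"),
        axis=-1,
    )
    brain = np.linalg.norm(coords - center, axis=-1) <= min(config.shape) / 2.0 - 1.0
    truth_artery &= brain
    truth_sss &= brain
    if not truth_artery.any() or not truth_sss.any():
        raise PulseVesselError("vessel geometry does not intersect the brain")

    size = 2 * config.roi_dilation + 1
    general_artery = dilate_mask(Mask3D(truth_artery, "ground_truth"), size)
    general_sss = dilate_mask(Mask3D(truth_sss, "ground_truth"), size)
    if np.any(general_artery.data & general_sss.data):
        raise PulseVesselError("general artery and SSS ROIs overlap")

    # --- signals ----------------------------------------------------------
    if config.slice_timing:
        slice_offsets = (np.arange(nz) / nz) * tr
    else:
        slice_offsets = None
    data = rng.normal(0.0, config.noise_sd, size=(nx, ny, nz, n_t))

    # slow per-voxel drift inside the brain
    vol_onsets = np.arange(n_t) * tr
    bx, by, bz = np.nonzero(brain)
    f_d = rng.uniform(0.01, 0.05, size=bx.size)
    ph_d = rng.uniform(0.0, 2.0 * np.pi, size=bx.size)
    if slice_offsets is None:
        t_acq_slice = vol_onsets[None, :] + tr / 2.0 + np.zeros((nz, 1))
    else:
        t_acq_slice = slice_offsets[:, None] + vol_onsets[None, :]
    drift = config.lowfreq_drift_amplitude * np.sin(
        2.0 * np.pi * f_d[:, None] * t_acq_slice[bz] + ph_d[:, None]
    )
    data[bx, by, bz, :] += drift

    # pulsatile vessel voxels, phase-locked at each voxel's slice time
    shell = np.zeros(config.shape, dtype=bool)
    if config.partial_volume_shell:
        full = _rasterize_tubes(list(config.vessels), config.shape, extra_radius=1.0)
        shell = full & ~(truth_artery | truth_sss) & brain
    for vessel_mask, amp_scale in ((truth_artery | truth_sss, 1.0), (shell, 0.5)):
        if not vessel_mask.any():
            continue
        vx, vy, vz = np.nonzero(vessel_mask)
        phases = _phase_at(t_acq_slice[vz].ravel(), systole).reshape(vz.size, n_t)
        data[vx, vy, vz, :] += (
            amp_scale * config.pulsatility_amplitude * generator_waveform_shape(phases)
        )
    data += config.baseline

    bold = Bold4D(
        data=data,
        voxel_dims=np.asarray(config.voxel_dims, dtype=float),
        tr=tr,
        slice_offsets=slice_offsets,
        affine=np.diag([*config.voxel_dims, 1.0]),
    )

    n_bins = 20
    centers = (np.arange(n_bins) + 0.5) / n_bins
    gen_wave = CardiacWaveform(
        n_bins=n_bins,
        bin_means=generator_waveform_shape(centers),
        bin_counts=np.ones(n_bins, dtype=int),
        interpolated=np.zeros(n_bins, dtype=bool),
    )

    return PhantomBundle(
        bold=bold,
        physio=physio,
        brain_mask=Mask3D(brain, "brain"),
        truth_artery=Mask3D(truth_artery, "ground_truth"),
        truth_sss=Mask3D(truth_sss, "ground_truth"),
        general_artery_roi=Mask3D(general_artery.data, "general_artery"),
        general_sss_roi=Mask3D(general_sss.data, "general_sss"),
        generator_waveform=gen_wave,
        true_peak_times=systole - retained_origin,
        config=config,
    )
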