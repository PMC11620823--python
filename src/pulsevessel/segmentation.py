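"""Data-driven vessel segmentation from cardiac-locked pulsatility.

The method identifies voxels containing large cerebral arteries or the
superior sagittal sinus (SSS) directly on the fMRI grid, in three steps:

1. *Split-half correlation mapping.*  The retained timepoints are split at
   random into two halves, each half is phase-binned into a cardiac
   waveform per voxel, and the two waveforms are correlated.  Averaging
   over 100 random splits yields a mean correlation map: voxels with
   reproducible cardiac-locked pulsatility score high, noise voxels score
   near zero.
2. *Preliminary artery region.*  Voxels inside the general (deliberately
   over-inclusive) artery ROI whose mean correlation exceeds the brain
   mean plus three standard deviations form a preliminary artery region;
   its pooled mean waveform becomes the first template.
3. *Iterative refinement.*  Each voxel's full-series cardiac waveform is
   correlated against the template; a data-driven cutoff is taken as a
   high quantile (99th for arteries, 95th for the SSS) of correlations in
   brain tissue outside both general ROIs; supra-threshold voxels inside
   the target's general ROI form the new segmentation, whose mean waveform
   becomes the next template.  Iteration stops when the segmentation
   volume changes by less than 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cardiac import (
    DEFAULT_N_BINS,
    MAX_INTERPOLATED_FRACTION,
    CardiacWaveform,
    PeakSeries,
    PhaseAssignment,
    assign_phase,
    detect_peaks,
    fill_empty_bins,
    phase_bin_indices,
)
from .errors import EmptyRegionError, PulseVesselError, QualityControlError
from .io import Bold4D, Mask3D, MotionTable, PhysioTrace
from .preprocessing import (
    DEFAULT_PPG_QUALITY_THRESHOLD,
    QcReport,
    highpass_filter,
    run_qc,
    trim_initial_volumes,
)

__all__ = [
    "CorrelationMap",
    "SegmentationResult",
    "SegmentationConfig",
    "PipelineResult",
    "split_halves",
    "waveform_correlation",
    "split_half_corr_map",
    "preliminary_threshold",
    "preliminary_region",
    "region_mean_waveform",
    "template_corr_map",
    "background_quantile",
    "refine_segmentation",
    "segment_vessels",
]

BACKGROUND_QUANTILE = {"artery": 0.99, "sss": 0.95}
CONVERGENCE_TOL = 0.01  # relative volume change between iterations


@dataclass
class CorrelationMap:
    """3D map of voxel-wise correlation coefficients.

    NaN marks voxels that are undefined: outside the search region, with a
    zero-variance waveform, or with too many interpolated phase bins.
    ``kind`` records provenance: the split-half mean map of Step 1 or a
    template-correlation map of Step 3.
    """

    values: np.ndarray
    kind: str
    n_repeats: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise PulseVesselError("correlation map must be 3D")
        if self.kind not in ("split_half_mean", "template"):
            raise PulseVesselError(f"unknown map kind {self.kind!r}")
        defined = self.values[np.isfinite(self.values)]
        if defined.size and (defined.min() < -1 - 1e-9 or defined.max() > 1 + 1e-9):
            raise PulseVesselError("correlation values must lie in [-1, 1]")


@dataclass
class SegmentationResult:
    """Final vessel mask plus the refinement trace that produced it."""

    mask: Mask3D
    target: str
    iterations: list[tuple[float, float, int]]  # (volume_cm3, threshold, n_voxels)
    converged: bool
    template_waveform: CardiacWaveform
    seed: int | None = None


@dataclass
class SegmentationConfig:
    """Tunable parameters of the pipeline, with the defaults it was built for."""

    n_trim: int = 10
    highpass_cutoff_hz: float = 0.005
    highpass_order: int = 2
    n_bins: int = DEFAULT_N_BINS
    n_repeats: int = 100
    max_iter: int = 20
    seed: int = 0
    ppg_quality_threshold: float = DEFAULT_PPG_QUALITY_THRESHOLD
    strict_qc: bool = False
    motion_metric: str = "per_axis"


@dataclass
class PipelineResult:
    """Everything `segment_vessels` computes, for persistence and QC."""

    artery: SegmentationResult
    sss: SegmentationResult | None
    split_half_map: CorrelationMap
    preliminary_mask: Mask3D
    preliminary_threshold: float
    preliminary_waveform: CardiacWaveform
    qc: QcReport
    peaks: PeakSeries
    warnings: list[str] = field(default_factory=list)


def split_halves(
    n_timepoints: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split timepoint indices into ⌊n/2⌋ and the complement."""
    if n_timepoints < 4:
        raise PulseVesselError("need at least 4 timepoints to split")
    perm = rng.permutation(n_timepoints)
    k = n_timepoints // 2
    first = np.sort(perm[:k])
    second = np.sort(perm[k:])
    return first, second


def waveform_correlation(a: CardiacWaveform, b: CardiacWaveform) -> float:
    """Pearson correlation between two cardiac waveforms.

    Both signals are standardized by their mean and (N-1)-normalized
    standard deviation and the products are summed over the N phase
    points; this is the ordinary product-moment correlation.  Undefined
    (NaN) if either waveform has zero variance.
    """
    if a.n_bins != b.n_bins:
        raise PulseVesselError("waveforms must have equal n_bins")
    x, y = a.bin_means, b.bin_means
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        return float("nan")
    n = a.n_bins
    return float(
        np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (n - 1)
    )


def _rowwise_pearson(w: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of ``w`` and matching rows of ``v``.

    ``v`` may be a single vector, broadcast against every row of ``w``.
    Zero-variance rows yield NaN.
    """
    w = np.asarray(w, dtype=float)
    v = np.asarray(v, dtype=float)
    wc = w - w.mean(axis=-1, keepdims=True)
    vc = v - v.mean(axis=-1, keepdims=True)
    num = (wc * vc).sum(axis=-1)
    den = np.sqrt((wc**2).sum(axis=-1) * (vc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


class _MaskedSeries:
    """Per-slice cache of the time series of the voxels in a mask.

    Phase-to-bin assignment is shared by every voxel in a slice (it
    depends only on the slice's acquisition times), so binning reduces to
    one small matrix product per slice and timepoint subset.
    """

    def __init__(
        self,
        bold: Bold4D,
        phases: PhaseAssignment,
        mask: Mask3D,
        n_bins: int,
    ) -> None:
        mask.check_grid(bold)
        if phases.phases.shape != (bold.data.shape[2], bold.n_volumes):
            raise PulseVesselError(
                "phase assignment must have shape (n_slices, n_volumes)"
            )
        self.n_bins = n_bins
        self.coords = np.nonzero(mask.data)
        xs, ys, zs = self.coords
        self.n_vox = xs.size
        self.slices: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for z in np.unique(zs):
            rows = np.nonzero(zs == z)[0]
            series = bold.data[xs[rows], ys[rows], z, :]
            ph = phases.phases[z]
            valid = phases.valid[z]
            self.slices.append((rows, series, ph, valid))

    def waveforms(
        self, subset: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-voxel binned waveforms.

        Returns ``(W, counts, interp_frac)``: waveform matrix
        (n_vox, n_bins) with empty bins interpolated circularly, per-voxel
        bin counts, and the per-voxel fraction of interpolated bins.
        """
        n_bins = self.n_bins
        W = np.empty((self.n_vox, n_bins))
        counts_out = np.zeros((self.n_vox, n_bins), dtype=np.intp)
        frac = np.zeros(self.n_vox)
        for rows, series, ph, valid in self.slices:
            sel = valid if subset is None else (valid & subset)
            n_sel = int(sel.sum())
            if n_sel == 0:
                W[rows] = np.nan
                frac[rows] = 1.0
                continue
            idx = phase_bin_indices(ph[sel], n_bins)
            counts = np.bincount(idx, minlength=n_bins)
            binmat = np.zeros((n_sel, n_bins))
            binmat[np.arange(n_sel), idx] = 1.0
            nonzero = counts > 0
            binmat[:, nonzero] /= counts[nonzero]
            wslice = series[:, sel] @ binmat
            empty = ~nonzero
            if empty.any():
                wslice = fill_empty_bins(
                    wslice, np.broadcast_to(empty, wslice.shape)
                )
            W[rows] = wslice
            counts_out[rows] = counts
            frac[rows] = empty.mean()
        return W, counts_out, frac

    def scatter(self, per_voxel: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
        """Place per-voxel values back onto a NaN-filled 3D grid."""
        out = np.full(shape, np.nan)
        out[self.coords] = per_voxel
        return out


def split_half_corr_map(
    bold: Bold4D,
    phases: PhaseAssignment,
    search_mask: Mask3D,
    n_repeats: int = 100,
    n_bins: int = DEFAULT_N_BINS,
    rng: np.random.Generator | None = None,
) -> CorrelationMap:
    """Step 1: mean split-half waveform correlation per voxel.

    For each of ``n_repeats`` random splits the two half-series waveforms
    of every voxel in ``search_mask`` are correlated; the map holds the
    mean over repeats.  Splits with rejected bin coverage or zero
    variance contribute NaN and are excluded from the mean; a voxel with
    no usable repeat is NaN.
    """
    rng = np.random.default_rng() if rng is None else rng
    cache = _MaskedSeries(bold, phases, search_mask, n_bins)
    n_t = bold.n_volumes
    acc = np.zeros(cache.n_vox)
    n_ok = np.zeros(cache.n_vox, dtype=np.intp)
    for _ in range(n_repeats):
        first, second = split_halves(n_t, rng)
        sub_a = np.zeros(n_t, dtype=bool)
        sub_a[first] = True
        sub_b = np.zeros(n_t, dtype=bool)
        sub_b[second] = True
        wa, _, fa = cache.waveforms(sub_a)
        wb, _, fb = cache.waveforms(sub_b)
        r = _rowwise_pearson(wa, wb)
        bad = (fa > MAX_INTERPOLATED_FRACTION) | (fb > MAX_INTERPOLATED_FRACTION)
        r = np.where(bad, np.nan, r)
        ok = np.isfinite(r)
        acc[ok] += r[ok]
        n_ok += ok
    with np.errstate(invalid="ignore"):
        mean_r = np.where(n_ok > 0, acc / np.maximum(n_ok, 1), np.nan)
    values = cache.scatter(mean_r, search_mask.data.shape)
    return CorrelationMap(values=values, kind="split_half_mean", n_repeats=n_repeats)


def preliminary_threshold(
    corr_map: CorrelationMap, brain_mask: Mask3D, n_sigma: float = 3.0
) -> float:
    """Step 2 threshold: brain mean plus ``n_sigma`` standard deviations."""
    vals = corr_map.values[brain_mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise PulseVesselError(
            f"too few defined brain voxels for the threshold ({vals.size} < 100)"
        )
    return float(vals.mean() + n_sigma * vals.std(ddof=1))


def preliminary_region(
    corr_map: CorrelationMap, general_artery_roi: Mask3D, threshold: float
) -> Mask3D:
    """Step 2 region: supra-threshold voxels inside the general artery ROI."""
    with np.errstate(invalid="ignore"):
        sel = (corr_map.values > threshold) & general_artery_roi.data
    if not sel.any():
        raise EmptyRegionError(
            "empty preliminary region: no pulsatile voxels exceed the "
            f"threshold {threshold:.4f} inside the general artery ROI"
        )
    return Mask3D(data=sel, label="segmentation")


def region_mean_waveform(
    bold: Bold4D,
    phases: PhaseAssignment,
    mask: Mask3D,
    n_bins: int = DEFAULT_N_BINS,
) -> CardiacWaveform:
    """Pooled cardiac waveform of a region.

    Each voxel's series is demeaned over its valid timepoints, and all
    (voxel, timepoint) samples are pooled into the phase bins — the
    region-mean signal binned at the sample level, which stays
    well-defined when different slices sample different cardiac phases.
    """
    if mask.n_voxels == 0:
        raise EmptyRegionError("cannot compute a waveform of an empty region")
    cache = _MaskedSeries(bold, phases, mask, n_bins)
    w, counts, _ = cache.waveforms()
    return _pooled_waveform(w, counts, n_bins)


def _pooled_waveform(
    w: np.ndarray, counts: np.ndarray, n_bins: int
) -> CardiacWaveform:
    """Combine per-voxel waveforms into a count-weighted regional waveform."""
    total = counts.sum(axis=1, keepdims=True).astype(float)
    if np.all(total == 0):
        raise EmptyRegionError("region has no valid samples")
    voxel_mean = (w * counts).sum(axis=1, keepdims=True) / np.maximum(total, 1.0)
    demeaned = w - voxel_mean
    bin_sums = (demeaned * counts).sum(axis=0)
    bin_counts = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(bin_counts > 0, bin_sums / np.maximum(bin_counts, 1), 0.0)
    empty = bin_counts == 0
    means = fill_empty_bins(means, empty)
    return CardiacWaveform(
        n_bins=n_bins, bin_means=means, bin_counts=bin_counts, interpolated=empty
    )


def template_corr_map(
    bold: Bold4D,
    phases: PhaseAssignment,
    template: CardiacWaveform,
    search_mask: Mask3D,
) -> CorrelationMap:
    """Correlate every voxel's full-series waveform against a template."""
    if not template.usable_as_template():
        raise PulseVesselError(
            "template rejected: more than "
            f"{MAX_INTERPOLATED_FRACTION:.0%} of its bins are interpolated"
        )
    cache = _MaskedSeries(bold, phases, search_mask, template.n_bins)
    w, _, frac = cache.waveforms()
    r = _rowwise_pearson(w, template.bin_means)
    r = np.where(frac > MAX_INTERPOLATED_FRACTION, np.nan, r)
    values = cache.scatter(r, search_mask.data.shape)
    return CorrelationMap(values=values, kind="template")


def background_quantile(
    corr_map: CorrelationMap,
    brain_mask: Mask3D,
    exclude_masks: list[Mask3D],
    q: float,
) -> float:
    """Quantile of map values in brain tissue outside the vessel ROIs.

    Uses linear interpolation between order statistics (type 7), so the
    cutoff is bit-reproducible for a given map.
    """
    eligible = brain_mask.data.copy()
    for m in exclude_masks:
        eligible &= ~m.data
    vals = corr_map.values[eligible]
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise PulseVesselError(
            f"too few eligible background voxels ({vals.size} < 100)"
        )
    return float(np.quantile(vals, q, method="linear"))


def _candidate_mask(target: str, general_rois: dict, brain_mask: Mask3D) -> np.ndarray:
    if target == "artery":
        return general_rois["artery"].data
    if target == "sss":
        # the SSS search region is its general ROI restricted to brain
        return general_rois["sss"].data & brain_mask.data
    raise PulseVesselError(f"unknown target {target!r}")


def refine_segmentation(
    bold: Bold4D,
    phases: PhaseAssignment,
    target: str,
    general_rois: dict,
    brain_mask: Mask3D,
    initial_waveform: CardiacWaveform,
    max_iter: int = 20,
    seed: int | None = None,
) -> SegmentationResult:
    """Step 3: iterative template-correlation refinement of one target.

    Each iteration correlates every voxel against the current template
    waveform, thresholds at the background quantile (99th for arteries,
    95th for the SSS, over brain voxels outside both general ROIs), keeps
    supra-threshold voxels inside the target's general ROI, and rebuilds
    the template from the new mask.  Converged when the volume changes by
    less than 1% between iterations; otherwise ``converged`` is False
    after ``max_iter`` iterations and the last mask is returned.
    """
    q = BACKGROUND_QUANTILE[target]
    n_bins = initial_waveform.n_bins
    exclude = [m for m in (general_rois.get("artery"), general_rois.get("sss")) if m]
    candidates = _candidate_mask(target, general_rois, brain_mask)

    # the search region must cover both the candidates and the background
    search = brain_mask.data.copy()
    for m in exclude:
        search |= m.data
    search_mask = Mask3D(data=search, label="brain")

    # per-voxel full-series waveforms never change across iterations;
    # compute them once and re-correlate against each new template
    cache = _MaskedSeries(bold, phases, search_mask, n_bins)
    w_full, counts_full, frac_full = cache.waveforms()
    usable = frac_full <= MAX_INTERPOLATED_FRACTION
    voxel_volume_cm3 = float(np.prod(bold.voxel_dims)) / 1000.0

    xs, ys, zs = cache.coords
    in_candidates = candidates[xs, ys, zs]
    eligible_bg = brain_mask.data.copy()
    for m in exclude:
        eligible_bg &= ~m.data
    in_background = eligible_bg[xs, ys, zs]

    template = initial_waveform
    iterations: list[tuple[float, float, int]] = []
    converged = False
    prev_n: int | None = None
    member = None
    for _ in range(max_iter):
        if not template.usable_as_template():
            raise PulseVesselError("template waveform rejected during refinement")
        r = _rowwise_pearson(w_full, template.bin_means)
        r = np.where(usable, r, np.nan)
        bg = r[in_background]
        bg = bg[np.isfinite(bg)]
        if bg.size < 100:
            raise PulseVesselError(
                f"too few eligible background voxels ({bg.size} < 100)"
            )
        threshold = float(np.quantile(bg, q, method="linear"))
        with np.errstate(invalid="ignore"):
            member = in_candidates & (r > threshold)
        n_vox = int(member.sum())
        if n_vox == 0:
            raise EmptyRegionError(
                f"refinement produced an empty {target} segmentation "
                f"(threshold {threshold:.4f})"
            )
        iterations.append((n_vox * voxel_volume_cm3, threshold, n_vox))
        if prev_n is not None and abs(n_vox - prev_n) / prev_n < CONVERGENCE_TOL:
            converged = True
            break
        prev_n = n_vox
        template = _pooled_waveform(w_full[member], counts_full[member], n_bins)

    mask_data = np.zeros(bold.spatial_shape, dtype=bool)
    mask_data[xs[member], ys[member], zs[member]] = True
    return SegmentationResult(
        mask=Mask3D(data=mask_data, label="segmentation"),
        target=target,
        iterations=iterations,
        converged=converged,
        template_waveform=template,
        seed=seed,
    )


def segment_vessels(
    bold: Bold4D,
    physio: PhysioTrace,
    brain_mask: Mask3D,
    general_artery_roi: Mask3D,
    general_sss_roi: Mask3D | None = None,
    motion: MotionTable | None = None,
    config: SegmentationConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline: QC, alignment, Steps 1-3 for both targets.

    The SSS target is skipped (with a warning recorded in the result) when
    no general SSS ROI is supplied.  All randomness — the 100 split-half
    partitions — is governed by ``config.seed``, so identical inputs and
    seed reproduce the result bit for bit.
    """
    config = config or SegmentationConfig()
    notes: list[str] = []
    for m in (brain_mask, general_artery_roi, general_sss_roi):
        if m is not None:
            m.check_grid(bold)

    # --- pre-processing -------------------------------------------------
    trimmed = trim_initial_volumes(bold, config.n_trim)
    search = brain_mask.data | general_artery_roi.data
    if general_sss_roi is not None:
        search = search | general_sss_roi.data
    search_mask = Mask3D(data=search, label="brain")
    filtered = highpass_filter(
        trimmed,
        cutoff=config.highpass_cutoff_hz,
        order=config.highpass_order,
        brain_mask=search_mask,
    )

    # --- quality gates ---------------------------------------------------
    qc = run_qc(
        physio,
        n_volumes_retained=filtered.n_volumes,
        motion=motion,
        voxel_dims=bold.voxel_dims if motion is not None else None,
        ppg_threshold=config.ppg_quality_threshold,
        motion_metric=config.motion_metric,
    )
    failed = (not qc.ppg_pass) or (qc.motion_pass is False)
    if failed:
        msg = (
            f"quality control failed (ppg_quality={qc.ppg_quality:.3f}, "
            f"max_translation_mm={qc.max_translation_mm})"
        )
        if config.strict_qc:
            raise QualityControlError(msg)
        notes.append(msg)

    # --- cardiac alignment ----------------------------------------------
    try:
        peaks = detect_peaks(physio)
        phases = assign_phase(filtered.acquisition_times(), peaks)
    except PulseVesselError as err:
        raise PulseVesselError(f"cardiac alignment failed: {err}") from err

    # --- Step 1: split-half correlation map ------------------------------
    rng = np.random.default_rng(config.seed)
    corr_map = split_half_corr_map(
        filtered,
        phases,
        search_mask,
        n_repeats=config.n_repeats,
        n_bins=config.n_bins,
        rng=rng,
    )

    # --- Step 2: preliminary artery region -------------------------------
    t_prelim = preliminary_threshold(corr_map, brain_mask)
    prelim = preliminary_region(corr_map, general_artery_roi, t_prelim)
    prelim_waveform = region_mean_waveform(filtered, phases, prelim, config.n_bins)

    # --- Step 3: refinement for each target ------------------------------
    general_rois = {"artery": general_artery_roi}
    if general_sss_roi is not None:
        general_rois["sss"] = general_sss_roi
    artery = refine_segmentation(
        filtered, phases, "artery", general_rois, brain_mask,
        prelim_waveform, max_iter=config.max_iter, seed=config.seed,
    )
    sss = None
    if general_sss_roi is not None:
        sss = refine_segmentation(
            filtered, phases, "sss", general_rois, brain_mask,
            prelim_waveform, max_iter=config.max_iter, seed=config.seed,
        )
    else:
        notes.append("no general SSS ROI supplied; artery-only run")

    return PipelineResult(
        artery=artery,
        sss=sss,
        split_half_map=corr_map,
        preliminary_mask=prelim,
        preliminary_threshold=t_prelim,
        preliminary_waveform=prelim_waveform,
        qc=qc,
        peaks=peaks,
        warnings=notes,
    )
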