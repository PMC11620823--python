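# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `pulsevessel`, and what the synthetic phantom does and
does not establish about real data.

## Signal model and assumptions

A voxel occupied (fully or partially) by a large vessel is modelled as

    x(t) = a · w(φ(t)) + drift(t) + ε(t),

where φ(t) ∈ [0, 1) is the cardiac phase at the voxel's acquisition time,
w is a fixed (per subject/region) waveform over one cardiac cycle, `a` is
the pulsatility amplitude, drift is slow non-cardiac physiology/scanner
drift and ε is white noise. The method assumes:

- the PPG systolic peaks are a valid cardiac reference for the whole
  brain (transit-time differences appear only as a constant phase offset,
  which correlation-based detection tolerates);
- heart rate varies, so phase is the *fraction of the RR interval*, not
  time-since-peak;
- sampling is incoherent with the heartbeat, so phase bins fill roughly
  uniformly over a few minutes of scanning. This is why temporal aliasing
  (cardiac frequency above 1/(2·TR)) does not harm phase binning;
- non-vessel brain voxels have no reproducible cardiac-locked waveform.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| trimmed initial volumes | 10 | volumes | discard T1-relaxation transients |
| high-pass cutoff | 0.005 | Hz | remove DC and scanner drift only |
| Butterworth order | 2 | — | gentle roll-off; applied forward-backward (zero phase) so cardiac phase is not shifted relative to the PPG |
| phase bins N | 20 | bins | ~11–25 samples per bin for 220–490 retained volumes; finer bins trade occupancy for phase resolution |
| split-half repeats | 100 | — | stabilizes the mean correlation map |
| preliminary threshold | brain mean + 3 s.d. | — | participant-specific, data-driven |
| refinement quantile | 0.99 artery / 0.95 SSS | — | background correlation quantile outside both general ROIs |
| convergence | < 1% | relative volume | between successive iterations; `max_iter` 20 |
| PPG quality pass | ≥ 0.30 | fraction | white-noise floor of the score is ≈ 0.24, a clean pulse scores > 0.9 |
| motion pass | max translation ≤ min voxel dim | mm | per-axis maximum by default; Euclidean-norm variant behind a flag |

The zero-phase high-pass is applied with maximum reflect padding and an
explicit residual-mean subtraction: at a 0.005 Hz cutoff the filter's
natural time scale (200 s) is comparable to a whole run, and the default
short padding both leaves a DC residue and inflates the negative
correlation between disjoint half-series (the split-half null). With the
long padding the null bias of the split-half map on pure noise is at the
per-mill level for 400+ volumes, and both data-driven thresholds adapt to
whatever null the filter leaves.

The PPG quality score is the fraction of periodogram power within
±0.15 Hz of the cardiac peak (located between 0.6 and 2.0 Hz) and its
first harmonic, relative to the total power between 0.5 and 3 Hz; traces
whose 0.5–3 Hz power is below 0.1% of their total variance score 0 (no
identifiable pulse). Peak detection band-passes the trace to 0.5–3 Hz
and keeps local maxima at least 0.3 s apart with prominence ≥ 0.5 × the
pulse amplitude, where the pulse amplitude is estimated as the 75th
percentile of candidate prominences — candidates include dicrotic bumps,
so the plain median would sit between the two modes and can let dicrotic
peaks through (doubling apparent heart rate for some noise draws). Gaps
longer than 2 s are re-searched among discarded candidates; RR intervals
outside 0.3–2.0 s are excluded from the mean heart rate, and timepoints
inside them are marked invalid.

## Design choices where the procedure was genuinely open

- **Phase binning.** The cardiac-aligned "signals" are phase-binned means
  over N = 20 equal bins (configurable). Empty bins are filled by
  circular linear interpolation and flagged; a waveform with more than
  25% interpolated bins is rejected as a template and its voxel is
  undefined (NaN) in correlation maps.
- **Correlation.** Eq-style (N−1)-normalized standardization — the
  ordinary Pearson product-moment coefficient over the N phase points.
  Zero-variance waveforms give NaN, and NaN never enters thresholds,
  quantiles or masks.
- **Regional waveform.** Voxel series are demeaned over their valid
  timepoints and all (voxel, timepoint) samples are pooled into the phase
  bins. Sample-level pooling (rather than binning a pre-averaged 1-D
  series) stays well defined when slice timing gives different slices
  different phases at the same volume.
- **SSS candidate set.** SSS candidates are the general SSS ROI
  intersected with the brain mask; the background-quantile population is
  brain ∧ ¬(artery ROI ∪ SSS ROI) for both targets.
- **Strict inequalities** for all thresholds (correlation > cutoff,
  probability > 0.005).
- **Quantiles** use linear interpolation between order statistics
  (type 7) for bit-reproducibility.
- **Randomness.** One integer seed drives the 100 split-half partitions;
  identical inputs and seed reproduce masks, maps and iteration traces
  bit for bit. Oscillating refinements return `converged=False` with the
  last mask after 20 iterations.
- **Slice timing** is optional metadata: when absent, all slices of a
  volume share the volume onset + TR/2.
- **Motion rule.** "Maximum translation" is read as the per-axis maximum
  absolute translation relative to the reference volume (most literal
  reading of a motion-parameter printout); a vector-magnitude variant is
  available.
- **Percent overlap** defaults to |X∩Y|/|Y|·100 (how much of the
  reference the tested segmentation covers); the raw size ratio
  |X|/|Y|·100 is available behind a flag since both readings of the
  definition occur in practice. Both orderings are reported by the CLI.
- **ICC.** ICC(A,1) — two-way model, single rater, absolute agreement —
  is computed from the two-way ANOVA mean squares with the McGraw & Wong
  F-based 95% CI and the F-test against ICC = 0. The test suite
  cross-checks it against pingouin's independent implementation.

## The synthetic phantom

The phantom emulates the statistical structure the algorithm relies on,
at desk scale: a 32³ grid of 2.5 mm voxels, 450 volumes at TR 0.5 s
(~225 s of data, 440 retained), a schematic arterial ring near the grid
centre and one SSS tube along the top of the brain sphere, a PPG sampled
at 100 Hz built from stereotyped pulses (systolic peak, dicrotic bump) on
beats with mean 66 bpm, ±2 bpm slow drift and 3 bpm beat-to-beat jitter,
vessel voxels carrying a non-sinusoidal two-component waveform (systolic
peak at phase ≈ 0.15, dicrotic bump at ≈ 0.5) at amplitude 2× the noise
s.d., slow sinusoidal drift (amplitude 0.5, 0.01–0.05 Hz) in all brain
voxels, and ascending slice timing. General ROIs are the ground-truth
tubes dilated by 2 voxels (~9–11× the true volume). An optional
partial-volume shell adds half-amplitude voxels around each tube.

Deliberate properties: the heart rate (1.1 Hz) exceeds the Nyquist
frequency (1.0 Hz), so the phantom exercises the alias-immunity of phase
binning and the folded-frequency reporting of the spectral module; the
waveform is phase-asymmetric so binning, not just frequency content, is
tested; the generator is bit-deterministic given its seed.

What the phantom does **not** emulate: respiratory modulation, motion,
EPI distortion, vascular territory anatomy, spatial noise correlations,
multi-vessel waveform differences, or BOLD-specific signal scaling.
Passing the phantom tests therefore shows the algorithm is implemented
correctly and recovers planted pulsatility at realistic SNR and timing —
not that it segments any particular scanner's data; on real data the
over-inclusiveness of the general ROIs and the PPG quality remain the
user's responsibility.

Problem sizes used in the automated checks (32³ grid, 450 volumes, 100
split repeats, 1000-voxel noise nulls, 400×4 simulated volume tables)
were chosen so the entire battery runs in about a minute on one core
while keeping the Monte-Carlo error well below the asserted margins.

## Degenerate inputs and numerical edges

- series shorter than 8 volumes cannot be filtered (hard error); fewer
  than 3 detected peaks, all-empty phase bins, empty regions and empty
  reference masks raise typed exceptions rather than propagating NaN;
- thresholds and quantiles require ≥ 100 defined voxels;
- identical paired series report a paired-t p of 1 (perfect agreement)
  instead of NaN;
- a TR conflict between the NIfTI header and an explicit configuration
  (> 1 ms) logs a warning and the configured value wins;
- masks are never resampled: any grid mismatch is an error, because
  registration is explicitly outside this package's scope.

## Known limitations

- The split-half null is not exactly zero-mean at short record lengths
  (the high-pass acts like a detrender, anti-correlating disjoint
  halves); both data-driven thresholds absorb this, but the raw map
  values at < 200 volumes should not be interpreted as unbiased
  correlation estimates.
- Averaging split-half repeats reduces map variance only ~2-fold relative
  to a single split: all splits share the same data, so the
  data-dependent component of the estimate does not average out.
- Phase assignment trusts the PPG clock; a clock offset that *drifts*
  relative to the scanner (rather than a constant t0) would smear
  waveforms and is not modelled.
- The SSS branch assumes the general SSS ROI, after its deliberate
  dilation, still overlaps the brain mask; a brain mask that excludes the
  sinus entirely empties the candidate set.
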