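"""Run the full data-driven vessel segmentation on the phantom.

The pipeline trims 10 volumes, high-passes at 0.005 Hz, checks PPG
quality, assigns each timepoint a cardiac phase, computes the 100-repeat
split-half correlation map (Step 1), thresholds it at the brain mean + 3
standard deviations inside the general artery ROI (Step 2), and
iteratively refines both targets against the region-mean waveform until
the segmentation volume stabilizes within 1% (Step 3).
"""

import pulsevessel as pv

bundle = pv.generate_phantom()
result = pv.segment_vessels(
    bundle.bold,
    bundle.physio,
    bundle.brain_mask,
    bundle.general_artery_roi,
    bundle.general_sss_roi,
    config=pv.SegmentationConfig(seed=1),
)

print(f"PPG quality: {result.qc.ppg_quality:.3f} (pass: {result.qc.ppg_pass})")
print(f"preliminary threshold (brain mean + 3 sd): {result.preliminary_threshold:.3f}")
print(f"preliminary artery region: {result.preliminary_mask.n_voxels} voxels\n")

for seg, truth in ((result.artery, bundle.truth_artery),
                   (result.sss, bundle.truth_sss)):
    d = pv.dice(seg.mask, truth)
    vol = pv.volume_cm3(seg.mask, bundle.bold.voxel_dims)
    print(f"{seg.target}: converged in {len(seg.iterations)} iterations, "
          f"{seg.mask.n_voxels} voxels ({vol:.2f} cm^3), Dice vs truth = {d:.3f}")
    for i, (v, thr, n) in enumerate(seg.iterations, 1):
        print(f"  iteration {i}: threshold {thr:.3f}, volume {v:.3f} cm^3")
# Dice near 1 means the pipeline recovered the simulated vessels from the
# over-inclusive search ROIs using pulsatility alone.
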