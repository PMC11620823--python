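"""Build the synthetic pulsatile phantom and inspect what it contains.

The phantom is a 32x32x32 grid of 2.5 mm voxels imaged for 450 volumes at
TR 0.5 s.  Tube-shaped vessel voxels carry a cardiac waveform locked to a
synthetic finger-plethysmography trace (66 bpm with jitter and drift);
everything else is noise plus slow drift.  The "general" ROIs are the
ground-truth tubes dilated by 2 voxels — deliberately over-inclusive, as
the segmentation expects.
"""

import pulsevessel as pv

bundle = pv.generate_phantom()  # default configuration, seed 7

print(f"BOLD shape:            {bundle.bold.data.shape}  (TR {bundle.bold.tr} s)")
print(f"brain voxels:          {bundle.brain_mask.n_voxels}")
print(f"true artery voxels:    {bundle.truth_artery.n_voxels}")
print(f"true SSS voxels:       {bundle.truth_sss.n_voxels}")
print(f"general artery ROI:    {bundle.general_artery_roi.n_voxels} voxels")
print(f"general SSS ROI:       {bundle.general_sss_roi.n_voxels} voxels")
print(f"PPG: {bundle.physio.duration:.0f} s at {bundle.physio.fs:.0f} Hz, "
      f"t0 = {bundle.physio.t0:.1f} s")

peaks = pv.detect_peaks(bundle.physio)
print(f"\ndetected mean heart rate: {peaks.mean_hr:.1f} bpm "
      f"(generator used {bundle.config.mean_hr:.0f} bpm)")
# The general ROIs are ~9-11x larger than the true vessels: the
# segmentation's job is to find the pulsatile voxels inside them.
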