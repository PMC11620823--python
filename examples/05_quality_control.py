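"""Quality gates: plethysmogram quality score and the motion rule.

The PPG score is the fraction of spectral power within +/-0.15 Hz of the
cardiac peak and its first harmonic, relative to the 0.5-3 Hz band; a
clean pulse scores near 1, a disconnected probe near the white-noise
floor (~0.24).  A scan fails the motion rule when the maximum translation
exceeds the voxel size.
"""

import numpy as np

import pulsevessel as pv

bundle = pv.generate_phantom()
rng = np.random.default_rng(0)

clean = bundle.physio
noisy = pv.PhysioTrace(
    clean.samples + rng.normal(0.0, 3.0, clean.samples.size), fs=clean.fs
)
flatline_noise = pv.PhysioTrace(rng.normal(size=clean.samples.size), fs=clean.fs)

for name, trace in (("clean phantom PPG", clean),
                    ("heavily corrupted", noisy),
                    ("probe disconnected (noise)", flatline_noise)):
    q = pv.ppg_quality(trace)
    print(f"{name:28s} quality = {q:.3f}  pass(>=0.30) = {q >= 0.30}")

print()
params = np.zeros((440, 6))
params[200, 3] = 1.8   # 1.8 mm translation spike in x
ok_table = pv.MotionTable(params)
max_t, ok = pv.motion_check(ok_table, bundle.bold.voxel_dims)
print(f"max translation {max_t:.1f} mm vs voxel {bundle.bold.voxel_dims.min()} mm "
      f"-> pass = {ok}")

params[300, 4] = 3.1   # exceeds the 2.5 mm voxel
max_t, ok = pv.motion_check(pv.MotionTable(params), bundle.bold.voxel_dims)
print(f"max translation {max_t:.1f} mm vs voxel {bundle.bold.voxel_dims.min()} mm "
      f"-> pass = {ok}")
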