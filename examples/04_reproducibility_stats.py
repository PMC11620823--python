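"""Reproducibility statistics for repeated segmentation volumes.

Simulates 4 repeated scans for 400 participants with a known
between-subject / within-subject variance split (true ICC = 0.8) and runs
the full agreement battery: ICC(A,1), total-least-squares regression,
Pearson correlation, Bland-Altman limits and the paired t-test for every
unordered scan pair.
"""

import numpy as np
import pandas as pd

import pulsevessel as pv

rng = np.random.default_rng(0)
n, k = 400, 4
subject_effect = rng.normal(0.0, 2.0, size=(n, 1))  # between-subject sd 2 cm^3
volumes = 10.0 + subject_effect + rng.normal(0.0, 1.0, size=(n, k))
table = pd.DataFrame(volumes, columns=["REST1_AP", "REST1_PA", "REST2_AP", "REST2_PA"])

icc, lo, hi, p = pv.icc_absolute_agreement(table.to_numpy())
print(f"ICC(A,1) = {icc:.3f} (95% CI {lo:.3f}-{hi:.3f}, p = {p:.2g})")
print("true ICC = 2^2 / (2^2 + 1^2) = 0.8\n")

pairs = pv.pairwise_agreement(table)
print(f"{len(pairs)} pairwise comparisons:")
for (a, b), rep in pairs.items():
    print(f"  {a} vs {b}: y = {rep.tls_slope:.2f}x + {rep.tls_intercept:.2f}, "
          f"r = {rep.pearson_r:.2f}; mean diff = {rep.mean_diff:+.2f} cm^3 "
          f"[{rep.loa_low:.2f}, {rep.loa_high:.2f}], paired-t p = {rep.paired_t_p:.2f}")
# With no systematic scan effect the slopes sit near 1, mean differences
# near 0, and the paired t-tests are non-significant.
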