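"""Digitization repeatability and outlier screening.

Simulates 200 faces landmarked twice with digitization noise at a 9:1
between/within variance ratio, estimates the intraclass correlation from
Procrustes ANOVA, and screens a contaminated dataset for outliers.
"""

import numpy as np
import pandas as pd

import dimorph as dm

template, base = dm.generate_template_face()
rng = np.random.default_rng(5)
n = 200
sigma_within = 0.004
true = base.reshape(-1) + rng.normal(0, 3 * sigma_within, (n, 40))
obs = np.repeat(true, 2, axis=0) + rng.normal(0, sigma_within, (2 * n, 40))
meta = pd.DataFrame({
    "id": [f"r{i}" for i in range(2 * n)],
    "individual": np.repeat([f"face{j}" for j in range(n)], 2),
})
aligned = dm.gpa(obs.reshape(-1, 20, 2), template=template, meta=meta)
rep = dm.repeatability(aligned)
print(f"repeatability (ICC) = {rep.repeatability:.3f}, "
      f"measurement error = {rep.measurement_error:.3f}")
print(f"variance components (between, within) = "
      f"({rep.variance_components[0]:.2e}, {rep.variance_components[1]:.2e})")

pts = base + rng.normal(0, 0.003, (50, 20, 2))
pts[13] = base + rng.normal(0, 0.3, (20, 2))  # one botched digitization
bad = dm.gpa(pts, template=template)
print(f"\noutliers flagged: {dm.detect_outliers(bad)}")
print("\nICC near 0.9 matches the simulated 9:1 variance ratio — the same")
print("quantity reported as landmarking precision in morphometric studies;")
print("the flagged specimen is the deliberately corrupted one.")
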