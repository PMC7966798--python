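"""Attractiveness preference models.

Fits the mixed-effects model rating ~ sexscore x sex with random intercepts
and slopes by population (females the reference category), then a
population-level Bayesian regression by quadratic approximation with an
89% compatibility interval.
"""

import numpy as np

import dimorph as dm

spec = dm.default_spec(seed=4, n_populations=8, n_per_sex=150)
dataset = dm.generate_dataset(spec)  # true slopes: women 0.2, men 0.0
aligned = dm.gpa(
    dm.assemble_dataset(dataset.configs, dataset.metadata, dataset.template)
)
result = dm.allometric_decomposition(aligned)
frame = result.to_frame()
heights = aligned.meta["height"].to_numpy(dtype=float)
frame["rating"] = aligned.meta["attractiveness"].to_numpy(dtype=float)[
    np.isfinite(heights)
]

scores = dm.standardize_ratings(frame["score_overall"].to_numpy(),
                                frame["population"].to_numpy())
lmm = dm.fit_attractiveness_lmm(scores, frame["rating"].to_numpy(),
                                frame["sex"].to_numpy(),
                                frame["population"].to_numpy())
print(lmm.fixed_effects.round(4).to_string())
print(f"\nfit: {lmm.method}; converged={lmm.converged}")

# population level: does the sex height gap predict dimorphism magnitude?
traj = dm.trajectory_analysis(aligned, n_perm=99, seed=0)
sex = aligned.meta["sex"].to_numpy()
pop = aligned.meta["population"].to_numpy()
gaps = np.array([
    heights[(pop == p) & (sex == "male")].mean()
    - heights[(pop == p) & (sex == "female")].mean()
    for p in traj.populations
])
x = (gaps - gaps.mean()) / gaps.std(ddof=1)
y = (traj.magnitudes - traj.magnitudes.mean()) / traj.magnitudes.std(ddof=1)
quap = dm.bayes_linear_quap(x, y)
lo, hi = quap.interval_89[1]
print(f"\nheight gap vs dimorphism magnitude: slope MAP = "
      f"{quap.map_estimate[1]:.3f}, 89% interval [{lo:.3f}, {hi:.3f}]")
print("\nThe women slope near 0.2 and men slope change near -0.2 recover")
print("the generative preference structure.  The population-level")
print("regression illustrates the quadratic approximation; with only eight")
print("populations sharing one height-gap parameter, its slope reflects")
print("sampling noise in the per-population magnitudes, not a real effect.")
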