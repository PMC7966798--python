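"""Trajectory analysis and morphological disparity across populations.

Compares sex-difference vectors between populations in magnitude and
direction with permutation tests, and estimates per-group Procrustes
variance (morphological disparity).  One population is generated with twice
the sex effect of the other so the magnitude test has something to find.
"""

import numpy as np

import dimorph as dm

template, base = dm.generate_template_face()
rng = np.random.default_rng(2)
d = dm.structured_vector(rng, base, template, 0.03)
pops = [
    dm.PopulationSpec(name="LOW", n_per_sex=150, mean_offset=np.zeros(40),
                      sex_effect=d, allometric_vector=np.zeros(40)),
    dm.PopulationSpec(name="HIGH", n_per_sex=150, mean_offset=np.zeros(40),
                      sex_effect=2 * d, allometric_vector=np.zeros(40)),
]
dataset = dm.generate_dataset(
    dm.SyntheticSpec(populations=pops, shape_noise_sd=0.003, seed=2)
)
aligned = dm.gpa(
    dm.assemble_dataset(dataset.configs, dataset.metadata, dataset.template)
)

traj = dm.trajectory_analysis(aligned, n_perm=999, seed=0)
print("sex-vector magnitude per population (truth: 0.03 vs 0.06):")
for p, m in zip(traj.populations, traj.magnitudes):
    print(f"  {p}: {m:.4f}")
print(f"magnitude difference p = {traj.p_magnitude[0, 1]:.4f}")
print(f"between-vector angle = {traj.angles_deg[0, 1]:.1f} deg, "
      f"p = {traj.p_angle[0, 1]:.4f}")

disp = dm.morphological_disparity(
    aligned.shapes, aligned.meta["population"].to_numpy(),
    n_perm=999, seed=1,
)
disp_nosex = dm.morphological_disparity(
    aligned.shapes, aligned.meta["population"].to_numpy(),
    partial_out_group_means=True, sex=aligned.meta["sex"].to_numpy(),
    n_perm=999, seed=1,
)
print("\nProcrustes variance per population (total | sex partialled out):")
for g, v, v0 in zip(disp.groups, disp.variances, disp_nosex.variances):
    print(f"  {g}: {v:.6f} | {v0:.6f}")
print(f"pairwise total-disparity difference p = {disp.pairwise_p[0, 1]:.4f}")
print("\nA small magnitude p confirms the doubled sex effect.  Total")
print("disparity is inflated in HIGH by its wider male-female separation;")
print("once sex means are partialled out the residual variation matches.")
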