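"""The two bespoke resampling tests on the regional dimorphism contrast.

The randomization test reassigns populations to faces at random (keeping
each face's sex and every population's sex counts) to get a null for the
regional median-distance contrast of sexscore distributions.  The random
split-sample test checks whether a statistic (here the allometric angle
alpha) differs more between populations than within them.
"""

import numpy as np

import dimorph as dm

# region A gets half the sex effect of region B
spec = dm.default_spec(seed=3, n_populations=4, n_per_sex=150,
                       sex_effect_norms=[0.015, 0.015, 0.03, 0.03])
dataset = dm.generate_dataset(spec)
aligned = dm.gpa(
    dm.assemble_dataset(dataset.configs, dataset.metadata, dataset.template)
)
sex = aligned.meta["sex"].to_numpy()
pop = aligned.meta["population"].to_numpy()
region = {"P1": "A", "P2": "A", "P3": "B", "P4": "B"}

scores = dm.sexscore(aligned.shapes,
                     dm.sex_difference_vector(aligned.shapes, sex))
observed = dm.median_distance_statistic(scores, sex, pop, region, "A")
print(f"median separation per population: "
      f"{ {k: round(v, 5) for k, v in observed['per_population'].items()} }")
print(f"contrast (other - region A) = {observed['contrast']:.5f}")


def contrast(labels):
    return dm.median_distance_statistic(scores, sex, labels, region,
                                        "A")["contrast"]


rand = dm.randomization_test(contrast, pop, sex, n_perm=999, seed=0,
                             label="median-distance contrast")
print(f"randomization test: p = {rand.p_value:.4f} "
      f"(null mean {rand.null_mean:.2e}, SD {rand.null_sd:.2e})")

shapes = aligned.shapes
h = aligned.meta["height"].to_numpy(dtype=float)


def alpha(idx):
    v = dm.sex_difference_vector(shapes[idx], sex[idx])
    _, _, v2 = dm.regress_shape_on_covariate(shapes[idx], h[idx])
    return dm.angle_between(v.v1, v2)


split = dm.split_sample_test(alpha, pop, sex, n_perm=499, seed=0,
                             label="allometric angle")
print(f"split-sample test on alpha: p = {split.p_value:.4f}")
print("\nA small randomization p says region A's weaker dimorphism is not")
print("a labelling accident.  The split-sample p is also small here: the")
print("four populations carry different allometric vectors, so alpha")
print("differs more between populations than between halves of one.")
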