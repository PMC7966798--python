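# dimorph

Geometric morphometrics of facial **sexual shape dimorphism (SShD)** for 2D
landmark data: a reusable, tested Python implementation of the analysis
chain used in cross-population studies of face shape — from raw landmark
files to preference models — plus a synthetic-data generator with known
ground truth so every stage can be validated end to end.

## Who it is for

Researchers in biological anthropology and evolutionary psychology working
with landmarked face photographs (or any bilateral 2D structure) who need:
superimposition with semilandmarks, per-individual dimorphism scores, an
allometric/non-allometric decomposition, cross-population comparisons with
permutation-based inference, and models linking dimorphism to perceived
attractiveness.

## The statistics at the core

Landmark configurations are superimposed by **generalized Procrustes
analysis** (translation removed, centroid size scaled to 1, rotations
iterated to the consensus), semilandmarks slide along their curve tangents
to minimize **thin-plate-spline bending energy**, and shapes are
**symmetrized** by averaging each configuration with its relabelled mirror
image.

An individual shape vector *A* is scored against the axis from the female
mean (FM) to the male mean (MM):

```
sexscore(A) = A · (MM − FM)
```

The raw dot product is kept un-normalized (squared Procrustes units).
Female scores are inverted so that higher always means more sex-typical.
With body height *h*, per-coordinate regression of shape on *h* yields the
allometric vector **v₂**; projecting fitted values on **v₁** = MM − FM
gives allometric SShD, and projecting the residuals on
**v₃** = MM_res − FM_res gives non-allometric SShD. The angles

```
cos α = v₁·v₂ / (‖v₁‖‖v₂‖),   cos ν = v₁·v₃ / (‖v₁‖‖v₃‖)
```

quantify how much of the dimorphism axis is body-size driven. Populations
are compared by trajectory analysis (magnitude and direction of per-
population sex vectors), Procrustes-variance disparity, a regional
median-distance contrast, and two bespoke resampling tests (population
randomization within sex; random split-sample). Preference is modelled as
`rating ~ sexscore × sex` with random intercepts and slopes by population
(REML), and population-level regressions use a Bayesian quadratic
approximation with N(0, 1) priors and 89% compatibility intervals.

## Worked example

```python
import dimorph as dm

spec = dm.default_spec(seed=1, n_populations=4, n_per_sex=100)
data = dm.generate_dataset(spec)                      # TPS-style study
aligned = dm.gpa(dm.assemble_dataset(data.configs, data.metadata,
                                     data.template))
result = dm.allometric_decomposition(aligned, scope="per-population")
print(result.per_population.round(4).to_string(index=False))
```

prints

```
population   n  v1_norm  v2_norm  v3_norm  alpha_deg  nu_deg
        P1 200   0.0326   0.0014   0.0154    15.8268 19.2787
        P2 200   0.0352   0.0016   0.0128     9.9284 18.3202
        P3 200   0.0256   0.0010   0.0145    24.1448 22.0386
        P4 200   0.0340   0.0017   0.0134    12.0921 20.0402
```

Each population's sex-vector magnitude (`v1_norm`, here generated at 0.03
plus the allometric contribution of the 13 cm height gap), the norm of the
shape-on-height coefficient vector, and the angles α and ν in degrees. The
small α values say most of the dimorphism axis lies along the allometric
direction — male and female faces differ largely the way tall and short
faces do. The `examples/` directory walks through every capability
(superimposition, scoring, trajectory/disparity, permutation tests,
preference models, repeatability) as short narrative scripts.

A thin CLI mirrors the library for shell use:

```bash
dimorph simulate --seed 1 --out study/
dimorph align --tps study/landmarks.tps --metadata study/metadata.csv \
        --template study/template.yaml --out aligned.csv
dimorph sshd --aligned aligned.csv --template study/template.yaml --out sshd/
dimorph all --out run/ --seed 1       # full pipeline, summary.json at the end
```

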