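# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `dimorph`, in the spirit of a statistical software
methods appendix. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from external
analyses.

## Superimposition

**Generalized Procrustes analysis.** Configurations are centred, scaled to
unit centroid size (partial Procrustes), and iteratively rotated to the
running consensus; the consensus is renormalized each iteration and the
loop stops when its root-mean-square change falls below `tol = 1e-10`
(default `max_iter = 100`; non-convergence is an error, not a warning).
Rotations come from the 2D Kabsch solution with the determinant forced to
+1, so reflections can never slip in. After convergence the rows are
orthogonally projected onto the tangent plane at the consensus (toggleable
via `project_to_tangent`), because every downstream operation — means,
regressions, dot products — is linear and assumes an approximately
Euclidean space. Projection perturbs row centroid sizes at second order
(about 1e-4 to 1e-3 for realistic dispersions); the scaling step itself is
exact to 1e-10.

**Semilandmark sliding.** Sliding minimizes the thin-plate-spline bending
energy of each specimen's deviation from the consensus. The bending-energy
quadratic form is the upper-left k×k block of L⁻¹ with the standard 2D
kernel U(r) = r² log r²; it is symmetrized numerically and annihilates
affine fields by construction. Each pass solves, per specimen, the joint
linear system for all sliding amounts along tangent directions (the unit
vector between a semilandmark's two flanking curve points), rather than
relaxing one semilandmark at a time; GPA is re-run after every pass and
three passes are the default. Tangent-direction sliding (not full spline
relaxation) was chosen because the quantity being minimized is the bending
energy alone, and the tangent variant keeps points on (a linearization of)
their curves. The recorded energy history measures
each pass against the consensus that pass minimized toward; it is
non-increasing on all synthetic data we generate, and the suite asserts
this. Sliding is against the grand consensus by default; a per-population
reference would require resolving what "the" reference shape is for
cross-population comparisons and is deliberately not implemented.

**Symmetrization.** For a centred configuration A, let M be the operator
that negates x and swaps each bilateral pair's labels. We rotate M(A)
optimally onto A (angle γ) and average: B = (A + M(A)·R_γ)/2. Because M is
an involution and conjugating a rotation by a reflection inverts it,
M(B) = B·R_γ⁻¹ *exactly*; rotating B by −γ/2 therefore yields an exact
fixed point of M. This constructive step is why symmetrized output
satisfies mirror equality to machine precision (~1e-16) rather than merely
to optimization tolerance, and why symmetrization is exactly idempotent.
Rows are rescaled to unit centroid size after averaging.

**Outlier screening.** Specimens whose Procrustes distance to the
consensus exceeds Q3 + 1.5·IQR of the distance distribution are flagged
(multiplier configurable). This mirrors routine digitization-error
screening; flagged ids are reported, never dropped automatically.

**Repeatability.** With r replicate digitizations of each of n
individuals, the total Procrustes sum of squares is partitioned by
individual; σ²_between = (MS_between − MS_within)/r clipped at zero, and
repeatability is the ICC σ²_b/(σ²_b + σ²_w). Identical replicates give
exactly 1. On a simulated 9:1 variance ratio at 200×2 the estimate is
0.90 ± 0.02.

## Dimorphism scoring and decomposition

`sexscore(A) = A·(MM − FM)` is the raw dot product — deliberately not
normalized by ‖v₁‖, so scores are in squared Procrustes units and only
comparable within one fixed sex vector. Female scores are multiplied by −1
(guarded against double application) so higher always means more
sex-typical. The height regression is per-coordinate simple OLS with the
covariate mean-centred within scope, keeping fitted values on shape scale;
missing heights exclude a row from the decomposition but not from
superimposition. Cosines are clipped to [−1, 1] before arccos.

Scope matters and is explicit: `per-population` (default) computes means,
regressions, vectors and angles within each population; `global` pools.
The height regression pools the sexes within scope. Pooling has a
quantifiable consequence used throughout the tests: if shape =
±d/2 + (h − h̄)·b + noise with a sex height gap Δh and within-sex height SD
σ_h, then the expected pooled regression vector is

    E[v₂] = b + λ·d,   λ = (Δh/4) / (σ_h² + Δh²/4),

the expected sex vector is E[v₁] = d + Δh·b, and the residual sex vector
is E[v₃] = (1 − λΔh)·d. These closed forms are the oracles for the
recovery tests: at 8 populations × 200/sex with σ = 0.005, ‖d‖ = 0.03, the
estimated α lands within about 1° of angle(E[v₁], E[v₂]), per-population
‖v₁‖ within a few percent, and ν collapses toward 0 as b → 0. They also
explain why a *sex-blind* size regression partially absorbs the sex
difference itself — the reason the non-allometric vector v₃ is shorter
than v₁.

Trajectory analysis compares per-population sex vectors in magnitude
(|‖v₁ₚ‖ − ‖v₁_q‖|) and direction (pairwise angle), with nulls from
permuting individuals across populations within sex, holding every
population × sex cell count fixed.

## Resampling inference

Procrustes variance (disparity) uses denominator n (switchable to n−1),
with an option to take deviations from sex-specific means within group —
the "without sex variation" variant. Pairwise tests permute group labels
(default 9,999 permutations) two-sided on absolute differences. The
regional median-distance contrast averages per-population
|median(male) − median(female)| of pre-inversion scores within a focal
region and subtracts it from the average elsewhere; it is tested one-sided
against the population-randomization null. All permutation p-values use
the add-one convention p = (#{null ≥ obs} + 1)/(n_perm + 1); with a
continuous statistic this makes the randomization and trajectory tests
exact under exchangeability, and the suite verifies empirical type-I error
of 0.05 ± 0.02 over 200 null datasets at n_perm = 499.

The split-sample test halves every population at random (both sexes
required in each half, with a retry cap), evaluates a pluggable scalar
statistic (the allometric angle α by default) on each half, and compares
the mean absolute difference between halves of the same population with
that between halves of different populations. The reported p is the
proportion of replicates in which within ≥ between. The exact comparison
rule between the two difference distributions admits several readings; the
proportion rule was chosen because it needs no distributional assumption,
sits near 0.5 under the null (verified), and goes to 1/(n+1) under strong
heterogeneity.

## Preference models

Ratings are standardized (mean 0, sample SD 1 — the n−1 convention, stated
because "SD" alone is ambiguous) within population, which removes rating-
scale differences between samples. The mixed model is
`rating ~ score × sex` with females as the reference category and
correlated random intercepts and slopes by population, fitted by REML via
statsmodels MixedLM. If the 2×2 random-effects covariance is singular the
model refits with independent random effects and flags it; with a single
population random effects are inestimable and the fit falls back to OLS on
the same fixed-effect structure (flagged in `method`). Reported degrees of
freedom are the residual approximation n_obs − n_fixed; statsmodels
provides no Satterthwaite correction, so p-values for small numbers of
populations should be read cautiously — estimates and standard errors are
the contract, and the recovery test checks truth-within-2-SE coverage.

The Bayesian population-level regression uses N(0, prior_sd = 1) priors on
the standardized intercept and slope and N(0, 1) on the log noise scale
(so the no-data posterior is proper in all coordinates), finds the MAP by
BFGS with an analytic gradient, and approximates the posterior by a
Gaussian with covariance the inverse numerical Hessian. The 89% interval
is MAP ± 1.5932·SD; compatibility corridors draw 1,000 coefficient vectors
from the Gaussian (seeded). With the noise scale fixed the log posterior
is exactly quadratic and the approximation matches dense grid integration
to ~1e-6; the unknown-σ case agrees with the grid to well under 2%.

## Synthetic data generator

The generator is the study-conditions definition, not a tuning knob.
Defaults: a stylized 20-landmark bilateral face (4 midline points, 8
bilateral pairs, 6 semilandmarks on the two outline curves), 8 populations
× 100 faces per sex, sex-difference vectors of norm 0.03 Procrustes units,
allometric vectors of norm 8×10⁻⁴ per cm (≈ 0.019 units across ±2 SD of
height), population mean offsets of norm 0.01, isotropic landmark noise SD
0.005, female/male heights N(165, 6²)/N(178, 6²) cm, attractiveness =
0.2·z(typicality) + N(0, 1) for women raters' targets and 0.0 slope for
men. The noise and effect norms were set so that group separations,
disparities and angle estimates occupy the same working range as published
facial-landmark analyses (sex vectors a few times the mean-estimate noise
at n ≈ 100–200 per cell); the height and slope values are ordinary human
anthropometrics and a moderate preference effect.

Effect vectors are drawn isotropically, symmetrized (so bilateral
symmetrization cannot erase them), projected out of the similarity
directions at the base shape (translations, rotation, scaling — which GPA
quotients away), and rescaled to their target norm. The sex effect enters
as ±d/2 about the population mean so MM − FM = d in expectation; allometry
is centred on the population's expected pooled height mean. Attractiveness
uses the *sex-typicality* score (raw projection, female-inverted) so the
generative slopes live on the same scale the preference model estimates.
Each specimen is written under a random rotation/translation/scale.
Optional features: duplicate digitizations with independent landmark noise
(sharing an `individual` label), a focal-length artifact proportional to
log focal length, and body weight derived from height.

What the generator does **not** emulate: correlated (non-isotropic)
landmark noise, curved shape-space effects at large dispersions,
non-Gaussian trait distributions, rater-level structure in attractiveness
(ratings are already face-level averages), and real facial integration
patterns. Passing tests therefore demonstrate correctness of the
estimators under the stated linear-Gaussian model, not robustness to every
property of real face data.

## Problem sizes and determinism

The test suite runs the full property checks at desk scale — e.g. 8 × 400
faces for decomposition recovery, 200 simulated datasets × 499
permutations for calibration, 100 mixed-model fits for slope recovery —
sizes chosen so the whole suite completes in a few minutes while keeping
Monte-Carlo error well inside the asserted bands. Every stochastic
routine takes an explicit seed (`numpy.random.default_rng`), permutation
machinery is bit-reproducible given (seed, n_perm), and a pipeline rerun
with the same config produces byte-identical summary output.

## Known limitations

2D landmarks only; no 3D superimposition. Sliding linearizes curves at
their tangents and can drift for very sparse curves or very large
deviations. The ICC assumes balanced replicates (an unbalanced design uses
the mean replicate count). MixedLM df are approximate (see above). The
quadratic approximation is a Laplace approximation — adequate for the
near-Gaussian posteriors of standardized linear regressions, not for
multimodal ones.
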