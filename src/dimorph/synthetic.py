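"""Synthetic multi-population landmark datasets with known ground truth.

Emulates the generative structure that the sexual-shape-dimorphism analyses
assume: a bilaterally symmetric base face; per-population mean offsets; a sex
difference applied as +/- d/2 about the population mean (so MM - FM = d in
expectation); a height-driven allometric vector b centred on the pooled
population height mean (so the shape-on-height regression recovers b without
sex-mean confounding); isotropic Gaussian landmark noise in the tangent
frame; optional replicate digitizations; an optional focal-length shape
artifact; and attractiveness ratings generated as a linear function of the
standardized true sexscore with sex-specific slopes.

Each specimen is written under an arbitrary random rotation, translation and
scale, so superimposition has real work to do.  The same seed produces
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    IndividualMetadata,
    LandmarkConfiguration,
    LandmarkTemplate,
    write_metadata,
    write_tps,
)
from .superimpose import centroid_size

__all__ = [
    "PopulationSpec",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_template_face",
    "structured_vector",
    "generate_dataset",
    "default_spec",
]

# stylized face layout: 4 midline points, 8 bilateral pairs (left x < 0),
# two facial-outline curves carrying 3 semilandmarks per side
_FACE_POINTS = np.array(
    [
        (0.00, 0.90),   # 0 forehead (midline)
        (0.00, 0.10),   # 1 nose tip (midline)
        (0.00, -0.35),  # 2 mouth centre (midline)
        (0.00, -0.85),  # 3 chin (midline)
        (-0.35, 0.55), (0.35, 0.55),    # 4,5 brows
        (-0.45, 0.35), (0.45, 0.35),    # 6,7 eye outer corners
        (-0.18, 0.35), (0.18, 0.35),    # 8,9 eye inner corners
        (-0.15, 0.00), (0.15, 0.00),    # 10,11 nose wings
        (-0.25, -0.35), (0.25, -0.35),  # 12,13 mouth corners
        (-0.55, 0.55), (0.55, 0.55),    # 14,15 temples (semilandmarks)
        (-0.60, 0.00), (0.60, 0.00),    # 16,17 cheeks (semilandmarks)
        (-0.42, -0.50), (0.42, -0.50),  # 18,19 jaw points (semilandmarks)
    ]
)

_PAIRS = ((4, 5), (6, 7), (8, 9), (10, 11), (12, 13), (14, 15), (16, 17),
          (18, 19))
_MIDLINE = (0, 1, 2, 3)
_CURVES = ((0, 14, 16, 18, 3), (0, 15, 17, 19, 3))
_SEMI = (14, 15, 16, 17, 18, 19)


def generate_template_face(k: int = 20) -> tuple[LandmarkTemplate, np.ndarray]:
    """Stylized bilateral face template with its base mean shape.

    The default (and only) layout has k = 20 landmarks: 4 midline points,
    8 bilateral pairs, and 6 semilandmarks on the two facial-outline curves.
    The base shape is exactly bilaterally symmetric, centred, and scaled to
    unit centroid size.
    """
    if k != 20:
        raise ValueError(
            "the stylized face template is defined for k = 20 "
            "(4 midline + 8 bilateral pairs)"
        )
    template = LandmarkTemplate(
        n_landmarks=20,
        semilandmark_indices=_SEMI,
        curves=_CURVES,
        bilateral_pairs=_PAIRS,
        midline_indices=_MIDLINE,
    )
    base = _FACE_POINTS - _FACE_POINTS.mean(axis=0)
    base = base / centroid_size(base)
    return template, base


def _mirror_relabel(pts: np.ndarray, template: LandmarkTemplate) -> np.ndarray:
    out = pts.copy()
    out[:, 0] *= -1
    for a, b in template.bilateral_pairs:
        out[[a, b]] = out[[b, a]]
    return out


def structured_vector(
    rng: np.random.Generator,
    base: np.ndarray,
    template: LandmarkTemplate,
    norm: float,
    symmetric: bool = True,
) -> np.ndarray:
    """Random effect vector in the tangent space of the base shape.

    Draws an isotropic Gaussian displacement field, optionally symmetrizes
    it (average with its mirror-relabelled image, so bilateral
    symmetrization does not erase the effect), removes the similarity
    components (translations, rotation and scaling at the base shape, which
    superimposition would quotient out), and rescales to the requested norm.
    Returned flat, order (x1, y1, x2, y2, ...).
    """
    k = base.shape[0]
    v = rng.standard_normal((k, 2))
    if symmetric:
        v = (v + _mirror_relabel(v, template)) / 2
    flat = v.reshape(-1)
    # orthonormal basis of the similarity directions at the base shape
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-base[:, 1], base[:, 0]]).reshape(-1)
    sc = base.reshape(-1)
    Q, _ = np.linalg.qr(np.column_stack([tx, ty, rot, sc]))
    flat = flat - Q @ (Q.T @ flat)
    n = np.linalg.norm(flat)
    if n == 0:
        raise RuntimeError("degenerate structured vector draw")
    return flat * (norm / n)


@dataclass
class PopulationSpec:
    """Generative parameters of one population."""

    name: str
    n_per_sex: int
    mean_offset: np.ndarray
    sex_effect: np.ndarray       # d: male mean minus female mean, flat 2k
    allometric_vector: np.ndarray  # b: shape change per cm of height, flat 2k
    height_mean_f: float = 165.0
    height_mean_m: float = 178.0
    height_sd: float = 6.0


@dataclass
class SyntheticSpec:
    """Full generative parameterization of a synthetic landmark study."""

    populations: list[PopulationSpec]
    shape_noise_sd: float = 0.005
    replicate_noise_sd: float | None = None
    attractiveness_slope_women: float = 0.2
    attractiveness_slope_men: float = 0.0
    attractiveness_noise_sd: float = 1.0
    focal_effect: np.ndarray | None = None
    focal_length_choices: tuple[float, ...] = (50.0, 85.0, 105.0)
    with_weight: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_noise_sd < 0:
            raise ValueError("shape_noise_sd must be >= 0")
        if self.replicate_noise_sd is not None and self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth behind it."""

    configs: list[LandmarkConfiguration]
    metadata: list[IndividualMetadata]
    template: LandmarkTemplate
    base_shape: np.ndarray
    individual: np.ndarray = field(repr=False)
    true_shapes: np.ndarray = field(repr=False)
    true_scores: np.ndarray = field(repr=False)
    truth: dict = field(repr=False, default_factory=dict)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write TPS landmarks + CSV metadata + JSON truth record."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "tps": directory / "landmarks.tps",
            "metadata": directory / "metadata.csv",
            "truth": directory / "truth.json",
            "template": directory / "template.yaml",
        }
        write_tps(self.configs, paths["tps"])
        write_metadata(self.metadata, paths["metadata"])
        from .io import write_template

        write_template(self.template, paths["template"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        return paths


def default_spec(
    seed: int = 0,
    n_populations: int = 8,
    n_per_sex: int = 100,
    sex_effect_norm: float = 0.03,
    allometric_norm_per_cm: float = 0.0008,
    mean_offset_norm: float = 0.01,
    shape_noise_sd: float = 0.005,
    shared_sex_effect: bool = False,
    sex_effect_norms: list[float] | None = None,
    **kwargs,
) -> SyntheticSpec:
    """Study-like default parameterization.

    Eight populations of 100 faces per sex; sex-difference vectors of norm
    0.03 Procrustes units (population-specific directions unless
    ``shared_sex_effect``); allometric vectors of norm 8e-4 per cm (about
    0.019 shape units across a +/- 2 SD height range); population mean
    offsets of norm 0.01; isotropic landmark noise SD 0.005; female/male
    height means 165/178 cm with SD 6.  ``sex_effect_norms`` overrides the
    per-population sex-effect magnitudes (e.g. to give one region half the
    dimorphism of the rest).
    """
    template, base = generate_template_face()
    rng = np.random.default_rng(seed)
    shared_d = structured_vector(rng, base, template, sex_effect_norm)
    pops = []
    for i in range(n_populations):
        if sex_effect_norms is not None:
            d = structured_vector(rng, base, template, sex_effect_norms[i])
        elif shared_sex_effect:
            d = shared_d.copy()
        else:
            d = structured_vector(rng, base, template, sex_effect_norm)
        b = structured_vector(rng, base, template, allometric_norm_per_cm)
        off = structured_vector(rng, base, template, mean_offset_norm)
        pops.append(
            PopulationSpec(
                name=f"P{i + 1}",
                n_per_sex=n_per_sex,
                mean_offset=off,
                sex_effect=d,
                allometric_vector=b,
            )
        )
    return SyntheticSpec(
        populations=pops, shape_noise_sd=shape_noise_sd, seed=seed, **kwargs
    )


def _random_similarity(rng: np.random.Generator, pts: np.ndarray) -> np.ndarray:
    """Apply a random rotation, scale and translation (image units)."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    scale = rng.uniform(80.0, 160.0)
    shift = rng.uniform(200.0, 800.0, size=2)
    return pts @ R.T * scale + shift


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a multi-population landmark dataset from ``spec``.

    Individual i of sex s in population p receives the true shape

        base + offset_p + (+1 if male else -1) * d_p / 2
             + (height_i - pooled height mean_p) * b_p + noise,

    with heights drawn from sex-specific normals and the allometric term
    centred on the population's expected pooled height mean.  Attractiveness
    is ``slope_sex * z + noise`` where z is the true sex-typicality score
    (the raw sexscore, female-inverted) standardized within population.  Each written configuration carries an
    arbitrary random rotation/translation/scale.  Optional replicates add
    independent digitization noise and share an ``individual`` label.
    """
    template, base = generate_template_face()
    rng = np.random.default_rng(spec.seed)
    k = base.shape[0]

    configs: list[LandmarkConfiguration] = []
    metadata: list[IndividualMetadata] = []
    individual: list[str] = []
    true_shapes: list[np.ndarray] = []
    true_scores: list[float] = []
    truth_pops = {}

    for pop in spec.populations:
        h_center = (pop.height_mean_f + pop.height_mean_m) / 2
        d = np.asarray(pop.sex_effect, dtype=float)
        b = np.asarray(pop.allometric_vector, dtype=float)
        off = np.asarray(pop.mean_offset, dtype=float)
        truth_pops[pop.name] = {
            "sex_effect": d.tolist(),
            "sex_effect_norm": float(np.linalg.norm(d)),
            "allometric_vector": b.tolist(),
            "allometric_norm_per_cm": float(np.linalg.norm(b)),
            "mean_offset": off.tolist(),
            "height_center": h_center,
        }
        pop_scores = []
        pop_rows = []
        for sex, sign, h_mean in (
            ("female", -1.0, pop.height_mean_f),
            ("male", +1.0, pop.height_mean_m),
        ):
            for j in range(pop.n_per_sex):
                uid = f"{pop.name}_{sex[0]}{j + 1:03d}"
                height = rng.normal(h_mean, pop.height_sd)
                shape = (
                    base.reshape(-1)
                    + off
                    + sign * d / 2
                    + (height - h_center) * b
                    + rng.normal(0, spec.shape_noise_sd, 2 * k)
                )
                focal = None
                if spec.focal_effect is not None:
                    focal = float(rng.choice(spec.focal_length_choices))
                    ref = float(np.median(spec.focal_length_choices))
                    shape = shape + np.log(focal / ref) * np.asarray(
                        spec.focal_effect, dtype=float
                    )
                weight = None
                if spec.with_weight:
                    weight = 22.0 * (height / 100.0) ** 2 + rng.normal(0, 2.0)
                # sex-typicality score: raw projection, female-inverted, so
                # attractiveness rewards masculinity in men / femininity in
                # women — the scale the preference model consumes
                score = float(shape @ d)
                pop_scores.append(score * sign)
                pop_rows.append(
                    (uid, sex, height, weight, focal, shape)
                )
        z = np.asarray(pop_scores)
        z = (z - z.mean()) / z.std(ddof=1) if z.std(ddof=1) > 0 else z * 0
        for (uid, sex, height, weight, focal, shape), zi in zip(pop_rows, z):
            slope = (
                spec.attractiveness_slope_men
                if sex == "male"
                else spec.attractiveness_slope_women
            )
            attract = slope * float(zi) + rng.normal(
                0, spec.attractiveness_noise_sd
            )
            pts = shape.reshape(k, 2)
            n_rep = 2 if spec.replicate_noise_sd is not None else 1
            for r in range(1, n_rep + 1):
                obs = pts
                cid = uid
                if spec.replicate_noise_sd is not None:
                    obs = pts + rng.normal(0, spec.replicate_noise_sd,
                                           (k, 2))
                    cid = f"{uid}.{r}"
                configs.append(
                    LandmarkConfiguration(
                        id=cid, points=_random_similarity(rng, obs)
                    )
                )
                metadata.append(
                    IndividualMetadata(
                        id=cid, sex=sex, population=pop.name, height=height,
                        weight=weight, focal_length=focal,
                        attractiveness=attract,
                    )
                )
                individual.append(uid)
                true_shapes.append(shape)
                true_scores.append(float(shape @ d))

    truth = {
        "seed": spec.seed,
        "shape_noise_sd": spec.shape_noise_sd,
        "replicate_noise_sd": spec.replicate_noise_sd,
        "attractiveness": {
            "slope_women": spec.attractiveness_slope_women,
            "slope_men": spec.attractiveness_slope_men,
            "noise_sd": spec.attractiveness_noise_sd,
        },
        "populations": truth_pops,
        "true_scores": {c.id: s for c, s in zip(configs, true_scores)},
    }
    return SyntheticDataset(
        configs=configs,
        metadata=metadata,
        template=template,
        base_shape=base,
        individual=np.asarray(individual),
        true_shapes=np.asarray(true_shapes),
        true_scores=np.asarray(true_scores),
        truth=truth,
    )
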