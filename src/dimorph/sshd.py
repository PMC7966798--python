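"""Sexual shape dimorphism: projection scores, decomposition, trajectories.

The degree of sexual shape dimorphism (SShD) of an individual face is scored
by projecting its aligned shape vector A onto the axis joining the female
mean (FM) and male mean (MM) shapes:

    sexscore(A) = A . (MM - FM)

The dot product is deliberately *not* normalized by ||MM - FM||; scores are
in squared Procrustes units and comparable only within a fixed sex vector.

Overall SShD decomposes into an allometric part (the component predictable
from body height via per-coordinate regression of shape on height) and a
non-allometric part (the residual shape projected on the sex-difference
vector of the residuals).  The angles alpha = angle(v1, v2) and
nu = angle(v1, v3) quantify how much of the dimorphism axis is aligned with
allometry, where v1 = MM - FM, v2 is the vector of shape-on-height
regression coefficients, and v3 = MM_res - FM_res.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimpose import AlignedDataset

__all__ = [
    "SexDifferenceVector",
    "SShDResult",
    "TrajectoryResult",
    "sex_difference_vector",
    "sexscore",
    "invert_female_scores",
    "regress_shape_on_covariate",
    "allometric_decomposition",
    "angle_between",
    "trajectory_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class SexDifferenceVector:
    """The male-mean minus female-mean axis in aligned shape space."""

    v1: np.ndarray
    MM: np.ndarray
    FM: np.ndarray
    scope: str = "global"
    population: str | None = None

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.v1))


def _sex_masks(sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sex = np.asarray(sex)
    return sex == "female", sex == "male"


def sex_difference_vector(
    shapes: np.ndarray,
    sex: np.ndarray,
    scope: str = "global",
    population: str | None = None,
) -> SexDifferenceVector:
    """Arithmetic male and female mean shapes and their difference v1 = MM - FM."""
    shapes = np.asarray(shapes, dtype=float)
    f, m = _sex_masks(sex)
    if not f.any() or not m.any():
        raise ValueError(
            f"both sexes required in scope "
            f"{population if population else scope!r}"
        )
    MM = shapes[m].mean(axis=0)
    FM = shapes[f].mean(axis=0)
    return SexDifferenceVector(v1=MM - FM, MM=MM, FM=FM, scope=scope,
                               population=population)


def sexscore(A: np.ndarray, v: SexDifferenceVector | np.ndarray) -> np.ndarray:
    """Project shape vector(s) onto the sex-difference axis: A . (MM - FM).

    Accepts a single flat shape vector or an (n, 2k) matrix.  Raw,
    un-normalized dot product, so sexscore(MM) - sexscore(FM) = ||v1||^2.
    """
    v1 = v.v1 if isinstance(v, SexDifferenceVector) else np.asarray(v, dtype=float)
    if not np.linalg.norm(v1) > 0:
        raise ValueError("degenerate sex vector (zero norm): cannot project")
    return np.asarray(A, dtype=float) @ v1


def invert_female_scores(scores: np.ndarray, sex: np.ndarray,
                         already_inverted: bool = False) -> np.ndarray:
    """Multiply female scores by -1 so higher = more sex-typical for both sexes.

    Guarded against double application via the ``already_inverted`` flag that
    callers must thread through.
    """
    if already_inverted:
        raise ValueError("scores already inverted: refusing double inversion")
    scores = np.asarray(scores, dtype=float).copy()
    f, _ = _sex_masks(sex)
    scores[f] *= -1
    return scores


def regress_shape_on_covariate(
    shapes: np.ndarray,
    covariate: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-coordinate simple regression of shape on one covariate.

    The covariate is mean-centred, so fitted values stay on shape scale and
    the intercept of every coordinate equals its mean.  Returns
    ``(fitted, residuals, coefficients)`` with ``fitted + residuals ==
    shapes`` exactly; the coefficient vector is v2 when the covariate is
    body height (shape change per unit height).

    Rows with missing covariate must be excluded by the caller beforehand;
    a constant covariate raises ``ValueError``.
    """
    X = np.asarray(shapes, dtype=float)
    h = np.asarray(covariate, dtype=float)
    if np.any(~np.isfinite(h)):
        raise ValueError("covariate contains missing values; exclude rows first")
    hc = h - h.mean()
    ss = float(hc @ hc)
    if ss == 0:
        raise ValueError("constant covariate: regression undefined")
    coef = (hc @ (X - X.mean(axis=0))) / ss
    fitted = X.mean(axis=0) + np.outer(hc, coef)
    residuals = X - fitted
    return fitted, residuals, coef


def angle_between(v: np.ndarray, w: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    arccos of the cosine (dot product over the product of norms), clipped to
    [-1, 1] before arccos to guard rounding.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("angle undefined for a zero vector")
    c = np.clip(v @ w / (nv * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class SShDResult:
    """Per-individual SShD scores and the vectors/angles behind them.

    Scores are on the raw squared-Procrustes-unit scale of the dot product;
    after ``female_inverted`` is set, higher values mean more masculine male
    faces and more feminine female faces.
    """

    scores_overall: np.ndarray
    scores_allometric: np.ndarray
    scores_nonallometric: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    alpha_deg: float
    nu_deg: float
    female_inverted: bool
    ids: np.ndarray
    sex: np.ndarray
    population: np.ndarray
    scope: str
    per_population: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "population": self.population,
                "sex": self.sex,
                "score_overall": self.scores_overall,
                "score_allometric": self.scores_allometric,
                "score_nonallometric": self.scores_nonallometric,
            }
        )

    def angles_summary(self) -> dict:
        return {
            "alpha_deg": self.alpha_deg,
            "nu_deg": self.nu_deg,
            "v1_norm": float(np.linalg.norm(self.v1)),
            "v2_norm": float(np.linalg.norm(self.v2)),
            "v3_norm": float(np.linalg.norm(self.v3)),
            "scope": self.scope,
            "female_inverted": self.female_inverted,
        }


def _decompose_block(
    shapes: np.ndarray, heights: np.ndarray, sex: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Decomposition within one scope (global or one population)."""
    sdv = sex_difference_vector(shapes, sex)
    overall = sexscore(shapes, sdv)
    fitted, residuals, v2 = regress_shape_on_covariate(shapes, heights)
    allometric = sexscore(fitted, sdv)
    sdv_res = sex_difference_vector(residuals, sex)
    v3 = sdv_res.v1
    nonallo = residuals @ v3
    alpha = angle_between(sdv.v1, v2) if np.linalg.norm(v2) > 0 else np.nan
    nu = angle_between(sdv.v1, v3) if np.linalg.norm(v3) > 0 else np.nan
    return overall, allometric, nonallo, sdv.v1, v2, v3, alpha, nu


def allometric_decomposition(
    aligned: AlignedDataset,
    scope: str = "per-population",
    invert_female: bool = True,
) -> SShDResult:
    """Decompose SShD into allometric and non-allometric components.

    Overall scores project the raw aligned rows on v1 = MM - FM; allometric
    scores project the fitted values of the shape-on-height regression on the
    same v1; non-allometric scores project the regression residuals on
    v3 = MM_res - FM_res, the sex-difference vector of the residuals.
    alpha = angle(v1, v2) and nu = angle(v1, v3).

    ``scope='per-population'`` (default) computes means, regressions and
    vectors within each population separately, matching per-sample analyses;
    ``scope='global'`` pools everything.  Rows with missing height are
    excluded (with a logged count); the shape data itself is untouched.
    With per-population scope the scalar ``alpha_deg``/``nu_deg`` are the
    unweighted means of the per-population angles, and the stored v1/v2/v3
    are the unweighted means of the per-population vectors.
    """
    heights = aligned.meta["height"].to_numpy(dtype=float)
    ok = np.isfinite(heights)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("allometric_decomposition: excluded %d rows with missing "
                    "height", n_dropped)
    shapes = aligned.shapes[ok]
    sex = aligned.meta["sex"].to_numpy()[ok]
    pop = aligned.meta["population"].to_numpy()[ok]
    ids = aligned.meta["id"].to_numpy()[ok]
    h = heights[ok]

    n = shapes.shape[0]
    overall = np.empty(n)
    allom = np.empty(n)
    nonallo = np.empty(n)
    per_population = None
    if scope == "global":
        overall, allom, nonallo, v1, v2, v3, alpha, nu = _decompose_block(
            shapes, h, sex
        )
    elif scope == "per-population":
        v1s, v2s, v3s, rows = [], [], [], []
        for p in np.unique(pop):
            mask = pop == p
            o, a, na, v1_p, v2_p, v3_p, al, nu_p = _decompose_block(
                shapes[mask], h[mask], sex[mask]
            )
            overall[mask], allom[mask], nonallo[mask] = o, a, na
            v1s.append(v1_p)
            v2s.append(v2_p)
            v3s.append(v3_p)
            rows.append(
                {
                    "population": p,
                    "n": int(mask.sum()),
                    "v1_norm": float(np.linalg.norm(v1_p)),
                    "v2_norm": float(np.linalg.norm(v2_p)),
                    "v3_norm": float(np.linalg.norm(v3_p)),
                    "alpha_deg": al,
                    "nu_deg": nu_p,
                }
            )
        per_population = pd.DataFrame(rows)
        v1 = np.mean(v1s, axis=0)
        v2 = np.mean(v2s, axis=0)
        v3 = np.mean(v3s, axis=0)
        alpha = float(np.nanmean(per_population["alpha_deg"]))
        nu = float(np.nanmean(per_population["nu_deg"]))
    else:
        raise ValueError(f"unknown scope {scope!r}")

    if invert_female:
        overall = invert_female_scores(overall, sex)
        allom = invert_female_scores(allom, sex)
        nonallo = invert_female_scores(nonallo, sex)
    return SShDResult(
        scores_overall=overall,
        scores_allometric=allom,
        scores_nonallometric=nonallo,
        v1=v1, v2=v2, v3=v3,
        alpha_deg=float(alpha), nu_deg=float(nu),
        female_inverted=invert_female,
        ids=ids, sex=sex, population=pop, scope=scope,
        per_population=per_population,
    )


@dataclass
class TrajectoryResult:
    """Magnitude and direction comparison of per-population sex vectors."""

    populations: list[str]
    magnitudes: np.ndarray
    magnitude_diff: np.ndarray
    angles_deg: np.ndarray
    p_magnitude: np.ndarray
    p_angle: np.ndarray
    n_perm: int
    seed: int

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = self.populations
        return {
            "magnitudes": pd.DataFrame(
                {"population": idx, "magnitude": self.magnitudes}
            ),
            "magnitude_diff": pd.DataFrame(self.magnitude_diff, index=idx,
                                           columns=idx),
            "angles_deg": pd.DataFrame(self.angles_deg, index=idx, columns=idx),
            "p_magnitude": pd.DataFrame(self.p_magnitude, index=idx,
                                        columns=idx),
            "p_angle": pd.DataFrame(self.p_angle, index=idx, columns=idx),
        }


def _pairwise_traj_stats(
    shapes: np.ndarray, f_mask: np.ndarray, pop_codes: np.ndarray, n_pop: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population sex vectors -> magnitudes, |mag diff|, pairwise angles."""
    d = shapes.shape[1]
    vecs = np.empty((n_pop, d))
    for g in range(n_pop):
        in_pop = pop_codes == g
        MM = shapes[in_pop & ~f_mask].mean(axis=0)
        FM = shapes[in_pop & f_mask].mean(axis=0)
        vecs[g] = MM - FM
    mags = np.linalg.norm(vecs, axis=1)
    mag_diff = np.abs(mags[:, None] - mags[None, :])
    cos = (vecs @ vecs.T) / np.outer(mags, mags)
    angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    np.fill_diagonal(angles, 0.0)
    return mags, mag_diff, angles


def trajectory_analysis(
    aligned: AlignedDataset,
    n_perm: int = 999,
    seed: int | None = None,
) -> TrajectoryResult:
    """Compare sex-difference vectors across populations.

    For each population p, v1_p = MM_p - FM_p.  Observed statistics are the
    magnitudes ||v1_p||, pairwise absolute magnitude differences, and
    pairwise angles between vectors.  The null permutes individuals across
    populations *within sex* (holding every population x sex cell size
    fixed), recomputing both pairwise statistics; p-values use the add-one
    convention p = (#{null >= observed} + 1) / (n_perm + 1).

    Populations lacking a sex are excluded with a warning.
    """
    if seed is None:
        raise ValueError("seed is a required, logged parameter")
    sex = aligned.meta["sex"].to_numpy()
    pop = aligned.meta["population"].to_numpy()
    keep_pops = []
    for p in np.unique(pop):
        sx = set(sex[pop == p])
        if sx >= {"female", "male"}:
            keep_pops.append(p)
        else:
            logger.warning("trajectory_analysis: population %r lacks a sex; "
                           "excluded", p)
    if len(keep_pops) < 2:
        raise ValueError("need >= 2 populations with both sexes")
    keep = np.isin(pop, keep_pops)
    shapes = aligned.shapes[keep]
    sex = sex[keep]
    pop = pop[keep]
    pops = sorted(keep_pops)
    pop_codes = np.searchsorted(np.array(pops), pop)
    f_mask = sex == "female"
    n_pop = len(pops)

    mags, obs_mag_diff, obs_angles = _pairwise_traj_stats(
        shapes, f_mask, pop_codes, n_pop
    )

    rng = np.random.default_rng(seed)
    ge_mag = np.zeros((n_pop, n_pop))
    ge_ang = np.zeros((n_pop, n_pop))
    idx_f = np.flatnonzero(f_mask)
    idx_m = np.flatnonzero(~f_mask)
    perm_codes = pop_codes.copy()
    for _ in range(n_perm):
        perm_codes[idx_f] = pop_codes[idx_f[rng.permutation(len(idx_f))]]
        perm_codes[idx_m] = pop_codes[idx_m[rng.permutation(len(idx_m))]]
        _, md, ang = _pairwise_traj_stats(shapes, f_mask, perm_codes, n_pop)
        ge_mag += md >= obs_mag_diff
        ge_ang += ang >= obs_angles
    p_mag = (ge_mag + 1) / (n_perm + 1)
    p_ang = (ge_ang + 1) / (n_perm + 1)
    np.fill_diagonal(p_mag, 1.0)
    np.fill_diagonal(p_ang, 1.0)
    logger.info("trajectory_analysis: %d populations, n_perm=%d, seed=%d",
                n_pop, n_perm, seed)
    return TrajectoryResult(
        populations=pops,
        magnitudes=mags,
        magnitude_diff=obs_mag_diff,
        angles_deg=obs_angles,
        p_magnitude=p_mag,
        p_angle=p_ang,
        n_perm=n_perm,
        seed=seed,
    )
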