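"""Morphological disparity and permutation machinery.

Provides Procrustes-variance disparity with pairwise permutation tests, the
regional median-distance contrast of sexscore distributions, and two bespoke
resampling tests:

* a randomization test that reassigns populations at random to faces while
  holding each face's sex and every population's sex composition fixed, and
* a random split-sample test comparing average statistic differences between
  half-samples of the same population against half-samples of different
  populations.

All permutation machinery is seeded and bit-reproducible given
``(seed, n_perm)``; p-values use the add-one convention
``p = (#{null >= observed} + 1) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .superimpose import AlignedDataset

__all__ = [
    "DisparityResult",
    "PermutationResult",
    "morphological_disparity",
    "median_distance_statistic",
    "randomization_test",
    "split_sample_test",
    "pearson_correlation",
]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the add-one p-value."""

    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int
    statistic: str
    null_draws: np.ndarray | None = None

    def null_frame(self) -> pd.DataFrame:
        """Long-format null draws for audit output."""
        if self.null_draws is None:
            raise ValueError("null draws were not retained")
        return pd.DataFrame(
            {"statistic": self.statistic, "draw": self.null_draws}
        )


@dataclass
class DisparityResult:
    """Per-group Procrustes variances with pairwise permutation tests."""

    groups: list[str]
    variances: np.ndarray
    pairwise_diff: np.ndarray
    pairwise_p: np.ndarray | None
    n_perm: int
    seed: int | None
    denominator: str = "n"

    def to_frames(self) -> dict[str, pd.DataFrame]:
        out = {
            "variances": pd.DataFrame(
                {"group": self.groups, "procrustes_variance": self.variances}
            ),
            "pairwise_diff": pd.DataFrame(
                self.pairwise_diff, index=self.groups, columns=self.groups
            ),
        }
        if self.pairwise_p is not None:
            out["pairwise_p"] = pd.DataFrame(
                self.pairwise_p, index=self.groups, columns=self.groups
            )
        return out


def _group_variances(
    X: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    sex_codes: np.ndarray | None,
    ddof0: bool,
) -> np.ndarray:
    """Procrustes variance per group; optionally around sex-specific means."""
    pv = np.empty(n_groups)
    for g in range(n_groups):
        mask = codes == g
        Xg = X[mask]
        if sex_codes is None:
            dev = Xg - Xg.mean(axis=0)
        else:
            sg = sex_codes[mask]
            dev = Xg.copy()
            for s in np.unique(sg):
                sm = sg == s
                dev[sm] -= Xg[sm].mean(axis=0)
        denom = Xg.shape[0] if ddof0 else Xg.shape[0] - 1
        pv[g] = np.sum(dev**2) / denom
    return pv


def morphological_disparity(
    aligned: AlignedDataset | np.ndarray,
    groups: np.ndarray | str = "population",
    partial_out_group_means: bool = False,
    sex: np.ndarray | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
    denominator: str = "n",
) -> DisparityResult:
    """Procrustes variance per group, with pairwise permutation tests.

    PV_g = sum_i ||s_i - mean_g||^2 / n_g (denominator ``n`` by default, the
    dominant morphometrics convention; ``n-1`` switchable).  With
    ``partial_out_group_means=True`` deviations are taken from sex-specific
    means within each group, removing sex variation from the disparity.

    Pairwise significance permutes group labels (``n_perm`` default 9999)
    and compares |PV_g - PV_h| two-sided on absolute differences.  Passing
    ``seed=None`` skips the permutation test.
    """
    if isinstance(aligned, AlignedDataset):
        X = aligned.shapes
        if isinstance(groups, str):
            groups = aligned.meta[groups].to_numpy()
        if partial_out_group_means and sex is None:
            sex = aligned.meta["sex"].to_numpy()
    else:
        X = np.asarray(aligned, dtype=float)
        groups = np.asarray(groups)
    if partial_out_group_means and sex is None:
        raise ValueError("partial_out_group_means requires sex labels")
    uniq, codes = np.unique(groups, return_inverse=True)
    counts = np.bincount(codes)
    if np.any(counts < 2):
        raise ValueError(
            f"groups of size < 2: {uniq[counts < 2].tolist()}"
        )
    sex_codes = None
    if partial_out_group_means:
        _, sex_codes = np.unique(np.asarray(sex), return_inverse=True)
    ddof0 = denominator == "n"
    pv = _group_variances(X, codes, len(uniq), sex_codes, ddof0)
    diff = np.abs(pv[:, None] - pv[None, :])

    pairwise_p = None
    if seed is not None and len(uniq) > 1:
        rng = np.random.default_rng(seed)
        ge = np.zeros_like(diff)
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            pvp = _group_variances(X, perm, len(uniq), sex_codes, ddof0)
            dp = np.abs(pvp[:, None] - pvp[None, :])
            ge += dp >= diff
        pairwise_p = (ge + 1) / (n_perm + 1)
        np.fill_diagonal(pairwise_p, 1.0)
    return DisparityResult(
        groups=[str(u) for u in uniq],
        variances=pv,
        pairwise_diff=diff,
        pairwise_p=pairwise_p,
        n_perm=n_perm if pairwise_p is not None else 0,
        seed=seed,
        denominator=denominator,
    )


def median_distance_statistic(
    scores: np.ndarray,
    sex: np.ndarray,
    population: np.ndarray,
    region_of: dict[str, str],
    focal_region: str,
) -> dict:
    """Regional contrast of per-population median sexscore separations.

    For each population, the separation is |median(male scores) -
    median(female scores)| of the (pre-inversion) overall sexscores.  The
    regional statistic averages separations over the region's populations;
    the contrast is mean(other regions) - mean(focal region) — positive when
    the focal region is *less* dimorphic.  Returns the observed quantities;
    feed the contrast through :func:`randomization_test` for significance.
    """
    scores = np.asarray(scores, dtype=float)
    sex = np.asarray(sex)
    population = np.asarray(population)
    per_pop = {}
    for p in np.unique(population):
        mask = population == p
        m = scores[mask & (sex == "male")]
        f = scores[mask & (sex == "female")]
        if len(m) == 0 or len(f) == 0:
            raise ValueError(f"population {p!r} lacks a sex")
        per_pop[str(p)] = abs(float(np.median(m)) - float(np.median(f)))
    focal = [d for p, d in per_pop.items() if region_of.get(p) == focal_region]
    other = [d for p, d in per_pop.items() if region_of.get(p) != focal_region]
    if not focal:
        raise ValueError(f"region {focal_region!r} has no populations")
    if not other:
        raise ValueError("no populations outside the focal region")
    return {
        "per_population": per_pop,
        "focal_mean": float(np.mean(focal)),
        "other_mean": float(np.mean(other)),
        "contrast": float(np.mean(other) - np.mean(focal)),
    }


def randomization_test(
    statistic: Callable[[np.ndarray], float],
    population: np.ndarray,
    sex: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    label: str = "statistic",
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation test with population labels randomized within sex.

    ``statistic`` receives a population-label array (first the observed one,
    then ``n_perm`` permuted versions) and returns a scalar.  Permutations
    shuffle population labels independently within each sex stratum, so each
    face keeps its sex and every population keeps its number of men and
    women.  One-sided: large observed values are extreme.
    """
    if seed is None:
        raise ValueError("seed is a required, logged parameter")
    population = np.asarray(population)
    sex = np.asarray(sex)
    observed = float(statistic(population))
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(sex == s) for s in np.unique(sex)]
    null = np.empty(n_perm)
    perm = population.copy()
    for i in range(n_perm):
        for idx in strata:
            perm[idx] = population[idx[rng.permutation(len(idx))]]
        try:
            null[i] = statistic(perm)
        except Exception as exc:  # noqa: BLE001 - annotate permutation index
            raise RuntimeError(
                f"statistic failed on permutation {i}: {exc}"
            ) from exc
    p = (int(np.sum(null >= observed)) + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        statistic=label,
        null_draws=null if keep_null else None,
    )


def _split_population(
    idx: np.ndarray,
    sex: np.ndarray,
    rng: np.random.Generator,
    require_both_sexes: bool,
    max_retries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split of one population's rows (halves differ by <= 1)."""
    n = len(idx)
    half = n // 2
    for _ in range(max_retries):
        perm = rng.permutation(idx)
        a, b = perm[:half], perm[half:]
        if not require_both_sexes:
            return a, b
        if (
            len(set(sex[a])) == 2
            and len(set(sex[b])) == 2
        ):
            return a, b
    raise RuntimeError(
        "could not split population with both sexes in each half after "
        f"{max_retries} retries; larger samples needed"
    )


def split_sample_test(
    statistic: Callable[[np.ndarray], float],
    population: np.ndarray,
    sex: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    label: str = "statistic",
    require_both_sexes: bool = True,
    keep_null: bool = False,
) -> PermutationResult:
    """Random split-sample test of between- vs within-population differences.

    In each of ``n_perm`` replicates every population is split into two
    random half-samples (each half containing both sexes; re-split up to a
    retry cap) and ``statistic`` is evaluated on each half's row indices.
    The replicate records the mean absolute statistic difference between
    half-samples of the same population (within) and between half-samples of
    different populations (between).

    The reported p-value is the proportion of replicates in which the
    within-population difference is at least the between-population
    difference (add-one convention) — small when populations genuinely
    differ, near 0.5 under the null.  ``observed`` is the mean
    between-minus-within gap over replicates.
    """
    if seed is None:
        raise ValueError("seed is a required, logged parameter")
    population = np.asarray(population)
    sex = np.asarray(sex)
    pops = np.unique(population)
    for p in pops:
        if np.sum(population == p) < 4:
            raise ValueError(f"population {p!r} smaller than 4: cannot split")
    rng = np.random.default_rng(seed)
    gaps = np.empty(n_perm)
    n_within_ge = 0
    for r in range(n_perm):
        stats_per_pop = []
        for p in pops:
            idx = np.flatnonzero(population == p)
            a, b = _split_population(idx, sex, rng, require_both_sexes)
            stats_per_pop.append((float(statistic(a)), float(statistic(b))))
        within = np.mean([abs(s1 - s2) for s1, s2 in stats_per_pop])
        between_vals = []
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                for si in stats_per_pop[i]:
                    for sj in stats_per_pop[j]:
                        between_vals.append(abs(si - sj))
        between = float(np.mean(between_vals))
        gaps[r] = between - within
        if within >= between:
            n_within_ge += 1
    p = (n_within_ge + 1) / (n_perm + 1)
    return PermutationResult(
        observed=float(gaps.mean()),
        null_mean=float(gaps.mean()),
        null_sd=float(gaps.std(ddof=1)),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        statistic=label,
        null_draws=gaps if keep_null else None,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_correlation needs n >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)
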