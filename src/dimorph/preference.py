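"""Attractiveness-preference models.

Relates average attractiveness ratings to sexual shape dimorphism scores:
per-population standardization of ratings, a linear mixed-effects model
``rating ~ SShD * sex`` with correlated random intercepts and slopes by
population (females as reference category), and a small Bayesian linear
regression fitted by quadratic (Laplace) approximation at the posterior mode
under weakly informative N(0, 1) priors on standardized coefficients, with
89% compatibility intervals and corridor sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PreferenceModelResult",
    "BayesRegressionResult",
    "standardize_ratings",
    "fit_attractiveness_lmm",
    "bayes_linear_quap",
]

# Gaussian quantile for the central 89% interval, z_{0.945}
Z89 = 1.5932


def standardize_ratings(ratings: np.ndarray, population: np.ndarray) -> np.ndarray:
    """Scale ratings to mean 0, SD 1 within each population.

    Sample SD (n-1 denominator).  Scale-free: any affine rescaling of the
    raw rating scale (7-point vs 0-10) yields identical output.
    """
    ratings = np.asarray(ratings, dtype=float)
    population = np.asarray(population)
    out = np.empty_like(ratings)
    for p in np.unique(population):
        mask = population == p
        vals = ratings[mask]
        if len(vals) < 2:
            raise ValueError(f"population {p!r} has < 2 rated faces")
        sd = np.std(vals, ddof=1)
        if sd == 0:
            raise ValueError(f"population {p!r} has zero rating SD")
        out[mask] = (vals - vals.mean()) / sd
    return out


@dataclass
class PreferenceModelResult:
    """Fixed effects and variance components of the attractiveness model.

    ``fixed_effects`` rows: intercept (women), SShD slope (women), change in
    intercept (men), change in slope (men); columns estimate, se, df, t, p.
    Degrees of freedom are the residual approximation n_obs - n_fixed
    (statsmodels provides no Satterthwaite df).
    """

    fixed_effects: pd.DataFrame
    random_effects_cov: pd.DataFrame | None
    converged: bool
    singular: bool
    method: str
    n_obs: int
    n_populations: int

    def to_frame(self) -> pd.DataFrame:
        return self.fixed_effects.reset_index(names="term")


_TERMS = {
    "Intercept": "intercept_women",
    "score": "slope_women",
    "male": "intercept_change_men",
    "score:male": "slope_change_men",
}


def _ols_interaction(df: pd.DataFrame) -> PreferenceModelResult:
    fit = smf.ols("rating ~ score * male", data=df).fit()
    fe = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "df": fit.df_resid,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).rename(index=_TERMS)
    return PreferenceModelResult(
        fixed_effects=fe,
        random_effects_cov=None,
        converged=True,
        singular=False,
        method="OLS (single population: random effects inestimable)",
        n_obs=len(df),
        n_populations=df["population"].nunique(),
    )


def fit_attractiveness_lmm(
    scores: np.ndarray,
    ratings: np.ndarray,
    sex: np.ndarray,
    population: np.ndarray,
) -> PreferenceModelResult:
    """Mixed model of attractiveness on SShD with sex interaction.

    Fits ``rating ~ score * sex`` (female = reference category) with
    correlated random intercepts and slopes by population, by REML.  With a
    single population the model collapses to OLS on the interaction terms
    (flagged in ``method``).  A singular random-effects covariance triggers a
    refit with independent (uncorrelated) random effects and sets the
    ``singular`` flag; the fixed-effect structure is unchanged.
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "rating": np.asarray(ratings, dtype=float),
            "male": (np.asarray(sex) == "male").astype(float),
            "population": np.asarray(population),
        }
    )
    if df[["score", "rating"]].isna().any().any():
        df = df.dropna(subset=["score", "rating"]).reset_index(drop=True)
    if df["male"].nunique() < 2:
        raise ValueError("both sexes required")
    if df["population"].nunique() < 2:
        return _ols_interaction(df)

    def _fit(free_structure: bool):
        model = smf.mixedlm(
            "rating ~ score * male",
            data=df,
            groups=df["population"],
            re_formula="~score",
        )
        kwargs = {}
        if not free_structure:
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            kwargs["free"] = MixedLMParams.from_components(
                fe_params=np.ones(4), cov_re=np.eye(2)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True, method=["lbfgs", "powell"], **kwargs)

    fit = _fit(free_structure=True)
    cov_re = np.asarray(fit.cov_re)
    singular = bool(
        not np.all(np.isfinite(fit.bse_fe))
        or np.linalg.eigvalsh(cov_re).min() < 1e-10
    )
    method = "MixedLM REML, correlated random intercept+slope by population"
    if singular:
        fit = _fit(free_structure=False)
        cov_re = np.asarray(fit.cov_re)
        method = (
            "MixedLM REML, independent random intercept+slope by population "
            "(correlated structure singular)"
        )
    params = fit.fe_params
    se = fit.bse_fe
    dof = len(df) - len(params)
    tvals = params / se
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)
    fe = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "df": float(dof),
            "t": tvals,
            "p": pvals,
        }
    ).rename(index=_TERMS)
    re_cov = pd.DataFrame(
        cov_re,
        index=["intercept", "slope"],
        columns=["intercept", "slope"],
    )
    return PreferenceModelResult(
        fixed_effects=fe,
        random_effects_cov=re_cov,
        converged=bool(fit.converged),
        singular=singular,
        method=method,
        n_obs=len(df),
        n_populations=df["population"].nunique(),
    )


@dataclass
class BayesRegressionResult:
    """Laplace-approximate posterior of a standardized linear regression."""

    names: list[str]
    map_estimate: np.ndarray
    posterior_sd: np.ndarray
    interval_89: np.ndarray  # (p, 2) lower/upper
    covariance: np.ndarray
    curvature: np.ndarray
    n: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.map_estimate,
                "sd": self.posterior_sd,
                "lo_89": self.interval_89[:, 0],
                "hi_89": self.interval_89[:, 1],
            },
            index=self.names,
        )

    def sample_corridor(
        self,
        grid: np.ndarray,
        n_draws: int = 1000,
        seed: int = 0,
    ) -> pd.DataFrame:
        """89% compatibility corridor of the regression line on ``grid``.

        Draws (intercept, slope) from the Gaussian posterior approximation
        and evaluates the line at each grid point.
        """
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            self.map_estimate[:2], self.covariance[:2, :2], size=n_draws
        )
        lines = draws[:, [0]] + draws[:, [1]] * grid[None, :]
        lo, hi = np.percentile(lines, [5.5, 94.5], axis=0)
        return pd.DataFrame(
            {"x": grid, "mean": lines.mean(axis=0), "lo_89": lo, "hi_89": hi}
        )


def bayes_linear_quap(
    x: np.ndarray,
    y: np.ndarray,
    prior_sd: float = 1.0,
    sigma: float | None = None,
) -> BayesRegressionResult:
    """Bayesian linear regression by quadratic approximation at the MAP.

    Model: y ~ Normal(a + b x, sigma), with weakly informative
    Normal(0, prior_sd) priors on the standardized intercept and slope and
    Normal(0, 1) on log sigma.  The posterior is approximated by a Gaussian
    centred at the MAP with covariance the inverse Hessian of the negative
    log posterior; the 89% compatibility interval is MAP +/- 1.5932 SD.

    With ``sigma`` given, the noise scale is held fixed and only (a, b) are
    estimated.  With no data the posterior equals the prior.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    fixed_sigma = sigma is not None

    def neg_log_post(theta: np.ndarray) -> float:
        a, b = theta[0], theta[1]
        s = sigma if fixed_sigma else float(np.exp(theta[2]))
        lp = (a**2 + b**2) / (2 * prior_sd**2)
        if not fixed_sigma:
            lp += theta[2] ** 2 / 2  # N(0,1) prior on log sigma
        if n:
            resid = y - a - b * x
            lp += n * np.log(s) + float(resid @ resid) / (2 * s**2)
        return lp

    def grad(theta: np.ndarray) -> np.ndarray:
        a, b = theta[0], theta[1]
        s = sigma if fixed_sigma else float(np.exp(theta[2]))
        g = np.empty(len(theta))
        g[0] = a / prior_sd**2
        g[1] = b / prior_sd**2
        if not fixed_sigma:
            g[2] = theta[2]
        if n:
            resid = y - a - b * x
            g[0] -= float(resid.sum()) / s**2
            g[1] -= float(resid @ x) / s**2
            if not fixed_sigma:
                g[2] += n - float(resid @ resid) / s**2
        return g

    p = 2 if fixed_sigma else 3
    res = optimize.minimize(neg_log_post, np.zeros(p), jac=grad,
                            method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 1000})
    if not res.success and np.linalg.norm(res.jac) > 1e-5:
        raise RuntimeError(
            f"quap optimizer did not converge (gradient norm "
            f"{np.linalg.norm(res.jac):.2e})"
        )
    theta = res.x
    # numerical Hessian by central differences
    eps = 1e-5
    H = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            ei = np.eye(p)[i] * eps
            ej = np.eye(p)[j] * eps
            H[i, j] = (
                neg_log_post(theta + ei + ej)
                - neg_log_post(theta + ei - ej)
                - neg_log_post(theta - ei + ej)
                + neg_log_post(theta - ei - ej)
            ) / (4 * eps**2)
    H = (H + H.T) / 2
    cov = np.linalg.inv(H)
    sd = np.sqrt(np.diag(cov))
    interval = np.column_stack([theta - Z89 * sd, theta + Z89 * sd])
    names = ["intercept", "slope"] + ([] if fixed_sigma else ["log_sigma"])
    return BayesRegressionResult(
        names=names,
        map_estimate=theta,
        posterior_sd=sd,
        interval_89=interval,
        covariance=cov,
        curvature=H,
        n=n,
    )
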