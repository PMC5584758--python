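"""GLMs relating fish community metrics to reef rugosity and covariates.

Abundance (integer counts) is modelled with a negative-binomial error
distribution and log link, biomass (continuous, positive) with a gamma
distribution and log link, and species richness with a Poisson distribution.
The most complex model regresses the response on DRR and DRR^2 (to detect a
unimodal species-habitat relationship), reef depth, water temperature, and —
for natural reefs only — sediment-depth standard deviation.  Candidate models
of reduced complexity are compared by AIC.

Pattern classification follows the significance of the rugosity terms in the
selected model: both DRR and DRR^2 significant (with a negative quadratic
coefficient and an interior vertex -b1/(2 b2)) -> unimodal; only the linear
term -> linear; only the quadratic -> quadratic; both marginal -> marginally
unimodal; neither -> no rugosity effect.

The negative-binomial dispersion (size) parameter is estimated by profiling
the likelihood over the GLM fit, and the gamma shape from its ML score
equation; both count toward AIC's parameter total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

FAMILIES = ("negative_binomial", "gamma", "poisson")

#: predictor name -> column of the samples frame it is built from
PREDICTOR_SOURCES = {
    "drr": "drr", "drr2": "drr", "depth": "depth",
    "temperature": "temperature", "sediment_sd": "sediment_sd",
}


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One candidate GLM: response, error family, predictors, reef type."""

    response: str
    family: str
    predictors: tuple[str, ...]
    reef_type: str = "natural"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        unknown = set(self.predictors) - set(PREDICTOR_SOURCES)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        if "drr2" in self.predictors and "drr" not in self.predictors:
            raise ValueError("drr2 requires drr (hierarchy)")
        if "sediment_sd" in self.predictors and self.reef_type != "natural":
            raise ValueError("sediment_sd is a natural-reef covariate only")


@dataclass
class GLMFitResult:
    """Fitted GLM with Wald table, dispersion, and selection statistics."""

    spec: ModelSpec
    table: pd.DataFrame          # index: intercept + predictors; columns coef/se/z/p
    dispersion: float | None     # NB size (theta) or gamma shape; None for Poisson
    llf: float
    aic: float
    n: int
    converged: bool
    mu: np.ndarray = field(repr=False, default=None)    # fitted means
    y: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    n_excluded_zeros: int = 0

    @property
    def coefficients(self) -> pd.Series:
        return self.table["coef"]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.table["coef"].to_numpy()


@dataclass
class PatternClassification:
    pattern: str                       # unimodal / unimodal_marginal / linear / quadratic / none
    inflection: float | None = None    # -b1 / (2 b2), DRR units
    inflection_in_range: bool | None = None


# ---------------------------------------------------------------------------
# design-matrix assembly

def design_matrix(samples: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, int]:
    """Build (y, X, used_rows, n_excluded_zeros) for a model spec.

    Gamma support is positive, so zero-biomass replicates are excluded (with a
    count) when the family is gamma.
    """
    df = samples
    if "reef_type" in df.columns:
        df = df[df["reef_type"] == spec.reef_type]
    needed = {PREDICTOR_SOURCES[p] for p in spec.predictors}
    df = df.dropna(subset=[spec.response, *needed])
    y = df[spec.response].to_numpy(dtype=float)
    n_excluded = 0
    if spec.family == "gamma":
        keep = y > 0
        n_excluded = int(np.sum(~keep))
        df, y = df[keep], y[keep]
    if spec.family in ("negative_binomial", "poisson"):
        if not np.allclose(y, np.round(y)):
            raise ValueError(f"{spec.family} requires integer response")
    cols = [np.ones(len(df))]
    for p in spec.predictors:
        base = df[PREDICTOR_SOURCES[p]].to_numpy(dtype=float)
        cols.append(base ** 2 if p == "drr2" else base)
    X = np.column_stack(cols)
    if len(y) <= X.shape[1] + 2:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} parameters")
    return y, X, df, n_excluded


# ---------------------------------------------------------------------------
# family-specific ML machinery

def _fit_nb_profile(y: np.ndarray, X: np.ndarray):
    """Profile the NB likelihood over the size parameter theta (= 1/alpha).

    For each alpha the mean model is refit by IRLS; the outer optimisation is
    over log alpha.  Mirrors the usual alternating scheme of glm.nb.
    """
    def negll(log_alpha):
        fam = sm.families.NegativeBinomial(alpha=np.exp(log_alpha))
        try:
            res = sm.GLM(y, X, family=fam).fit()
        except Exception:
            return np.inf
        return -res.llf

    opt = optimize.minimize_scalar(negll, bounds=(np.log(1e-6), np.log(1e3)),
                                   method="bounded",
                                   options={"xatol": 1e-6, "maxiter": 80})
    alpha = float(np.exp(opt.x))
    res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    return res, 1.0 / alpha, float(res.llf)


def _gamma_shape_ml(y: np.ndarray, mu: np.ndarray) -> float:
    """Solve the gamma ML score equation for the shape parameter.

    d loglik / d k = 0  <=>  log k - digamma(k) = mean(y/mu - log(y/mu)) - 1.
    """
    c = float(np.mean(y / mu - np.log(y / mu)) - 1.0)
    if c <= 0:
        return 1e6  # essentially no residual gamma variation
    f = lambda k: np.log(k) - special.digamma(k) - c
    return float(optimize.brentq(f, 1e-4, 1e8))


def _gamma_llf(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    return float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu / shape)))


def fit_glm(samples: pd.DataFrame, spec: ModelSpec) -> GLMFitResult:
    """Fit one GLM by maximum likelihood with a log link throughout.

    Returns Wald coefficient table (SEs from the observed information at the
    ML dispersion), log-likelihood, and AIC = 2k - 2 logLik with k counting
    the dispersion/shape parameter where one is estimated.
    """
    y, X, df, n_excl = design_matrix(samples, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConvergenceError(f"{spec}: degenerate (rank-deficient) design")
    names = ["intercept", *spec.predictors]
    k_params = X.shape[1]
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if spec.family == "poisson":
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                dispersion, llf = None, float(res.llf)
            elif spec.family == "negative_binomial":
                res, dispersion, llf = _fit_nb_profile(y, X)
                k_params += 1
            else:  # gamma
                model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
                res0 = model.fit()
                shape = _gamma_shape_ml(y, res0.mu)
                res = model.fit(scale=1.0 / shape)  # Wald SEs at the ML dispersion
                dispersion = shape
                llf = _gamma_llf(y, res.mu, shape)
                k_params += 1
            converged = bool(getattr(res, "converged", True))
        except Exception as exc:
            raise ConvergenceError(f"{spec}: {exc}") from exc
    if not converged:
        raise ConvergenceError(f"{spec}: IRLS did not converge")
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"coef": coef, "se": se, "z": z, "p": p}, index=names)
    aic = 2.0 * k_params - 2.0 * llf
    return GLMFitResult(spec=spec, table=table, dispersion=dispersion, llf=llf,
                        aic=aic, n=len(y), converged=converged,
                        mu=np.asarray(res.mu), y=y, X=X, n_excluded_zeros=n_excl)


# ---------------------------------------------------------------------------
# model selection

def candidate_specs(response: str, family: str, reef_type: str) -> list[ModelSpec]:
    """All nested candidates: drop {temperature}, {sediment_sd}, {drr, drr2}
    blocks from the full model, preserving the drr2 => drr hierarchy."""
    blocks = [("temperature",)]
    if reef_type == "natural":
        blocks.append(("sediment_sd",))
    blocks.append(("drr", "drr2"))
    full = ["drr", "drr2", "depth", "temperature"]
    if reef_type == "natural":
        full.append("sediment_sd")
    specs = []
    for mask in range(2 ** len(blocks)):
        dropped = set()
        for j, block in enumerate(blocks):
            if mask >> j & 1:
                dropped |= set(block)
        preds = tuple(p for p in full if p not in dropped)
        specs.append(ModelSpec(response=response, family=family,
                               predictors=preds, reef_type=reef_type))
    return specs


def model_select(samples: pd.DataFrame, specs: list[ModelSpec]):
    """Fit every candidate on the same samples and return the minimum-AIC fit.

    Non-convergent candidates are excluded from selection but retained in the
    AIC table with a warning, never silently dropped.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 candidate specs")
    fits, rows = [], []
    for spec in specs:
        try:
            fit = fit_glm(samples, spec)
            fits.append(fit)
            rows.append({"predictors": "+".join(spec.predictors) or "intercept",
                         "family": spec.family, "aic": fit.aic,
                         "llf": fit.llf, "converged": True})
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"candidate excluded ({exc})", stacklevel=2)
            rows.append({"predictors": "+".join(spec.predictors) or "intercept",
                         "family": spec.family, "aic": np.nan,
                         "llf": np.nan, "converged": False})
    if not fits:
        raise ConvergenceError("no candidate converged")
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    best = min(fits, key=lambda f: f.aic)
    return best, table


# ---------------------------------------------------------------------------
# assessment of fit and pattern classification

def _conditional_distribution(fit: GLMFitResult, mu: np.ndarray):
    if fit.spec.family == "poisson":
        return stats.poisson(mu)
    if fit.spec.family == "negative_binomial":
        theta = fit.dispersion
        return stats.nbinom(theta, theta / (theta + mu))
    return stats.gamma(a=fit.dispersion, scale=mu / fit.dispersion)


def assess_fit(fit: GLMFitResult, y: np.ndarray | None = None,
               two_sided: bool = True):
    """Predictive-distribution P-value for each observation.

    Each observation is treated as the test statistic against the fitted
    conditional distribution at its covariates; the two-sided tail probability
    is P = 2 min(F(y), 1 - F(y-)) capped at 1 (y- is the next-lower support
    point for count families).  Also returns a density/pmf grid per
    observation range for graphical overlay of observed values on the
    estimated distribution.
    """
    if y is None:
        y = fit.y
    dist = _conditional_distribution(fit, fit.mu)
    discrete = fit.spec.family in ("poisson", "negative_binomial")
    cdf_y = dist.cdf(y)
    upper = dist.sf(y - 1.0) if discrete else dist.sf(y)
    if two_sided:
        pvals = np.minimum(1.0, 2.0 * np.minimum(cdf_y, upper))
    else:
        pvals = np.minimum(cdf_y, upper)
    # grid for the graphical assessment of fit
    lo, hi = float(np.min(fit.mu)) * 0.0, float(np.max(y)) * 1.5 + 10
    if discrete:
        grid = np.arange(0, int(np.ceil(hi)) + 1)
        density = _conditional_distribution(fit, np.full_like(grid, np.mean(fit.mu),
                                                              dtype=float)).pmf(grid)
    else:
        grid = np.linspace(max(lo, 1e-9), hi, 400)
        density = _conditional_distribution(
            fit, np.full_like(grid, np.mean(fit.mu))).pdf(grid)
    return pvals, {"grid": grid, "density": density}


def classify_pattern(fit: GLMFitResult, drr_range: tuple[float, float],
                     alpha: float = 0.05,
                     marginal_alpha: float = 0.10) -> PatternClassification:
    """Categorize the rugosity pattern of a fitted model.

    Both rugosity terms significant -> unimodal (when the quadratic
    coefficient is negative and the vertex -b1/(2 b2) lies inside the observed
    DRR range; otherwise plain quadratic); one term significant -> linear or
    quadratic respectively; significance only in the marginal band
    (alpha, marginal_alpha] -> marginally unimodal; neither -> none.
    """
    if "drr" not in fit.table.index or "drr2" not in fit.table.index:
        return PatternClassification(pattern="none")
    row1, row2 = fit.table.loc["drr"], fit.table.loc["drr2"]
    if not (np.isfinite(row1["se"]) and np.isfinite(row2["se"])):
        raise ValueError("missing standard errors for rugosity terms")
    b1, b2, p1, p2 = row1["coef"], row2["coef"], row1["p"], row2["p"]
    inflection = float(-b1 / (2.0 * b2)) if b2 != 0 else None
    in_range = (inflection is not None
                and drr_range[0] <= inflection <= drr_range[1])
    sig1, sig2 = p1 < alpha, p2 < alpha
    marg1 = alpha <= p1 <= marginal_alpha
    marg2 = alpha <= p2 <= marginal_alpha
    if sig1 and sig2:
        if b2 < 0 and in_range:
            pattern = "unimodal"
        else:
            pattern = "quadratic"
    elif (sig1 and marg2) or (marg1 and sig2) or (marg1 and marg2):
        pattern = "unimodal_marginal" if b2 < 0 else "none"
    elif sig1:
        pattern = "linear"
    elif sig2:
        pattern = "quadratic"
    else:
        pattern = "none"
    return PatternClassification(pattern=pattern, inflection=inflection,
                                 inflection_in_range=bool(in_range))


def prediction_surface(fit: GLMFitResult, samples: pd.DataFrame,
                       drr_grid: np.ndarray, depth_grid: np.ndarray):
    """GLM predictions exp(eta) on a DRR x depth grid.

    Other covariates are held at their sample means.  Returns (surface, signs)
    where signs[i] = +1/-1 marks raw points above/below the fitted surface at
    their own covariates.
    """
    coefs = fit.table["coef"]
    DD, ZZ = np.meshgrid(drr_grid, depth_grid, indexing="ij")
    eta = np.full(DD.shape, coefs["intercept"])
    means = {p: float(samples[PREDICTOR_SOURCES[p]].mean())
             for p in fit.spec.predictors}
    for p in fit.spec.predictors:
        if p == "drr":
            eta = eta + coefs[p] * DD
        elif p == "drr2":
            eta = eta + coefs[p] * DD ** 2
        elif p == "depth":
            eta = eta + coefs[p] * ZZ
        else:
            eta = eta + coefs[p] * means[p]
    surface = np.exp(eta)
    signs = np.where(fit.y >= fit.mu, 1, -1)
    return surface, signs


# ---------------------------------------------------------------------------
# table output

def results_table(entries: list[tuple[str, str, GLMFitResult, PatternClassification]]) -> pd.DataFrame:
    """Long-format model table: one row per predictor of each selected model."""
    rows = []
    for response, reef_type, fit, cls in entries:
        for name, r in fit.table.iterrows():
            rows.append({
                "response": response, "reef_type": reef_type,
                "family": fit.spec.family, "predictor": name,
                "coefficient": r["coef"], "se": r["se"], "z": r["z"],
                "p": r["p"], "pattern": cls.pattern,
            })
    return pd.DataFrame(rows)
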