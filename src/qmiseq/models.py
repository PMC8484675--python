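"""Spatial univariate models for eDNA quantities, OTU counts and backscatter.

Three model families cover the response types that arise in the survey:

* Poisson with log link for OTU richness (counts);
* gamma with log link for eDNA copy concentrations (continuous, positive);
* a gamma hurdle (binomial presence × gamma magnitude on positives) for
  species whose concentration is zero at some stations.

Distance from the focal reef enters as log(distance_m + 0.1), so the reef
station itself (0 m) anchors the curve at log(0.1); echo intensity enters as
log10 of the linear volume backscattering coefficient.  The candidate set
for model selection is the hierarchical family {1; cov; depth; cov+depth;
cov+depth+cov×depth}, ranked by BIC = k·ln(n) − 2·logL with the gamma shape
counted as a parameter.  Station effects are screened with likelihood-ratio
tests and followed up with Tukey-type single-step max-|z| contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

FAMILIES = ("poisson_log", "gamma_log", "gamma_hurdle")

CANDIDATE_TERM_SETS: tuple[tuple[str, ...], ...] = (
    (),
    ("cov",),
    ("depth",),
    ("cov", "depth"),
    ("cov", "depth", "cov:depth"),
)


def log_distance(distance_m) -> np.ndarray:
    """The reef-distance covariate log(distance + 0.1), distance in metres."""
    d = np.asarray(distance_m, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative (use absolute distance)")
    return np.log(d + 0.1)


def echo_covariate(sv_linear) -> np.ndarray:
    """Echo-intensity covariate: log10 of linear S_V (spans ~3 decades)."""
    sv = np.asarray(sv_linear, dtype=float)
    if (sv <= 0).any():
        raise ValueError("linear S_V must be positive to log-transform")
    return np.log10(sv)


@dataclass(frozen=True)
class ModelSpec:
    response: str
    family: str
    terms: tuple[str, ...]
    covariate: str = "log(distance_m + 0.1)"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if "cov:depth" in self.terms and not {"cov", "depth"} <= set(self.terms):
            raise ValueError("interaction requires both main effects")


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n: int
    k: int
    bic: float
    fitted: np.ndarray
    shape: float | None = None  # gamma shape (None for Poisson)
    pseudo_r2: float = float("nan")
    factor_levels: tuple[str, ...] | None = None
    # hurdle-only: the binomial (presence) component
    binom_params: pd.Series | None = None
    binom_bse: pd.Series | None = None
    degenerate: str | None = None  # "all_positive" / "all_zero" fallbacks


def build_design(
    covariate: np.ndarray | None = None,
    depth_layer: Sequence[str] | None = None,
    terms: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Design matrix with canonical columns const / cov / depth_middle / interaction.

    Depth is coded with the bottom layer as reference, so "depth_middle" is
    the middle-vs-bottom effect.
    """
    n = None
    cols: dict[str, np.ndarray] = {}
    if "cov" in terms or "cov:depth" in terms:
        if covariate is None:
            raise ValueError("terms include the covariate but none was supplied")
        cov = np.asarray(covariate, dtype=float)
        n = len(cov)
    if "depth" in terms or "cov:depth" in terms:
        if depth_layer is None:
            raise ValueError("terms include depth but no depth layer was supplied")
        middle = np.asarray([1.0 if d == "middle" else 0.0 for d in depth_layer])
        n = len(middle) if n is None else n
    if n is None:
        if covariate is not None:
            n = len(np.asarray(covariate))
        elif depth_layer is not None:
            n = len(depth_layer)
        else:
            raise ValueError("cannot infer n for an intercept-only design")
    cols["const"] = np.ones(n)
    if "cov" in terms:
        cols["cov"] = cov
    if "depth" in terms:
        cols["depth_middle"] = middle
    if "cov:depth" in terms:
        cols["cov:depth_middle"] = cov * middle
    return pd.DataFrame(cols)


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    return float(
        np.sum(
            alpha * np.log(alpha)
            - alpha * np.log(mu)
            + (alpha - 1.0) * np.log(y)
            - alpha * y / mu
            - gammaln(alpha)
        )
    )


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile MLE of the gamma shape given fitted means (1-D optimisation)."""
    s = float(np.sum(np.log(y / mu) - y / mu))
    n = len(y)

    def neg(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        return -(n * (a * log_alpha - gammaln(a)) + a * s)

    res = optimize.minimize_scalar(neg, bounds=(-6.0, 12.0), method="bounded")
    return float(np.exp(res.x))


def _pseudo_r2(y: np.ndarray, fitted: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(fitted) == 0:
        return float("nan")
    return float(np.corrcoef(y, fitted)[0, 1] ** 2)


def fit_glm(
    y,
    design: pd.DataFrame,
    family: str,
    response_name: str = "y",
    spec: ModelSpec | None = None,
) -> ModelFit:
    """Maximum-likelihood GLM fit (log link) with BIC on the full likelihood.

    The gamma fit uses IRLS for the coefficients (which do not depend on the
    shape) and then profiles the shape by ML; coefficient covariance is the
    inverse Fisher information (X'X)⁻¹/α under the log link.  Poisson fits
    come straight from IRLS.  BIC counts the gamma shape as a parameter.
    """
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response and design lengths differ")
    if spec is None:
        terms = tuple(t for t in ("cov", "depth", "cov:depth")
                      if {"cov": "cov", "depth": "depth_middle",
                          "cov:depth": "cov:depth_middle"}[t] in design.columns)
        spec = ModelSpec(response_name, family, terms)

    if family == "poisson_log":
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("Poisson responses must be non-negative integers")
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit()
        if not res.converged:
            raise RuntimeError(f"Poisson GLM did not converge: {res.mle_retvals}")
        llf = float(res.llf)
        k = p
        params = pd.Series(res.params, index=design.columns)
        bse = pd.Series(res.bse, index=design.columns)
        cov = pd.DataFrame(res.cov_params(), index=design.columns, columns=design.columns)
        fitted = np.asarray(res.mu)
        shape = None
    elif family == "gamma_log":
        if (y <= 0).any():
            raise ValueError(
                "gamma responses must be strictly positive; "
                "zeros call for the gamma hurdle model"
            )
        model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
        res = model.fit()
        if not res.converged:
            raise RuntimeError(f"gamma GLM did not converge: {res.mle_retvals}")
        fitted = np.asarray(res.mu)
        shape = _gamma_shape_mle(y, fitted)
        llf = _gamma_loglik(y, fitted, shape)
        k = p + 1  # shape is estimated too
        params = pd.Series(res.params, index=design.columns)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov_arr = xtx_inv / shape
        cov = pd.DataFrame(cov_arr, index=design.columns, columns=design.columns)
        bse = pd.Series(np.sqrt(np.diag(cov_arr)), index=design.columns)
    else:
        raise ValueError(f"fit_glm handles poisson_log/gamma_log, not {family!r}")

    bic = k * np.log(n) - 2.0 * llf
    return ModelFit(
        spec=spec, params=params, bse=bse, cov_params=cov,
        llf=llf, n=n, k=k, bic=float(bic), fitted=fitted,
        shape=shape, pseudo_r2=_pseudo_r2(y, fitted),
    )


def fit_gamma_hurdle(
    y,
    design_gamma: pd.DataFrame,
    design_binom: pd.DataFrame | None = None,
    response_name: str = "y",
) -> ModelFit:
    """Two-part model: logistic presence × gamma magnitude on positives.

    The joint log-likelihood is the sum of the two components' likelihoods,
    and k sums their parameter counts (gamma shape included).  Fitted values
    are Pr(positive) × E[y | positive].  Degenerate inputs (no zeros / no
    positives) fall back to the single informative component with a warning.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("hurdle responses must be non-negative")
    if design_binom is None:
        design_binom = pd.DataFrame({"const": np.ones(len(y))})
    positive = y > 0

    if positive.all():
        logger.warning("no zeros in response: hurdle reduces to the gamma GLM")
        fit = fit_glm(y, design_gamma, "gamma_log", response_name)
        fit.degenerate = "all_positive"
        fit.spec = ModelSpec(response_name, "gamma_hurdle", fit.spec.terms,
                             fit.spec.covariate)
        return fit
    if not positive.any():
        logger.warning("no positives in response: fitting the binomial part only")
        bres = sm.GLM(positive.astype(float), design_binom.to_numpy(),
                      family=sm.families.Binomial()).fit()
        kb = design_binom.shape[1]
        llf = float(bres.llf)
        bic = kb * np.log(len(y)) - 2 * llf
        empty = pd.Series(dtype=float)
        return ModelFit(
            spec=ModelSpec(response_name, "gamma_hurdle", ()),
            params=empty, bse=empty, cov_params=pd.DataFrame(),
            llf=llf, n=len(y), k=kb, bic=float(bic),
            fitted=np.zeros(len(y)), degenerate="all_zero",
            binom_params=pd.Series(bres.params, index=design_binom.columns),
            binom_bse=pd.Series(bres.bse, index=design_binom.columns),
        )

    bres = sm.GLM(positive.astype(float), design_binom.to_numpy(),
                  family=sm.families.Binomial()).fit()
    llf_b = float(bres.llf)
    p_pos = np.asarray(bres.mu)

    gfit = fit_glm(y[positive], design_gamma.loc[positive].reset_index(drop=True),
                   "gamma_log", response_name)
    llf_g = gfit.llf

    n = len(y)
    k = gfit.k + design_binom.shape[1]
    llf = llf_b + llf_g
    bic = k * np.log(n) - 2.0 * llf

    # E[y | positive] over the full design, then scale by Pr(positive)
    Xg = design_gamma.to_numpy(dtype=float)
    mu_pos = np.exp(Xg @ gfit.params.to_numpy())
    fitted = p_pos * mu_pos

    spec = ModelSpec(response_name, "gamma_hurdle", gfit.spec.terms, gfit.spec.covariate)
    return ModelFit(
        spec=spec, params=gfit.params, bse=gfit.bse, cov_params=gfit.cov_params,
        llf=llf, n=n, k=k, bic=float(bic), fitted=fitted, shape=gfit.shape,
        pseudo_r2=_pseudo_r2(y, fitted),
        binom_params=pd.Series(bres.params, index=design_binom.columns),
        binom_bse=pd.Series(bres.bse, index=design_binom.columns),
    )


def fit_factor_glm(y, factor: Sequence[str], family: str,
                   response_name: str = "y") -> ModelFit:
    """GLM with a categorical predictor (first level = reference)."""
    levels = tuple(dict.fromkeys(factor))  # stable order of appearance
    if len(levels) < 2:
        raise ValueError("factor must have at least two levels")
    cols = {"const": np.ones(len(list(factor)))}
    for lv in levels[1:]:
        cols[f"level[{lv}]"] = np.asarray([1.0 if f == lv else 0.0 for f in factor])
    design = pd.DataFrame(cols)
    fit = fit_glm(y, design, family, response_name)
    fit.factor_levels = levels
    return fit


def lr_test_factor(y, factor: Sequence[str], family: str) -> tuple[float, int, float]:
    """Likelihood-ratio test of a factor (e.g. station) against intercept-only.

    Returns (statistic, df, p) with the statistic referred to chi-square on
    (levels − 1) degrees of freedom.  For the gamma family both likelihoods
    are profiled over their own ML shape.
    """
    levels = tuple(dict.fromkeys(factor))
    if len(levels) < 2:
        raise ValueError("factor must have at least two levels")
    null = fit_glm(y, pd.DataFrame({"const": np.ones(len(list(factor)))}), family)
    full = fit_factor_glm(y, factor, family)
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    df = len(levels) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def pairwise_contrasts(
    fit: ModelFit,
    adjust: str = "single-step",
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tukey-type all-pairs comparisons on the linear-predictor scale.

    Wald z statistics for every pair of factor levels are adjusted with the
    single-step max-|z| method: the contrasts' correlation matrix (from the
    coefficient covariance) defines a multivariate normal whose max-|Z|
    distribution is evaluated by seeded Monte Carlo.  ``adjust="holm"``
    gives a deterministic step-down fallback.
    """
    if fit.factor_levels is None:
        raise ValueError("fit must come from fit_factor_glm")
    levels = fit.factor_levels
    idx = list(fit.params.index)
    m = len(levels)
    # linear-predictor level means: const + level effect (ref effect = 0)
    L = np.zeros((m, len(idx)))
    L[:, idx.index("const")] = 1.0
    for i, lv in enumerate(levels[1:], start=1):
        L[i, idx.index(f"level[{lv}]")] = 1.0
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    C = np.array([L[i] - L[j] for i, j in pairs])
    Sigma = fit.cov_params.to_numpy()
    est = C @ fit.params.to_numpy()
    V = C @ Sigma @ C.T
    se = np.sqrt(np.diag(V))
    if (se <= 0).any() or not np.isfinite(se).all():
        raise np.linalg.LinAlgError("singular contrast covariance")
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))

    if len(pairs) == 1:
        p_adj = p_raw.copy()
    elif adjust == "single-step":
        R = V / np.outer(se, se)
        # symmetrise + ridge for numerical PSD-ness
        R = (R + R.T) / 2 + 1e-10 * np.eye(len(pairs))
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(np.zeros(len(pairs)), R, size=n_mc,
                                        method="cholesky")
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([(np.sum(maxabs >= abs(zk)) + 1) / (n_mc + 1) for zk in z])
    elif adjust == "holm":
        from statsmodels.stats.multitest import multipletests
        p_adj = multipletests(p_raw, method="holm")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "level_a": [levels[i] for i, _ in pairs],
            "level_b": [levels[j] for _, j in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_unadjusted": p_raw,
            "p_adjusted": p_adj,
        }
    )


def bic_select(
    y,
    covariate: np.ndarray,
    depth_layer: Sequence[str],
    family_policy: str = "auto",
    binom_terms: str = "intercept",
    response_name: str = "y",
    covariate_name: str = "log(distance_m + 0.1)",
) -> tuple[ModelFit, pd.DataFrame]:
    """Fit the hierarchical candidate set and return the minimum-BIC model.

    Candidates: intercept-only; covariate; depth; covariate+depth; and the
    full model with the covariate×depth interaction.  ``family_policy`` is
    "poisson", "gamma", or "auto" (gamma when all responses are positive,
    gamma hurdle when zeros are present).  For the hurdle, the binomial
    component is intercept-only by default ("intercept") or mirrors the
    gamma terms ("same").
    """
    y = np.asarray(y, dtype=float)
    if family_policy == "auto":
        family = "gamma_log" if (y > 0).all() else "gamma_hurdle"
    elif family_policy in ("poisson", "poisson_log"):
        family = "poisson_log"
    elif family_policy in ("gamma", "gamma_log"):
        family = "gamma_log"
    elif family_policy in ("hurdle", "gamma_hurdle"):
        family = "gamma_hurdle"
    else:
        raise ValueError(f"unknown family policy {family_policy!r}")

    fits: list[ModelFit] = []
    rows = []
    for terms in CANDIDATE_TERM_SETS:
        Xg = build_design(covariate, depth_layer, terms)
        if family == "gamma_hurdle":
            Xb = (Xg if binom_terms == "same"
                  else pd.DataFrame({"const": np.ones(len(y))}))
            fit = fit_gamma_hurdle(y, Xg, Xb, response_name)
        else:
            fit = fit_glm(y, Xg, family, response_name)
        fit.spec = ModelSpec(response_name, family, terms, covariate_name)
        fits.append(fit)
        rows.append(
            {"terms": "+".join(terms) if terms else "1",
             "k": fit.k, "llf": fit.llf, "bic": fit.bic,
             "pseudo_r2": fit.pseudo_r2}
        )
    table = pd.DataFrame(rows)
    table["delta_bic"] = table["bic"] - table["bic"].min()
    order = np.argsort(table["bic"].to_numpy(), kind="stable")
    best = fits[int(order[0])]
    return best, table.iloc[order].reset_index(drop=True)


def predict_response(
    fit: ModelFit,
    covariate_value: float,
    depth_layer: str = "bottom",
) -> float:
    """Expected response at a covariate value and depth layer.

    exp(linear predictor) for the log-link families; for the hurdle,
    Pr(positive) × E[y | positive].  Values outside the fitted covariate
    range are extrapolations and are logged as such.
    """
    row = {"const": 1.0, "cov": covariate_value,
           "depth_middle": 1.0 if depth_layer == "middle" else 0.0}
    row["cov:depth_middle"] = row["cov"] * row["depth_middle"]

    def lp(params: pd.Series) -> float:
        return float(sum(params[c] * row.get(c, 0.0) for c in params.index
                         if c in row or c == "const"))

    mu = float(np.exp(lp(fit.params))) if len(fit.params) else 0.0
    if fit.spec.family == "gamma_hurdle" and fit.binom_params is not None \
            and fit.degenerate != "all_positive":
        eta_b = float(sum(fit.binom_params[c] * row.get(c, 0.0)
                          for c in fit.binom_params.index))
        p_pos = 1.0 / (1.0 + np.exp(-eta_b))
        return p_pos * mu
    return mu


def expected_response(
    coefficients: Mapping[str, float],
    covariate_value: float,
    depth_layer: str = "bottom",
) -> float:
    """exp(linear predictor) from a plain coefficient mapping.

    Keys: "const"/"intercept", "cov", "depth_middle", "cov:depth_middle".
    Useful for evaluating published coefficient tables without refitting.
    """
    middle = 1.0 if depth_layer == "middle" else 0.0
    eta = (
        coefficients.get("const", coefficients.get("intercept", 0.0))
        + coefficients.get("cov", 0.0) * covariate_value
        + coefficients.get("depth_middle", 0.0) * middle
        + coefficients.get("cov:depth_middle", 0.0) * covariate_value * middle
    )
    return float(np.exp(eta))
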