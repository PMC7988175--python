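"""Overall mixed model and simulation-based meta-regressions.

Two analyses live here. The overall model pools every yearly observation:

    log(lambda) = alpha + beta P + eta T + theta P x T + eps

with random population effects on the intercept and both slopes, fit by
REML. The meta-regressions relate per-population effect sizes to a site
or species predictor (water availability index, mean annual temperature,
or log generation time), propagating the uncertainty of each effect size
by simulation: each of ``n_datasets`` simulated datasets perturbs every
effect by its standard error, a 1/SE-weighted regression is fit (linear
for signed effects, gamma with a log link for absolute effects), and
``n_draws`` normal values are drawn from each fitted slope's sampling
distribution. The pooled n_datasets x n_draws values give the confidence
interval and the one-tailed test: the slope is declared significant when
more than 95% of pooled values fall below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .popfit import EffectSize

__all__ = [
    "OverallFit",
    "MetaResult",
    "fit_overall",
    "simulate_meta",
    "one_tailed_significant",
]

PREDICTORS = ("WAI", "MAT", "logT")


@dataclass
class OverallFit:
    """Fixed effects of the pooled mixed model with 95% CIs."""

    beta: float  # precipitation
    eta: float  # temperature
    theta: float  # interaction
    ci: dict[str, tuple[float, float]]
    random_variances: dict[str, float]
    converged: bool
    simplified: bool  # True when the random structure had to be reduced
    n_obs: int
    n_groups: int

    def __post_init__(self) -> None:
        for name, est in (("P", self.beta), ("T", self.eta), ("PxT", self.theta)):
            lo, hi = self.ci[name]
            if not lo <= est <= hi:
                raise ValueError(f"CI for {name} does not contain the estimate")

    def to_dict(self) -> dict:
        return {
            "beta_precip": self.beta,
            "eta_temp": self.eta,
            "theta_interaction": self.theta,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "random_variances": self.random_variances,
            "converged": self.converged,
            "simplified_random_structure": self.simplified,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


@dataclass
class MetaResult:
    """Distribution of simulated meta-regression slopes."""

    predictor: str
    family: str
    beta_meta_point: float
    draws: np.ndarray = field(repr=False)
    ci95: tuple[float, float] = (np.nan, np.nan)
    frac_below_zero: float = np.nan
    significant: bool = False
    n_datasets: int = 0
    n_draws: int = 0
    n_effects: int = 0

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "family": self.family,
            "beta_meta_point": self.beta_meta_point,
            "ci95": list(self.ci95),
            "frac_below_zero": self.frac_below_zero,
            "significant": self.significant,
            "n_datasets": self.n_datasets,
            "n_draws": self.n_draws,
            "n_effects": self.n_effects,
            "n_pooled_draws": int(self.draws.size),
        }


def fit_overall(records: pd.DataFrame) -> OverallFit:
    """REML fit of the pooled model with random intercept and slopes.

    ``records`` needs columns pop_id, log_lambda, P, T. Quadratic terms are
    deliberately absent: single populations rarely contribute enough years
    to identify them in the pooled model. A singular random-effects fit is
    retried with a random intercept only (with a warning).
    """
    df = records.copy()
    required = {"pop_id", "log_lambda", "P", "T"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    counts = df.groupby("pop_id").size()
    if len(counts) < 2:
        raise ValueError("overall model needs at least 2 populations")
    if (counts < 6).any():
        short = counts[counts < 6].index.tolist()
        raise ValueError(f"populations with fewer than 6 records: {short}")
    df["PxT"] = df["P"] * df["T"]

    simplified = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "log_lambda ~ P + T + PxT", df, groups=df["pop_id"], re_formula="~P + T"
        )
        try:
            res = model.fit(reml=True)
            singular = not np.all(np.isfinite(res.bse_fe)) or np.any(
                np.diag(res.cov_re) < 1e-10
            )
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            res = None
        if res is None or singular or not res.converged:
            simplified = True
            model = smf.mixedlm(
                "log_lambda ~ P + T + PxT", df, groups=df["pop_id"], re_formula="~1"
            )
            res = model.fit(reml=True)
    if simplified:
        warnings.warn(
            "random slopes were singular; refit with random intercept only",
            stacklevel=2,
        )

    ci_frame = res.conf_int()
    ci = {
        "P": (float(ci_frame.loc["P", 0]), float(ci_frame.loc["P", 1])),
        "T": (float(ci_frame.loc["T", 0]), float(ci_frame.loc["T", 1])),
        "PxT": (float(ci_frame.loc["PxT", 0]), float(ci_frame.loc["PxT", 1])),
    }
    re_cov = np.atleast_2d(res.cov_re)
    re_names = list(res.cov_re.index) if hasattr(res.cov_re, "index") else ["Intercept"]
    random_variances = {
        str(name): float(re_cov[i, i]) for i, name in enumerate(re_names)
    }
    return OverallFit(
        beta=float(res.params["P"]),
        eta=float(res.params["T"]),
        theta=float(res.params["PxT"]),
        ci=ci,
        random_variances=random_variances,
        converged=bool(res.converged),
        simplified=simplified,
        n_obs=len(df),
        n_groups=len(counts),
    )


def _meta_weights(se: np.ndarray, weighting: str) -> np.ndarray:
    se_safe = np.maximum(se, np.finfo(float).eps)
    if weighting == "inv_se":
        return 1.0 / se_safe
    if weighting == "inv_se2":
        return 1.0 / se_safe**2
    raise ValueError("weighting must be 'inv_se' or 'inv_se2'")


def _weighted_linear_slopes(
    x: np.ndarray, Y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted simple-linear-regression slope and SE for each column of Y.

    Solves all simulated datasets in one set of matrix products; identical
    to a per-dataset WLS fit with weights w (residual variance df-corrected
    with n - 2).
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w  # (2, n)
    G = XtW @ X  # X' W X
    Ginv = np.linalg.inv(G)
    coef = Ginv @ (XtW @ Y)  # (2, m)
    resid = Y - X @ coef
    wrss = np.einsum("ij,ij->j", resid * w[:, None], resid)
    sigma2 = wrss / (n - 2)
    se = np.sqrt(Ginv[1, 1] * sigma2)
    return coef[1], se


def _gamma_slope(
    x: np.ndarray, y_abs: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Gamma GLM with log link of |beta| on the predictor; slope and SE."""
    X = np.column_stack([np.ones(x.size), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            y_abs, X, family=sm.families.Gamma(link=sm.families.links.Log()),
            var_weights=w,
        )
        res = model.fit()
    return float(res.params[1]), float(res.bse[1])


def _predictor_values(effects: Sequence[EffectSize], predictor: str) -> np.ndarray:
    if predictor == "WAI":
        vals = np.array([e.wai for e in effects])
    elif predictor == "MAT":
        vals = np.array([e.mat for e in effects])
    elif predictor == "logT":
        vals = np.array([np.log(e.generation_time) for e in effects])
    else:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite {predictor} values among the effects")
    return vals


def simulate_meta(
    effects: Sequence[EffectSize],
    predictor: str,
    family: str = "linear",
    *,
    n_datasets: int = 1000,
    n_draws: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    weighting: str = "inv_se",
) -> MetaResult:
    """Two-stage simulation meta-regression with SE propagation.

    ``family='linear'`` regresses signed effects on the predictor (for the
    aridity and temperature hypotheses); ``family='gamma_log'`` regresses
    absolute effects with a gamma log-link (for generation time, where the
    response is bounded below by zero). Weights are 1/SE in either family.
    """
    if len(effects) < 3:
        raise ValueError(f"need at least 3 effects, got {len(effects)}")
    if family not in ("linear", "gamma_log"):
        raise ValueError("family must be 'linear' or 'gamma_log'")
    rng = np.random.default_rng(seed)
    beta = np.array([e.beta for e in effects])
    se = np.array([e.se for e in effects])
    x = _predictor_values(effects, predictor)
    w = _meta_weights(se, weighting)
    n = beta.size
    eps = np.finfo(float).eps

    if family == "linear":
        point, _ = _weighted_linear_slopes(x, beta[:, None], w)
        point = float(point[0])
        Y = beta[:, None] + se[:, None] * rng.standard_normal((n, n_datasets))
        slopes, slope_ses = _weighted_linear_slopes(x, Y, w)
    else:
        point, _ = _gamma_slope(x, np.maximum(np.abs(beta), eps), w)
        slopes = np.empty(n_datasets)
        slope_ses = np.empty(n_datasets)
        perturbed = beta[:, None] + se[:, None] * rng.standard_normal((n, n_datasets))
        y_abs = np.maximum(np.abs(perturbed), eps)  # truncate zero draws
        for d in range(n_datasets):
            slopes[d], slope_ses[d] = _gamma_slope(x, y_abs[:, d], w)

    draws = rng.normal(
        loc=slopes[None, :], scale=np.maximum(slope_ses, 0.0)[None, :],
        size=(n_draws, n_datasets),
    ).ravel()
    ci95 = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    frac = float(np.mean(draws < 0))
    result = MetaResult(
        predictor=predictor,
        family=family,
        beta_meta_point=point,
        draws=draws,
        ci95=ci95,
        frac_below_zero=frac,
        n_datasets=n_datasets,
        n_draws=n_draws,
        n_effects=n,
    )
    result.significant = one_tailed_significant(result)
    return result


def one_tailed_significant(result: MetaResult, threshold: float = 0.95) -> bool:
    """True iff strictly more than 95% of pooled draws are below zero."""
    if result.draws.size == 0:
        raise ValueError("MetaResult has no draws")
    return bool(result.frac_below_zero > threshold)
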