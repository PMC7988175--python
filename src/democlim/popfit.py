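"""Per-population regression of log(lambda) on climate anomalies.

The baseline model is a multiple regression with an AR(1) error term:

    log(lambda)_y = alpha + beta_p P_y + beta_t T_y + eps_y
    eps_y = rho eps_{y-1} + eta_y,   eta_y ~ N(0, sigma^2)

estimated by exact Gaussian maximum likelihood under the stationary AR(1)
covariance (Prais-Winsten transform, likelihood concentrated over the
regression coefficients and innovation variance, optimized over rho).
When a study contains contiguous spatial replicates of one population,
coefficients are shared across replicates while rho is estimated
separately per replicate.

Up to six candidate models per population — baseline, three quadratic
variants (admissible only for series longer than 14 years), and two
covariate-interaction variants — are compared by AICc; effect sizes and
standard errors of the selected model are combined into a single per-
variable slope (e.g. beta_p + beta_p2 for a selected quadratic model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "CandidateModel",
    "ModelFit",
    "EffectSize",
    "MODEL_IDS",
    "fit_ar1",
    "aicc",
    "candidate_set",
    "build_design",
    "fit_candidates",
    "select_model",
    "combine_effect",
    "percent_change_of_effect",
]

MODEL_IDS = ("baseline", "quad_P", "quad_T", "quad_both", "inter_PxC", "inter_TxC")

_RHO_BOUND = 0.999


@dataclass(frozen=True)
class CandidateModel:
    """One candidate regression structure for a population."""

    model_id: str
    terms: tuple[str, ...]

    @property
    def k(self) -> int:
        # parameters counted for AICc: coefficients + rho + innovation variance
        return len(self.terms) + 2


@dataclass
class ModelFit:
    """A fitted candidate: coefficients, SEs, rho, log-likelihood, AICc."""

    model_id: str
    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    rho: dict[str, float]  # replicate id -> rho ("0" when unreplicated)
    sigma: float
    loglik: float
    n: int
    k: int
    aicc: float
    converged: bool = True
    method: str = "ml"

    def __post_init__(self) -> None:
        if not np.isfinite(self.aicc):
            raise ValueError("AICc must be finite")
        if self.n <= self.k + 1:
            raise ValueError(f"n = {self.n} too small for k = {self.k} parameters")


@dataclass
class EffectSize:
    """A population's climate effect on log(lambda) per 1-SD anomaly."""

    pop_id: str
    variable: str  # precip | temp
    beta: float
    se: float
    model_id: str = "baseline"
    rho: float = 0.0
    n_years: int = 0
    wai: float = np.nan
    mat: float = np.nan
    generation_time: float = np.nan
    plant_type: str = ""

    def __post_init__(self) -> None:
        if self.variable not in ("precip", "temp"):
            raise ValueError("variable must be 'precip' or 'temp'")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not self.se > 0:
            raise ValueError("se must be positive")


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n = {n} must exceed k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _prais_winsten(
    y: np.ndarray, X: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    ystar = np.empty_like(y)
    Xstar = np.empty_like(X)
    r = np.sqrt(1.0 - rho**2)
    ystar[0] = r * y[0]
    Xstar[0] = r * X[0]
    ystar[1:] = y[1:] - rho * y[:-1]
    Xstar[1:] = X[1:] - rho * X[:-1]
    return ystar, Xstar


def _gls_given_rho(
    y: np.ndarray,
    X: np.ndarray,
    blocks: list[np.ndarray],
    rhos: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """GLS coefficients for fixed per-block rho; returns (b, ystar, Xstar, logdet)."""
    ystar = np.empty_like(y)
    Xstar = np.empty_like(X)
    logdet = 0.0
    for idx, rho in zip(blocks, rhos):
        ys, Xs = _prais_winsten(y[idx], X[idx], rho)
        ystar[idx] = ys
        Xstar[idx] = Xs
        logdet += -np.log(1.0 - rho**2)  # log|Sigma(rho)| up to sigma^2 factor
    b, *_ = np.linalg.lstsq(Xstar, ystar, rcond=None)
    return b, ystar, Xstar, logdet


def _concentrated_negloglik(
    rhos: np.ndarray, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]
) -> float:
    n = y.size
    _, ystar, Xstar, logdet = _gls_given_rho(y, X, blocks, rhos)
    b, *_ = np.linalg.lstsq(Xstar, ystar, rcond=None)
    rss = float(np.sum((ystar - Xstar @ b) ** 2))
    if rss <= 0:
        rss = np.finfo(float).tiny
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return -ll


def fit_ar1(
    y: Sequence[float],
    X: np.ndarray,
    *,
    term_names: Sequence[str] | None = None,
    replicate_ids: Sequence | None = None,
    model_id: str = "baseline",
    rho_fixed: float | None = None,
) -> ModelFit:
    """Maximum-likelihood regression with stationary AR(1) errors.

    Parameters
    ----------
    y : array-like
        Response (log lambda), ordered by year within replicate.
    X : ndarray, shape (n, p)
        Design matrix including the intercept column.
    replicate_ids : optional
        When given, one rho is estimated per replicate while coefficients
        are shared; each replicate's rows must be contiguous in time.
    rho_fixed : optional
        Fix rho instead of estimating it (e.g. 0 for an OLS-equivalent
        fit). Fixed rho is still counted in k so AICc values remain
        comparable across candidates.

    Standard errors come from the GLS information matrix at the ML rho,
    with the residual variance df-corrected (n - p).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    n, p = X.shape
    names = list(term_names) if term_names is not None else [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("term_names length must match number of columns")
    k = p + 2  # coefficients + rho + innovation variance
    if n <= k + 1:
        raise ValueError(
            f"series length n = {n} too short to fit {p} coefficients "
            f"plus AR(1) parameters (need n > {k + 1})"
        )
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient (collinear columns)")

    if replicate_ids is None:
        blocks = [np.arange(n)]
        block_labels = ["0"]
    else:
        replicate_ids = np.asarray(replicate_ids)
        block_labels = [str(r) for r in dict.fromkeys(replicate_ids)]
        blocks = [np.where(replicate_ids == r)[0] for r in dict.fromkeys(replicate_ids)]
        for idx in blocks:
            if not (np.diff(idx) == 1).all():
                raise ValueError("each replicate's rows must be contiguous")

    method = "ml"
    if rho_fixed is not None:
        rhos = np.full(len(blocks), float(rho_fixed))
    elif len(blocks) == 1:
        res = optimize.minimize_scalar(
            lambda r: _concentrated_negloglik(np.array([r]), y, X, blocks),
            bounds=(-_RHO_BOUND, _RHO_BOUND),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rhos = np.array([float(res.x)])
    else:
        x0 = np.zeros(len(blocks))
        res = optimize.minimize(
            _concentrated_negloglik,
            x0,
            args=(y, X, blocks),
            method="L-BFGS-B",
            bounds=[(-_RHO_BOUND, _RHO_BOUND)] * len(blocks),
        )
        if not res.success:
            # iterated feasible-GLS (Cochrane-Orcutt style) fallback
            method = "fgls"
            rhos = np.zeros(len(blocks))
            for _ in range(50):
                b, ystar, Xstar, _ = _gls_given_rho(y, X, blocks, rhos)
                resid = y - X @ b
                new = np.array(
                    [
                        _lag1_corr(resid[idx]) if idx.size > 2 else 0.0
                        for idx in blocks
                    ]
                )
                new = np.clip(new, -_RHO_BOUND, _RHO_BOUND)
                if np.max(np.abs(new - rhos)) < 1e-8:
                    rhos = new
                    break
                rhos = new
            else:
                raise RuntimeError(
                    "AR(1) fit did not converge (L-BFGS-B and iterated GLS both "
                    f"failed); replicates = {block_labels}, n = {n}"
                )
        else:
            rhos = np.asarray(res.x, dtype=float)

    b, ystar, Xstar, logdet = _gls_given_rho(y, X, blocks, rhos)
    resid_star = ystar - Xstar @ b
    rss = float(resid_star @ resid_star)
    sigma2_ml = max(rss / n, np.finfo(float).tiny)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0) - 0.5 * logdet
    dof = max(n - p, 1)
    sigma2_df = rss / dof
    XtX = Xstar.T @ Xstar
    cov = sigma2_df * np.linalg.inv(XtX)
    bse = np.sqrt(np.diag(cov))

    return ModelFit(
        model_id=model_id,
        terms=tuple(names),
        params=dict(zip(names, map(float, b))),
        bse=dict(zip(names, map(float, bse))),
        rho=dict(zip(block_labels, map(float, rhos))),
        sigma=float(np.sqrt(sigma2_ml)),
        loglik=float(loglik),
        n=n,
        k=k,
        aicc=aicc(float(loglik), k, n),
        method=method,
    )


def _lag1_corr(r: np.ndarray) -> float:
    r = r - r.mean()
    denom = float(r @ r)
    if denom == 0:
        return 0.0
    return float(r[:-1] @ r[1:] / denom)


def candidate_set(
    n_years: int,
    has_covariate: bool,
    covariate_varies: bool = True,
    *,
    quad_threshold: int = 14,
) -> list[CandidateModel]:
    """Admissible candidate models for a population.

    The baseline is always fit; quadratic variants only for series longer
    than 14 years (model selection between linear and quadratic forms is
    unreliable below that); interaction variants only when a non-climatic
    covariate exists and varies within the population (a constant
    covariate is implicitly absorbed by the intercept).
    """
    if n_years < 6:
        raise ValueError(f"n_years = {n_years} below the minimum of 6 transitions")
    base = ("intercept", "P", "T")
    out = [CandidateModel("baseline", base)]
    if n_years > quad_threshold:
        out.append(CandidateModel("quad_P", base + ("P2",)))
        out.append(CandidateModel("quad_T", base + ("T2",)))
        out.append(CandidateModel("quad_both", base + ("P2", "T2")))
    if has_covariate and covariate_varies:
        out.append(CandidateModel("inter_PxC", base + ("C", "PxC")))
        out.append(CandidateModel("inter_TxC", base + ("C", "TxC")))
    return out


def build_design(
    P: np.ndarray,
    T: np.ndarray,
    model: CandidateModel,
    covariate: np.ndarray | None = None,
) -> np.ndarray:
    """Design matrix for one candidate, columns ordered as model.terms."""
    cols = {
        "intercept": np.ones_like(np.asarray(P, dtype=float)),
        "P": np.asarray(P, dtype=float),
        "T": np.asarray(T, dtype=float),
    }
    cols["P2"] = cols["P"] ** 2
    cols["T2"] = cols["T"] ** 2
    if covariate is not None:
        C = np.asarray(covariate, dtype=float)
        cols["C"] = C
        cols["PxC"] = cols["P"] * C
        cols["TxC"] = cols["T"] * C
    try:
        return np.column_stack([cols[t] for t in model.terms])
    except KeyError as e:
        raise ValueError(f"model {model.model_id} needs a covariate") from e


def fit_candidates(
    y: Sequence[float],
    P: np.ndarray,
    T: np.ndarray,
    covariate: np.ndarray | None = None,
    replicate_ids: Sequence | None = None,
    quad_threshold: int = 14,
) -> list[ModelFit]:
    """Fit every admissible candidate; candidates that fail are dropped."""
    y = np.asarray(y, dtype=float)
    has_cov = covariate is not None
    varies = bool(has_cov and np.ptp(np.asarray(covariate, dtype=float)) > 0)
    fits = []
    for cand in candidate_set(y.size, has_cov, varies, quad_threshold=quad_threshold):
        X = build_design(P, T, cand, covariate)
        if y.size <= cand.k + 1:
            continue  # series too short for this candidate's parameter count
        try:
            fits.append(
                fit_ar1(
                    y,
                    X,
                    term_names=cand.terms,
                    replicate_ids=replicate_ids,
                    model_id=cand.model_id,
                )
            )
        except (ValueError, RuntimeError) as e:
            warnings.warn(f"candidate {cand.model_id} failed: {e}", stacklevel=2)
    if not fits:
        raise RuntimeError("no candidate model could be fit")
    return fits


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Minimum-AICc fit; near-ties go to fewer parameters, then baseline."""
    if not fits:
        raise ValueError("no fits to select from")
    best = min(f.aicc for f in fits)
    tied = [f for f in fits if f.aicc - best < 1e-9]
    tied.sort(key=lambda f: (f.k, f.model_id != "baseline"))
    return tied[0]


def combine_effect(
    fit: ModelFit,
    variable: str,
    *,
    covariate_mean: float | None = None,
    covariate_kind: str = "none",
    se_combine: str = "sum",
) -> tuple[float, float]:
    """Single effect size (and SE) for one climate variable.

    Baseline: the linear coefficient as-is. Quadratic: linear + quadratic
    coefficient. Interaction with a continuous covariate: linear +
    interaction x mean covariate; with a categorical covariate: linear +
    interaction x 0.5 (the mean effect across the two categories).
    Combined SEs are the arithmetic sum of the two terms' SEs by default
    (``se_combine='quadrature'`` switches to the root-sum-of-squares).
    """
    if variable not in ("precip", "temp"):
        raise ValueError("variable must be 'precip' or 'temp'")
    lin = "P" if variable == "precip" else "T"
    if lin not in fit.params:
        raise ValueError(f"model {fit.model_id} has no {variable} term")
    beta = fit.params[lin]
    se = fit.bse[lin]
    extra: tuple[float, float] | None = None

    quad = lin + "2"
    if quad in fit.params:
        extra = (fit.params[quad], fit.bse[quad])
    inter = lin + "xC"
    if inter in fit.params:
        if covariate_kind == "continuous":
            if covariate_mean is None:
                raise ValueError("covariate_mean required for a continuous covariate")
            extra = (fit.params[inter] * covariate_mean, fit.bse[inter])
        else:
            extra = (fit.params[inter] * 0.5, fit.bse[inter])

    if extra is not None:
        beta = beta + extra[0]
        if se_combine == "sum":
            se = se + extra[1]
        elif se_combine == "quadrature":
            se = float(np.hypot(se, extra[1]))
        else:
            raise ValueError("se_combine must be 'sum' or 'quadrature'")
    return float(beta), float(se)


def percent_change_of_effect(beta_without: float, beta_with: float) -> float:
    """Percent change in effect magnitude when a model term is added.

    Negative values are reductions: an effect moving from -0.189 to -0.158
    changes by -16.4%.
    """
    if beta_without == 0:
        raise ValueError("reference effect is zero; percent change undefined")
    return 100.0 * (abs(beta_with) - abs(beta_without)) / abs(beta_without)
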