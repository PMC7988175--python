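"""Seeded synthetic studies with known climate responses.

Generates monthly site climate, anomaly-driven yearly vital rates, and the
resulting annual projection matrices, so that every downstream stage of
the analysis (per-population AR(1) regression, model selection,
meta-regression) can be checked by parameter recovery.

The generative model mirrors the statistical structure the analysis
assumes: for each population, yearly log(lambda) follows

    log(lambda)_y = alpha + beta_p P_y + beta_t T_y
                    (+ quadratic and covariate-interaction terms)
                    + eps_y,        eps_y = rho eps_{y-1} + eta_y

with P, T the standardized climate anomalies of the census window and
eta_y white noise. The yearly matrix is obtained from the population's
baseline matrix by scaling fecundities (and survivals, capped so no
survival column sum exceeds 1) by a common factor found by root-finding
so that the dominant eigenvalue hits the target lambda exactly.

Conventions: a matrix stamped with census year y describes the transition
ending at the census of year y, and is paired with the anomaly of the 12
months preceding that census.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import climate as clim
from . import demography as dem

__all__ = [
    "SiteSpec",
    "PopulationSpec",
    "StudyConfig",
    "generate_climate",
    "generate_population",
    "generate_study",
    "make_ensemble",
    "population_seed",
]

PLANT_TYPES = ("graminoid", "herbaceous", "fern", "woody", "succulent")


@dataclass
class SiteSpec:
    """Monthly climate distribution of one site.

    Means/SDs are per calendar month (12 values each); precipitation in
    mm/month, temperature in deg C. ``pet_annual`` (mm/yr) feeds the water
    availability index. ``n_years`` must hold a 40-year baseline plus at
    least six annual transitions.
    """

    site_id: str
    monthly_precip_mean: Sequence[float]
    monthly_precip_sd: Sequence[float]
    monthly_temp_mean: Sequence[float]
    monthly_temp_sd: Sequence[float]
    pet_annual: float
    n_years: int = 46
    census_month: int = 1
    start_year: int = 1961

    def __post_init__(self) -> None:
        for name in (
            "monthly_precip_mean",
            "monthly_precip_sd",
            "monthly_temp_mean",
            "monthly_temp_sd",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (12,):
                raise ValueError(f"{name} must have 12 values, got {v.shape}")
            setattr(self, name, v)
        if (self.monthly_precip_sd < 0).any() or (self.monthly_temp_sd < 0).any():
            raise ValueError("monthly SDs must be nonnegative")
        if (self.monthly_precip_mean < 0).any():
            raise ValueError("monthly precipitation means must be nonnegative")
        if self.n_years <= 0:
            raise ValueError(f"n_years must be positive, got {self.n_years}")
        if self.n_years < 46:
            raise ValueError(
                f"n_years = {self.n_years} too short for a 40-year baseline "
                "plus six transitions (need >= 46)"
            )
        if not 1 <= self.census_month <= 12:
            raise ValueError("census_month must be in 1..12")

    @property
    def map_annual(self) -> float:
        """Expected mean annual precipitation (mm/yr)."""
        return float(np.sum(self.monthly_precip_mean))

    @property
    def mat_annual(self) -> float:
        """Expected mean annual temperature (deg C)."""
        return float(np.mean(self.monthly_temp_mean))


@dataclass
class PopulationSpec:
    """A population with known climate-response coefficients.

    The baseline life cycle is a stage ladder: stage i survives with
    probability ``baseline_survivals[i]`` and, conditional on survival,
    advances to stage i+1 with probability ``baseline_growth[i]`` (the
    last stage has no advancement); ``baseline_fecundities[i]`` recruits
    per stage-i individual enter stage 1. Climate coefficients act on the
    log(lambda) scale per 1-SD anomaly.
    """

    pop_id: str
    site_id: str
    plant_type: str = "herbaceous"
    n_stages: int = 2
    baseline_survivals: Sequence[float] = (0.5, 0.8)
    baseline_growth: Sequence[float] = (0.6, 0.0)
    baseline_fecundities: Sequence[float] = (0.0, 1.5)
    beta_p: float = 0.0
    beta_t: float = 0.0
    beta_p2: float = 0.0
    beta_t2: float = 0.0
    covariate_kind: str = "none"  # none | discrete | continuous
    beta_x: float = 0.0
    beta_px_or_tx: float = 0.0
    interaction_with: str = "precip"  # precip | temp
    noise_sd: float = 0.0
    rho_true: float = 0.0
    n_transitions: int = 6

    def __post_init__(self) -> None:
        if self.plant_type not in PLANT_TYPES:
            raise ValueError(
                f"plant_type must be one of {PLANT_TYPES}, got {self.plant_type!r}"
            )
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        surv = np.asarray(self.baseline_survivals, dtype=float)
        grow = np.asarray(self.baseline_growth, dtype=float)
        fec = np.asarray(self.baseline_fecundities, dtype=float)
        for name, v in (
            ("baseline_survivals", surv),
            ("baseline_growth", grow),
            ("baseline_fecundities", fec),
        ):
            if v.shape != (self.n_stages,):
                raise ValueError(f"{name} must have n_stages = {self.n_stages} values")
        if ((surv < 0) | (surv > 1)).any() or ((grow < 0) | (grow > 1)).any():
            raise ValueError("survival and growth must be probabilities in [0, 1]")
        if (fec < 0).any():
            raise ValueError("fecundities must be nonnegative")
        self.baseline_survivals = surv
        self.baseline_growth = grow
        self.baseline_fecundities = fec
        if self.covariate_kind not in ("none", "discrete", "continuous"):
            raise ValueError(f"unknown covariate_kind {self.covariate_kind!r}")
        if self.interaction_with not in ("precip", "temp"):
            raise ValueError("interaction_with must be 'precip' or 'temp'")
        if not -1 < self.rho_true < 1:
            raise ValueError("rho_true must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_transitions < 6:
            raise ValueError(
                f"n_transitions = {self.n_transitions} below the minimum of 6"
            )

    def baseline_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.n_stages
        U = np.zeros((s, s))
        F = np.zeros((s, s))
        for j in range(s):
            sv, g = self.baseline_survivals[j], self.baseline_growth[j]
            if j < s - 1:
                U[j + 1, j] = sv * g
                U[j, j] = sv * (1 - g)
            else:
                U[j, j] = sv
            F[0, j] = self.baseline_fecundities[j]
        return U, F


def population_seed(master_seed: int, pop_id: str) -> np.random.SeedSequence:
    """Per-population seed stream via stable hashing of pop_id.

    Independent of the order in which populations are generated.
    """
    digest = hashlib.sha256(pop_id.encode("utf-8")).digest()
    h = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.SeedSequence([int(master_seed) % (2**31), h])


def generate_climate(spec: SiteSpec, seed: int | np.random.SeedSequence) -> clim.ClimateSeries:
    """Draw monthly climate from the site's stated normal distributions.

    Each month is drawn independently; precipitation draws below zero are
    redrawn (truncation at 0), temperatures are untruncated. tmin/tmax are
    placed symmetrically +-2 deg C around the drawn monthly mean so that
    (tmin + tmax)/2 reproduces it exactly.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    rows = []
    for y in years:
        precip = rng.normal(spec.monthly_precip_mean, spec.monthly_precip_sd)
        for _ in range(1000):
            neg = precip < 0
            if not neg.any():
                break
            precip[neg] = rng.normal(
                spec.monthly_precip_mean[neg], spec.monthly_precip_sd[neg]
            )
        else:
            raise RuntimeError("precipitation truncation failed to converge")
        tmean = rng.normal(spec.monthly_temp_mean, spec.monthly_temp_sd)
        for m in range(12):
            rows.append(
                {
                    "year": int(y),
                    "month": m + 1,
                    "precip_mm": precip[m],
                    "tmin_c": tmean[m] - 2.0,
                    "tmax_c": tmean[m] + 2.0,
                }
            )
    return clim.ClimateSeries(site_id=spec.site_id, records=pd.DataFrame(rows))


def _scaled_matrices(
    U0: np.ndarray, F0: np.ndarray, c: float
) -> tuple[np.ndarray, np.ndarray]:
    # Scale survivals per column only while headroom allows (column sum <= 1);
    # fecundities absorb the rest of the scaling.
    colsums = U0.sum(axis=0)
    with np.errstate(divide="ignore"):
        caps = np.where(colsums > 0, 1.0 / colsums, np.inf)
    factors = np.minimum(c, caps)
    return U0 * factors[np.newaxis, :], F0 * c


def scale_to_lambda(
    U0: np.ndarray, F0: np.ndarray, target_lambda: float
) -> tuple[np.ndarray, np.ndarray]:
    """Find the common factor putting the dominant eigenvalue at target_lambda.

    Monotone 1-D root-finding on the factor; survival columns are capped at
    sum 1, beyond which only fecundities keep growing. Raises if the target
    is unreachable (e.g. no reproduction and all survival columns capped).
    """
    if target_lambda <= 0:
        raise ValueError("target lambda must be positive")

    def lam(c: float) -> float:
        U, F = _scaled_matrices(U0, F0, c)
        return float(np.max(np.abs(np.linalg.eigvals(U + F))))

    lo, hi = 1e-12, 1.0
    f = lambda c: lam(c) - target_lambda
    it = 0
    while f(hi) < 0:
        hi *= 4.0
        it += 1
        if it > 60:
            raise ValueError(
                f"target lambda {target_lambda:.4g} unreachable by scaling "
                "(survival capped and fecundity cannot compensate)"
            )
    while f(lo) > 0:
        lo /= 4.0
        if lo < 1e-300:
            raise ValueError(f"target lambda {target_lambda:.4g} unreachable (too small)")
    c = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return _scaled_matrices(U0, F0, c)


def ar1_noise(
    n: int, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise: eps_1 ~ N(0, sd^2/(1-rho^2))."""
    eps = np.zeros(n)
    if sd == 0:
        return eps
    eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho**2))
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        eps[t] = rho * eps[t - 1] + innov[t - 1]
    return eps


def make_covariate(
    kind: str, n: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Yearly non-climatic covariate values: 0/1 (discrete) or N(0,1)."""
    if kind == "none":
        return None
    if kind == "discrete":
        return rng.integers(0, 2, size=n).astype(float)
    if kind == "continuous":
        return rng.normal(0.0, 1.0, size=n)
    raise ValueError(f"unknown covariate kind {kind!r}")


def target_log_lambdas(
    pspec: PopulationSpec,
    alpha: float,
    P: np.ndarray,
    T: np.ndarray,
    covariate: np.ndarray | None,
    eps: np.ndarray,
) -> np.ndarray:
    """Linear predictor + AR(1) noise for each transition year."""
    g = alpha + pspec.beta_p * P + pspec.beta_t * T
    g = g + pspec.beta_p2 * P**2 + pspec.beta_t2 * T**2
    if covariate is not None:
        inter = P if pspec.interaction_with == "precip" else T
        g = g + pspec.beta_x * covariate + pspec.beta_px_or_tx * covariate * inter
    return g + eps


def generate_population(
    pspec: PopulationSpec,
    anomalies: clim.AnomalySeries,
    seed: int | np.random.SeedSequence,
    covariate: np.ndarray | None = None,
) -> list[dem.ProjectionModel]:
    """Yearly projection matrices whose log(lambda) follows the known model.

    The last ``n_transitions`` census years of ``anomalies`` are used; the
    matrix stamped with census year y realizes the target log(lambda) for
    the transition ending at that census.
    """
    if len(anomalies.census_years) < pspec.n_transitions:
        raise ValueError(
            f"anomalies cover {len(anomalies.census_years)} census years; "
            f"{pspec.n_transitions} required"
        )
    rng = np.random.default_rng(seed)
    years = anomalies.census_years[-pspec.n_transitions:]
    sel = np.isin(anomalies.census_years, years)
    P, T = anomalies.P[sel], anomalies.T[sel]
    if covariate is not None and len(covariate) != pspec.n_transitions:
        raise ValueError("covariate length must equal n_transitions")

    U0, F0 = pspec.baseline_matrices()
    alpha = float(np.log(dem.lambda_of(U0 + F0)))
    eps = ar1_noise(pspec.n_transitions, pspec.rho_true, pspec.noise_sd, rng)
    targets = target_log_lambdas(pspec, alpha, P, T, covariate, eps)

    models = []
    for y, g in zip(years, targets):
        U, F = scale_to_lambda(U0, F0, float(np.exp(g)))
        models.append(
            dem.ProjectionModel(pop_id=pspec.pop_id, census_year=int(y), U=U, F=F)
        )
    return models


@dataclass
class StudyConfig:
    """An ensemble of sites and populations forming one synthetic study."""

    sites: list[SiteSpec]
    populations: list[PopulationSpec]
    baseline_years: int = 40
    meta: dict = field(default_factory=dict)  # free-form truth annotations

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("a study needs at least one population")
        pop_ids = [p.pop_id for p in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            dupes = sorted({p for p in pop_ids if pop_ids.count(p) > 1})
            raise ValueError(f"pop_id collision: {dupes}")
        site_ids = {s.site_id for s in self.sites}
        for p in self.populations:
            if p.site_id not in site_ids:
                raise ValueError(f"population {p.pop_id!r} references unknown site {p.site_id!r}")


def _census_years_for(site: SiteSpec, n_transitions: int) -> np.ndarray:
    last = site.start_year + site.n_years - 1
    return np.arange(last - n_transitions + 1, last + 1)


def generate_study(
    config: StudyConfig, seed: int, out_dir: str | Path
) -> dict[str, Path]:
    """Write a complete on-disk study fixture with ground truth.

    Produces matrices.csv (long format), climate.csv, sites.csv,
    populations.csv, covariates.csv (when any population has one) and
    truth.json. Byte-identical for a fixed seed.
    """
    from . import io as dio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    site_by_id = {s.site_id: s for s in config.sites}

    climates = {}
    anomalies = {}
    for site in config.sites:
        ss = np.random.SeedSequence(
            [int(seed) % (2**31), int.from_bytes(hashlib.sha256(site.site_id.encode()).digest()[:4], "big") % (2**31)]
        )
        climates[site.site_id] = generate_climate(site, ss)

    all_models: list[dem.ProjectionModel] = []
    cov_rows = []
    truth: dict[str, dict] = {}
    for pspec in config.populations:
        site = site_by_id[pspec.site_id]
        years = _census_years_for(site, pspec.n_transitions)
        if pspec.site_id not in anomalies:
            # every census year with a complete 12-month window before it
            anomalies[pspec.site_id] = clim.build_anomalies(
                climates[pspec.site_id],
                site.census_month,
                _census_years_for(site, site.n_years - 1),
                baseline_years=config.baseline_years,
            )
        anom = anomalies[pspec.site_id]
        ss = population_seed(seed, pspec.pop_id)
        s_pop, s_cov = ss.spawn(2)
        covariate = make_covariate(
            pspec.covariate_kind, pspec.n_transitions, np.random.default_rng(s_cov)
        )
        models = generate_population(pspec, anom, s_pop, covariate=covariate)
        all_models.extend(models)
        if covariate is not None:
            for y, x in zip(years, covariate):
                cov_rows.append(
                    {"pop_id": pspec.pop_id, "census_year": int(y), "covariate": x}
                )
        U0, F0 = pspec.baseline_matrices()
        base = dem.ProjectionModel(pspec.pop_id, 0, U0, F0)
        truth[pspec.pop_id] = {
            "alpha": float(np.log(dem.lambda_of(base))),
            "beta_p": pspec.beta_p,
            "beta_t": pspec.beta_t,
            "beta_p2": pspec.beta_p2,
            "beta_t2": pspec.beta_t2,
            "beta_x": pspec.beta_x,
            "beta_interaction": pspec.beta_px_or_tx,
            "rho": pspec.rho_true,
            "noise_sd": pspec.noise_sd,
            "T_true": float(dem.generation_time(base)),
        }

    paths = {
        "matrices": out_dir / "matrices.csv",
        "climate": out_dir / "climate.csv",
        "sites": out_dir / "sites.csv",
        "populations": out_dir / "populations.csv",
        "truth": out_dir / "truth.json",
    }
    dio.write_matrices(all_models, paths["matrices"])
    dio.write_climate(list(climates.values()), paths["climate"])

    site_rows = [
        {
            "site_id": s.site_id,
            "census_month": s.census_month,
            "map_mm": s.map_annual,
            "pet_mm": s.pet_annual,
            "mat_c": s.mat_annual,
        }
        for s in config.sites
    ]
    pd.DataFrame(site_rows).to_csv(paths["sites"], index=False)
    pop_rows = [
        {
            "pop_id": p.pop_id,
            "site_id": p.site_id,
            "plant_type": p.plant_type,
            "covariate_kind": p.covariate_kind,
            "n_transitions": p.n_transitions,
        }
        for p in config.populations
    ]
    pd.DataFrame(pop_rows).to_csv(paths["populations"], index=False)
    if cov_rows:
        paths["covariates"] = out_dir / "covariates.csv"
        pd.DataFrame(cov_rows).to_csv(paths["covariates"], index=False)

    payload = {"populations": truth, "meta": dict(config.meta), "seed": int(seed)}
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths


def _default_site(site_id: str, rng: np.random.Generator, n_years: int = 90) -> SiteSpec:
    base_p = rng.uniform(20.0, 90.0)
    seasonal = base_p * 0.5 * np.sin(2 * np.pi * np.arange(12) / 12)
    precip_mean = np.clip(base_p + seasonal, 5.0, None)
    base_t = rng.uniform(2.0, 18.0)
    temp_mean = base_t + 8.0 * np.sin(2 * np.pi * (np.arange(12) - 3) / 12)
    return SiteSpec(
        site_id=site_id,
        monthly_precip_mean=precip_mean,
        monthly_precip_sd=0.35 * precip_mean,
        monthly_temp_mean=temp_mean,
        monthly_temp_sd=np.full(12, 1.2),
        pet_annual=rng.uniform(400.0, 1200.0),
        n_years=n_years,
        census_month=int(rng.integers(1, 13)),
    )


def make_ensemble(
    n_populations: int,
    seed: int,
    *,
    meta_slope_logT: float = -0.5,
    meta_intercept: float = -1.0,
    n_transitions_range: tuple[int, int] = (15, 40),
    rho_range: tuple[float, float] = (0.0, 0.6),
    noise_sd_range: tuple[float, float] = (0.05, 0.2),
    populations_per_site: int = 4,
) -> StudyConfig:
    """Ensemble with planted generation-time scaling of climate effects.

    Generation times are varied through adult survival and fecundity; each
    population's effect magnitudes are |beta| = exp(meta_intercept +
    meta_slope_logT * log T) with random sign, so a gamma log-link
    meta-regression of |beta| on log T has true slope ``meta_slope_logT``.
    Sites carry heterogeneous aridity (WAI) and mean temperature.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 911]))
    n_sites = max(1, int(np.ceil(n_populations / populations_per_site)))
    n_tr_hi = n_transitions_range[1]
    sites = [
        _default_site(f"site_{i:03d}", rng, n_years=max(46, 42 + n_tr_hi))
        for i in range(n_sites)
    ]
    pops = []
    types = list(PLANT_TYPES)
    for i in range(n_populations):
        site = sites[i % n_sites]
        # Adult survival spans short- to long-lived life cycles (T ~ 1.5-60 yr)
        s_adult = rng.uniform(0.05, 0.97)
        s_juv = rng.uniform(0.3, 0.7)
        g_juv = rng.uniform(0.4, 0.9)
        # long-lived species recruit rarely: keeps lambda near 1 and
        # spreads generation time over more than an order of magnitude
        fec = rng.uniform(0.8, 2.5) * (1.0 - s_adult)
        probe = PopulationSpec(
            pop_id=f"pop_{i:03d}",
            site_id=site.site_id,
            plant_type=types[i % len(types)],
            baseline_survivals=(s_juv, s_adult),
            baseline_growth=(g_juv, 0.0),
            baseline_fecundities=(0.0, fec),
        )
        U0, F0 = probe.baseline_matrices()
        T_true = dem.generation_time(dem.ProjectionModel(probe.pop_id, 0, U0, F0))
        mag_p = float(np.exp(meta_intercept + meta_slope_logT * np.log(T_true)))
        mag_t = float(np.exp(meta_intercept + meta_slope_logT * np.log(T_true)))
        pops.append(
            PopulationSpec(
                pop_id=probe.pop_id,
                site_id=probe.site_id,
                plant_type=probe.plant_type,
                baseline_survivals=probe.baseline_survivals,
                baseline_growth=probe.baseline_growth,
                baseline_fecundities=probe.baseline_fecundities,
                beta_p=mag_p * rng.choice([-1.0, 1.0]),
                beta_t=mag_t * rng.choice([-1.0, 1.0]),
                noise_sd=rng.uniform(*noise_sd_range),
                rho_true=rng.uniform(*rho_range),
                n_transitions=int(rng.integers(n_transitions_range[0], n_transitions_range[1] + 1)),
            )
        )
    return StudyConfig(
        sites=sites,
        populations=pops,
        meta={"meta_slope_logT": meta_slope_logT, "meta_intercept": meta_intercept},
    )
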