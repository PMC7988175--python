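"""End-to-end orchestration: matrices + climate in, meta-results out.

The pipeline reproduces the full analysis chain on any study laid out in
the package's CSV formats: yearly log(lambda) per population, census-
aligned standardized anomalies, per-population AR(1) candidate fits with
AICc selection, effect-size combination, the pooled mixed model, the four
meta-regression hypotheses (precipitation effects vs. water availability,
temperature effects vs. mean annual temperature, absolute effects of
either variable vs. log generation time), and the plant-type sensitivity
analysis. Every stage is seeded from the single config seed and the run
writes a manifest with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as clim
from . import demography as dem
from . import io as dio
from . import metareg, planttype, popfit

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("democlim")

EFFECTS_COLUMNS = [
    "pop_id",
    "variable",
    "beta",
    "se",
    "model_id",
    "rho",
    "n_years",
    "wai",
    "mat",
    "generation_time",
    "plant_type",
    "nonlinear",
]


@dataclass
class RunConfig:
    """Paths, analysis constants and the master seed for one run."""

    matrices_path: str
    climate_path: str
    sites_path: str
    populations_path: str
    covariates_path: str | None = None
    output_dir: str = "results"
    baseline_years: int = 40
    quad_threshold: int = 14  # quadratic terms only for series strictly longer
    n_datasets: int = 1000
    n_draws: int = 1000
    seed: int = 0
    sd_denominator: str = "n-1"  # baseline SD convention: "n-1" or "n"
    weighting: str = "inv_se"
    se_combine: str = "sum"
    fail_fast: bool = True
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.baseline_years < 30:
            raise ValueError("baseline_years must be >= 30")
        if self.quad_threshold <= 0 or self.n_datasets <= 0 or self.n_draws <= 0:
            raise ValueError("thresholds and draw counts must be positive")
        if self.sd_denominator not in ("n-1", "n"):
            raise ValueError("sd_denominator must be 'n-1' or 'n'")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_denominator == "n-1" else 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    effects: pd.DataFrame
    overall: metareg.OverallFit | None
    meta: dict[str, metareg.MetaResult]
    anova: dict[str, tuple[float, float]]
    tukey: dict[str, pd.DataFrame]
    reruns: dict[str, metareg.MetaResult]
    selection_log: list[dict]
    records: pd.DataFrame


def _to_effect_objects(effects: pd.DataFrame) -> list[popfit.EffectSize]:
    return [
        popfit.EffectSize(
            pop_id=r.pop_id,
            variable=r.variable,
            beta=r.beta,
            se=r.se,
            model_id=r.model_id,
            rho=r.rho,
            n_years=int(r.n_years),
            wai=r.wai,
            mat=r.mat,
            generation_time=r.generation_time,
            plant_type=r.plant_type,
        )
        for r in effects.itertuples()
    ]


def analyze_population(
    models: list[dem.ProjectionModel],
    anom: clim.AnomalySeries,
    *,
    covariate: pd.Series | None = None,
    covariate_kind: str = "none",
    quad_threshold: int = 14,
    se_combine: str = "sum",
) -> tuple[dict, pd.DataFrame, list[dict]]:
    """Candidate fits, selection and combined effects for one population.

    Returns (effects row dict per variable, per-year records, AICc log).
    """
    series = dem.log_lambda_series(models)
    years = series.index.to_numpy()
    sel = np.isin(anom.census_years, years)
    if sel.sum() != years.size:
        missing = sorted(set(years) - set(anom.census_years[sel]))
        raise ValueError(f"anomalies missing for census years {missing}")
    P, T = anom.P[sel], anom.T[sel]
    cov = None
    if covariate is not None:
        cov = covariate.reindex(years)
        if cov.isna().any():
            raise ValueError(
                f"covariate missing for census years "
                f"{cov.index[cov.isna()].tolist()}"
            )
        cov = cov.to_numpy(dtype=float)

    fits = popfit.fit_candidates(
        series.to_numpy(), P, T, covariate=cov, quad_threshold=quad_threshold
    )
    best = popfit.select_model(fits)
    log_rows = [
        {
            "pop_id": models[0].pop_id,
            "model_id": f.model_id,
            "aicc": f.aicc,
            "loglik": f.loglik,
            "k": f.k,
            "selected": f is best,
        }
        for f in sorted(fits, key=lambda f: f.aicc)
    ]

    cov_mean = float(np.mean(cov)) if cov is not None else None
    rho = float(np.mean(list(best.rho.values())))
    out = {}
    for variable in ("precip", "temp"):
        beta, se = popfit.combine_effect(
            best,
            variable,
            covariate_mean=cov_mean,
            covariate_kind=covariate_kind,
            se_combine=se_combine,
        )
        out[variable] = {
            "beta": beta,
            "se": se,
            "model_id": best.model_id,
            "rho": rho,
            "n_years": int(years.size),
            "nonlinear": best.model_id.startswith("quad"),
        }
    records = pd.DataFrame(
        {
            "pop_id": models[0].pop_id,
            "census_year": years,
            "log_lambda": series.to_numpy(),
            "P": P,
            "T": T,
        }
    )
    return out, records, log_rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the results bundle to disk."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        models = dio.read_matrices(config.matrices_path)
        climates = dio.read_climate(config.climate_path)
        sites = dio.read_sites(config.sites_path)
        pops = dio.read_populations(config.populations_path)
        covariates = (
            dio.read_covariates(config.covariates_path)
            if config.covariates_path
            else {}
        )

        by_pop: dict[str, list[dem.ProjectionModel]] = {}
        for m in models:
            by_pop.setdefault(m.pop_id, []).append(m)

        anomaly_cache: dict[str, clim.AnomalySeries] = {}
        effect_rows = []
        all_records = []
        selection_log: list[dict] = []
        for pop_id, pop_models in sorted(by_pop.items()):
            try:
                if pop_id not in pops.index:
                    raise ValueError(f"population {pop_id!r} missing from the site table")
                meta_row = pops.loc[pop_id]
                site_id = str(meta_row["site_id"])
                site = sites.loc[site_id]
                if site_id not in anomaly_cache:
                    years_all = sorted(
                        {m.census_year for ms in by_pop.values() for m in ms
                         if str(pops.loc[m.pop_id, "site_id"]) == site_id}
                    )
                    anomaly_cache[site_id] = clim.build_anomalies(
                        climates[site_id],
                        int(site["census_month"]),
                        years_all,
                        baseline_years=config.baseline_years,
                        ddof=config.ddof,
                    )
                anom = anomaly_cache[site_id]
                effects, records, log_rows = analyze_population(
                    sorted(pop_models, key=lambda m: m.census_year),
                    anom,
                    covariate=covariates.get(pop_id),
                    covariate_kind=str(meta_row.get("covariate_kind", "none")),
                    quad_threshold=config.quad_threshold,
                    se_combine=config.se_combine,
                )
                selection_log.extend(log_rows)
                for row in log_rows:
                    logger.info(
                        "pop=%s model=%s aicc=%.4f selected=%s",
                        row["pop_id"], row["model_id"], row["aicc"], row["selected"],
                    )
                gen_time = dem.generation_time(dem.mean_model(pop_models))
                wai = clim.water_availability_index(
                    float(site["map_mm"]), float(site["pet_mm"])
                )
                for variable, vals in effects.items():
                    effect_rows.append(
                        {
                            "pop_id": pop_id,
                            "variable": variable,
                            **vals,
                            "wai": wai,
                            "mat": float(site["mat_c"]),
                            "generation_time": gen_time,
                            "plant_type": str(meta_row["plant_type"]),
                        }
                    )
                all_records.append(records)
            except Exception as e:
                logger.error("pop=%s failed: %s", pop_id, e)
                if config.fail_fast:
                    raise RuntimeError(f"population {pop_id!r} failed: {e}") from e
                warnings.warn(f"skipping population {pop_id!r}: {e}", stacklevel=2)

        effects = pd.DataFrame(effect_rows, columns=EFFECTS_COLUMNS)
        records = pd.concat(all_records, ignore_index=True)
        effects.to_csv(out_dir / "effects.csv", index=False)

        overall = None
        if records["pop_id"].nunique() >= 2:
            overall = metareg.fit_overall(records)
            _write_json(out_dir / "overall.json", overall.to_dict())

        eff_objects = _to_effect_objects(effects)
        precip_eff = [e for e in eff_objects if e.variable == "precip"]
        temp_eff = [e for e in eff_objects if e.variable == "temp"]
        ss = np.random.SeedSequence(config.seed % (2**31))
        seeds = ss.spawn(6)
        meta_results = {
            "H2_precip_vs_WAI": metareg.simulate_meta(
                precip_eff, "WAI", "linear",
                n_datasets=config.n_datasets, n_draws=config.n_draws,
                seed=seeds[0], weighting=config.weighting,
            ),
            "H3_temp_vs_MAT": metareg.simulate_meta(
                temp_eff, "MAT", "linear",
                n_datasets=config.n_datasets, n_draws=config.n_draws,
                seed=seeds[1], weighting=config.weighting,
            ),
            "H4_precip_vs_logT": metareg.simulate_meta(
                precip_eff, "logT", "gamma_log",
                n_datasets=config.n_datasets, n_draws=config.n_draws,
                seed=seeds[2], weighting=config.weighting,
            ),
            "H4_temp_vs_logT": metareg.simulate_meta(
                temp_eff, "logT", "gamma_log",
                n_datasets=config.n_datasets, n_draws=config.n_draws,
                seed=seeds[3], weighting=config.weighting,
            ),
        }
        for name, result in meta_results.items():
            _write_json(out_dir / f"meta_{name}.json", result.to_dict())

        anova, tukey, reruns = {}, {}, {}
        for variable in ("precip", "temp"):
            try:
                anova[variable] = planttype.anova_by_type(eff_objects, variable)
                tukey[variable] = planttype.tukey_hsd(eff_objects, variable)
                tukey[variable].to_csv(
                    out_dir / f"tukey_{variable}.csv", index=False
                )
            except ValueError as e:
                logger.warning("plant-type test skipped for %s: %s", variable, e)
        _write_json(
            out_dir / "anova.json",
            {v: {"F": f, "p": p} for v, (f, p) in anova.items()},
        )
        # re-run the precipitation hypotheses without any divergent type
        if "precip" in tukey:
            flagged = sorted(
                set(tukey["precip"].loc[tukey["precip"]["reject"], "type_a"])
                | set(tukey["precip"].loc[tukey["precip"]["reject"], "type_b"])
            )
            counts = effects[effects["variable"] == "precip"][
                "plant_type"
            ].value_counts(normalize=True)
            for ptype in flagged:
                if counts.get(ptype, 0.0) > 0.78:
                    logger.info(
                        "not excluding dominant type %s (%.0f%% of effects)",
                        ptype, 100 * counts.get(ptype, 0.0),
                    )
                    continue
                try:
                    reruns[f"H2_excl_{ptype}"] = planttype.rerun_excluding(
                        precip_eff, ptype, "WAI", "linear",
                        seed=seeds[4],
                        n_datasets=config.n_datasets, n_draws=config.n_draws,
                        weighting=config.weighting,
                    )
                    reruns[f"H4_precip_excl_{ptype}"] = planttype.rerun_excluding(
                        precip_eff, ptype, "logT", "gamma_log",
                        seed=seeds[5],
                        n_datasets=config.n_datasets, n_draws=config.n_draws,
                        weighting=config.weighting,
                    )
                except ValueError as e:
                    logger.warning("rerun excluding %s skipped: %s", ptype, e)
            for name, result in reruns.items():
                _write_json(out_dir / f"meta_{name}.json", result.to_dict())

        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_populations": int(records["pop_id"].nunique()),
            "n_effects": int(len(effects)),
            "n_nonlinear": int(
                effects.loc[effects["variable"] == "precip", "nonlinear"].sum()
            ),
        }
        _write_json(out_dir / "manifest.json", manifest)

        if config.make_plots:
            from . import plots

            plots.plot_effects_bundle(effects, out_dir)

        return PipelineResult(
            effects=effects,
            overall=overall,
            meta=meta_results,
            anova=anova,
            tukey=tukey,
            reruns=reruns,
            selection_log=selection_log,
            records=records,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
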