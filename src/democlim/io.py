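"""Plain-text serialization of projection models and climate series.

Matrices travel in a long-format CSV — one row per matrix cell with the
survival/growth (U) and fecundity (F) components side by side:

    pop_id, year, stage_from, stage_to, U_value, F_value

with 1-based stage indices. Climate is one row per site-month:

    site_id, year, month, precip_mm, tmin_c, tmax_c
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .demography import ProjectionModel

__all__ = [
    "MATRIX_COLUMNS",
    "read_matrices",
    "write_matrices",
    "read_climate",
    "write_climate",
    "read_sites",
    "read_populations",
    "read_covariates",
]

MATRIX_COLUMNS = ["pop_id", "year", "stage_from", "stage_to", "U_value", "F_value"]


def write_matrices(models: Sequence[ProjectionModel], path: str | Path) -> Path:
    """Serialize models to the long-format CSV (every cell, zeros included)."""
    rows = []
    for m in sorted(models, key=lambda m: (m.pop_id, m.census_year)):
        s = m.n_stages
        for j in range(s):  # stage_from = column (origin stage)
            for i in range(s):  # stage_to = row (destination stage)
                rows.append(
                    {
                        "pop_id": m.pop_id,
                        "year": m.census_year,
                        "stage_from": j + 1,
                        "stage_to": i + 1,
                        "U_value": repr(float(m.U[i, j])),
                        "F_value": repr(float(m.F[i, j])),
                    }
                )
    path = Path(path)
    pd.DataFrame(rows, columns=MATRIX_COLUMNS).to_csv(path, index=False)
    return path


def read_matrices(path: str | Path) -> list[ProjectionModel]:
    """Read the long-format CSV back into validated projection models.

    Every (pop_id, year) block must form a complete square grid of stage
    indices 1..s; validation failures name the population and year.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; no models read", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path} has no records; no models read", stacklevel=2)
        return []
    missing = set(MATRIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")

    models = []
    for (pop_id, year), block in df.groupby(["pop_id", "year"], sort=True):
        stages = sorted(block["stage_from"].unique())
        s = len(stages)
        if stages != list(range(1, s + 1)) or sorted(
            block["stage_to"].unique()
        ) != list(range(1, s + 1)):
            raise ValueError(
                f"pop {pop_id!r}, year {year}: stage indices must be 1..{s}"
            )
        if len(block) != s * s:
            raise ValueError(
                f"pop {pop_id!r}, year {year}: expected {s * s} cells, "
                f"got {len(block)} (missing or duplicated entries)"
            )
        U = np.zeros((s, s))
        F = np.zeros((s, s))
        for _, r in block.iterrows():
            i, j = int(r["stage_to"]) - 1, int(r["stage_from"]) - 1
            U[i, j] = r["U_value"]
            F[i, j] = r["F_value"]
        try:
            models.append(
                ProjectionModel(pop_id=str(pop_id), census_year=int(year), U=U, F=F)
            )
        except ValueError as e:
            raise ValueError(f"pop {pop_id!r}, year {year}: {e}") from e
    return models


def write_climate(series: Sequence[ClimateSeries], path: str | Path) -> Path:
    frames = []
    for s in sorted(series, key=lambda s: s.site_id):
        df = s.records.copy()
        df.insert(0, "site_id", s.site_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["precip_mm"] = out["precip_mm"].map(lambda v: repr(float(v)))
    out["tmin_c"] = out["tmin_c"].map(lambda v: repr(float(v)))
    out["tmax_c"] = out["tmax_c"].map(lambda v: repr(float(v)))
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_climate(path: str | Path) -> dict[str, ClimateSeries]:
    """Read the climate CSV into one ClimateSeries per site."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"site_id", "year", "month", "precip_mm", "tmin_c", "tmax_c"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")
    return {
        str(site_id): ClimateSeries(
            site_id=str(site_id), records=block.drop(columns="site_id")
        )
        for site_id, block in df.groupby("site_id")
    }


def read_sites(path: str | Path) -> pd.DataFrame:
    """Site table: site_id, census_month, map_mm, pet_mm, mat_c."""
    df = pd.read_csv(path)
    missing = {"site_id", "census_month", "map_mm", "pet_mm", "mat_c"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")
    return df.set_index("site_id")


def read_populations(path: str | Path) -> pd.DataFrame:
    """Population table: pop_id, site_id, plant_type, covariate_kind."""
    df = pd.read_csv(path)
    missing = {"pop_id", "site_id", "plant_type"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")
    if "covariate_kind" not in df.columns:
        df["covariate_kind"] = "none"
    return df.set_index("pop_id")


def read_covariates(path: str | Path) -> dict[str, pd.Series]:
    """Optional per-population yearly covariates, keyed by pop_id."""
    df = pd.read_csv(path)
    missing = {"pop_id", "census_year", "covariate"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")
    return {
        str(pop_id): block.set_index("census_year")["covariate"].sort_index()
        for pop_id, block in df.groupby("pop_id")
    }
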