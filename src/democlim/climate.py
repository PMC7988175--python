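"""Census-aligned climate aggregation and standardized anomalies.

Monthly site climate (total precipitation, min/max temperature) is
aggregated over the 12 months preceding each population census; annual
values are standardized against a 40-year baseline into z-score anomalies.
A z-score of 1 therefore marks a year one baseline standard deviation
wetter (or warmer) than normal, which for a normal climate recurs roughly
every 6 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClimateSeries",
    "AnomalySeries",
    "census_annual",
    "standardized_anomalies",
    "skewness",
    "water_availability_index",
    "anomaly_return_interval",
    "build_anomalies",
]

CLIMATE_COLUMNS = ["site_id", "year", "month", "precip_mm", "tmin_c", "tmax_c"]


@dataclass
class ClimateSeries:
    """Monthly climate records for one site.

    ``records`` has columns year, month, precip_mm, tmin_c, tmax_c.
    """

    site_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        required = {"year", "month", "precip_mm", "tmin_c", "tmax_c"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"climate records missing columns: {sorted(missing)}")
        if not df["month"].between(1, 12).all():
            raise ValueError("months must be in 1..12")
        if df.duplicated(["year", "month"]).any():
            dup = df[df.duplicated(["year", "month"])].iloc[0]
            raise ValueError(
                f"duplicate record for year {int(dup['year'])}, month {int(dup['month'])}"
            )
        if (df["precip_mm"] < 0).any():
            raise ValueError("precipitation must be nonnegative")
        self.records = df.sort_values(["year", "month"]).reset_index(drop=True)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.records["year"].unique())


@dataclass
class AnomalySeries:
    """Standardized annual anomalies aligned to census years."""

    site_id: str
    census_years: np.ndarray
    P: np.ndarray  # precipitation z-scores
    T: np.ndarray  # temperature z-scores
    baseline_mean: dict = field(default_factory=dict)
    baseline_sd: dict = field(default_factory=dict)
    skewness: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.census_years = np.asarray(self.census_years, dtype=int)
        self.P = np.asarray(self.P, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if not (len(self.census_years) == len(self.P) == len(self.T)):
            raise ValueError("census_years, P and T must have equal length")
        for var, sd in self.baseline_sd.items():
            if sd <= 0:
                raise ValueError(f"baseline sd for {var} must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "census_year": self.census_years,
                "P_z": self.P,
                "T_z": self.T,
            }
        )


def census_annual(
    series: ClimateSeries, census_month: int, years: np.ndarray | list[int]
) -> pd.DataFrame:
    """Annual totals/means over the 12 months preceding each census.

    For a census in month m of year y the window runs from month m of
    year y-1 through month m-1 of year y (the census month itself is
    excluded). Precipitation is summed; temperature is the mean of
    (tmin + tmax) / 2 over the window.

    Returns a DataFrame with columns census_year, precip_total, temp_mean.
    """
    if not 1 <= census_month <= 12:
        raise ValueError("census_month must be in 1..12")
    df = series.records
    lookup = df.set_index(["year", "month"])
    out = []
    for y in years:
        y = int(y)
        window = [
            (y - 1, m) for m in range(census_month, 13)
        ] + [(y, m) for m in range(1, census_month)]
        missing = [key for key in window if key not in lookup.index]
        if missing:
            yr, mo = missing[0]
            raise ValueError(
                f"site {series.site_id!r}: missing climate for year {yr}, "
                f"month {mo} in the window of census year {y}"
            )
        sub = lookup.loc[window]
        precip = float(sub["precip_mm"].sum())
        temp = float(((sub["tmin_c"] + sub["tmax_c"]) / 2).mean())
        out.append({"census_year": y, "precip_total": precip, "temp_mean": temp})
    return pd.DataFrame(out)


def standardized_anomalies(
    values: np.ndarray | list[float],
    baseline: np.ndarray | list[float],
    *,
    ddof: int = 1,
    min_baseline: int = 30,
) -> np.ndarray:
    """z = (x - mean(baseline)) / sd(baseline).

    The baseline is nominally 40 years; at least ``min_baseline`` (default
    30, the conventional minimum for climate normals) are required. The
    standard deviation uses the n-1 denominator by default (``ddof=0``
    switches to n).
    """
    baseline = np.asarray(baseline, dtype=float)
    values = np.asarray(values, dtype=float)
    if baseline.size < min_baseline:
        raise ValueError(
            f"baseline has {baseline.size} values; at least {min_baseline} required"
        )
    sd = baseline.std(ddof=ddof)
    if sd == 0:
        raise ValueError("baseline standard deviation is zero")
    return (values - baseline.mean()) / sd


def skewness(values: np.ndarray | list[float], *, flag_threshold: float = 1.0):
    """Adjusted Fisher-Pearson sample skewness and a |skew| > 1 flag.

    The flag is report-only: strongly skewed anomaly distributions weaken
    the z-score interpretation but never drop data.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.allclose(values, values[0]):
        raise ValueError("skewness undefined for a constant vector")
    g = float(stats.skew(values, bias=False))
    return g, abs(g) > flag_threshold


def water_availability_index(map_mm: float, pet_mm: float) -> float:
    """WAI = mean annual precipitation - mean annual potential evapotranspiration.

    Both inputs in mm/yr; negative WAI marks water-limited (arid) sites.
    """
    if map_mm < 0 or pet_mm < 0:
        raise ValueError("MAP and PET must be nonnegative")
    return float(map_mm) - float(pet_mm)


def anomaly_return_interval(z: float) -> int:
    """Expected recurrence (years) of anomalies exceeding z, assuming normality.

    round(1 / P(Z > z)) for standard normal Z; z = 1 -> 6 years,
    z = 2 -> 44 years.
    """
    if z < 0:
        raise ValueError("z must be nonnegative")
    p = stats.norm.sf(z)
    return int(round(1.0 / p))


def build_anomalies(
    series: ClimateSeries,
    census_month: int,
    census_years: np.ndarray | list[int],
    *,
    baseline_years: int = 40,
    ddof: int = 1,
) -> AnomalySeries:
    """Full anomaly construction for one site.

    The baseline is the ``baseline_years`` census-aligned annual values
    ending with the last census year; census-year values are standardized
    against it. Skewness of the baseline annual values is recorded for
    both variables.
    """
    census_years = np.asarray(sorted(int(y) for y in census_years))
    last = int(census_years[-1])
    baseline_span = np.arange(last - baseline_years + 1, last + 1)
    annual = census_annual(series, census_month, baseline_span)
    annual = annual.set_index("census_year")
    base_p = annual["precip_total"].to_numpy()
    base_t = annual["temp_mean"].to_numpy()

    target = census_annual(series, census_month, census_years)
    P = standardized_anomalies(
        target["precip_total"].to_numpy(), base_p, ddof=ddof, min_baseline=30
    )
    T = standardized_anomalies(
        target["temp_mean"].to_numpy(), base_t, ddof=ddof, min_baseline=30
    )
    skew_p, _ = skewness(base_p)
    skew_t, _ = skewness(base_t)
    return AnomalySeries(
        site_id=series.site_id,
        census_years=census_years,
        P=P,
        T=T,
        baseline_mean={"precip": float(base_p.mean()), "temp": float(base_t.mean())},
        baseline_sd={
            "precip": float(base_p.std(ddof=ddof)),
            "temp": float(base_t.std(ddof=ddof)),
        },
        skewness={"precip": skew_p, "temp": skew_t},
    )
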