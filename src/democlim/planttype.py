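"""Plant-type sensitivity analysis.

Effect sizes are grouped into five plant types (graminoid, herbaceous
perennial, fern, woody, succulent; shrubs and trees are merged into
"woody"). A one-way ANOVA asks whether mean effect sizes differ between
types, Tukey's honestly significant difference test locates the pairwise
differences, and any divergent type can be excluded and the affected
meta-regression hypotheses re-run on the remaining effects. Tests are run
on the raw effect sizes, without weighting by their uncertainty.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .metareg import MetaResult, simulate_meta
from .popfit import EffectSize

__all__ = [
    "PLANT_TYPES",
    "group_by_type",
    "anova_by_type",
    "tukey_hsd",
    "rerun_excluding",
]

PLANT_TYPES = ("graminoid", "herbaceous", "fern", "woody", "succulent")

# Excluding a type this dominant leaves the rerun uninformative
_DOMINANT_FRACTION = 0.78


def _select(effects: Sequence[EffectSize], variable: str) -> list[EffectSize]:
    if variable not in ("precip", "temp"):
        raise ValueError("variable must be 'precip' or 'temp'")
    return [e for e in effects if e.variable == variable]


def group_by_type(
    effects: Sequence[EffectSize], variable: str
) -> dict[str, np.ndarray]:
    """Effect sizes of one climate variable grouped by plant type."""
    groups: dict[str, list[float]] = {}
    for e in _select(effects, variable):
        groups.setdefault(e.plant_type, []).append(e.beta)
    return {k: np.asarray(v) for k, v in sorted(groups.items())}


def anova_by_type(
    effects: Sequence[EffectSize], variable: str
) -> tuple[float, float]:
    """One-way ANOVA of effect sizes across plant types: (F, p-value)."""
    groups = group_by_type(effects, variable)
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError(
            f"ANOVA needs >= 2 plant types with >= 2 effects each; "
            f"got {sorted((k, v.size) for k, v in groups.items())}"
        )
    f_stat, p = stats.f_oneway(*usable.values())
    return float(f_stat), float(p)


def tukey_hsd(effects: Sequence[EffectSize], variable: str) -> pd.DataFrame:
    """All pairwise plant-type contrasts with studentized-range adjusted p.

    Returns a tidy frame: type_a, type_b, diff (mean_b - mean_a), p_adj,
    reject (at alpha = 0.05).
    """
    groups = group_by_type(effects, variable)
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError("Tukey HSD needs >= 2 plant types with >= 2 effects each")
    values = np.concatenate(list(usable.values()))
    labels = np.concatenate([[k] * v.size for k, v in usable.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=0.05)
    from itertools import combinations

    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "type_a": [a for a, _ in pairs],
            "type_b": [b for _, b in pairs],
            "diff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )


def rerun_excluding(
    effects: Sequence[EffectSize],
    excluded_type: str,
    predictor: str,
    family: str = "linear",
    *,
    variable: str | None = None,
    seed: int | np.random.SeedSequence | None = None,
    **meta_kwargs,
) -> MetaResult:
    """Re-run a meta-regression hypothesis without one plant type.

    ``variable`` restricts the rerun to effects of one climate variable
    (e.g. only precipitation effects of graminoids are dropped when the
    ANOVA flags precipitation). Excluding a type that dominates the data
    (> 78% of effects) emits a warning: the remaining sample no longer
    supports meaningful inference.
    """
    pool = list(effects) if variable is None else _select(effects, variable)
    n_total = len(pool)
    kept = [e for e in pool if e.plant_type != excluded_type]
    n_dropped = n_total - len(kept)
    if n_dropped > 0 and n_dropped / n_total > _DOMINANT_FRACTION:
        warnings.warn(
            f"excluded type {excluded_type!r} holds {n_dropped}/{n_total} effects; "
            "the rerun is unlikely to be informative",
            stacklevel=2,
        )
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} effects remain after excluding {excluded_type!r}"
        )
    return simulate_meta(kept, predictor, family, seed=seed, **meta_kwargs)
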