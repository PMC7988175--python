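"""Diagnostic plots: effect sizes against site and species predictors.

Point sizes are inversely proportional to the standard error of each
effect, so precisely estimated populations dominate visually the way they
dominate the weighted meta-regressions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_effect_vs_predictor", "plot_effects_bundle"]

_TYPE_COLORS = {
    "graminoid": "tab:olive",
    "herbaceous": "tab:green",
    "fern": "tab:cyan",
    "woody": "tab:brown",
    "succulent": "tab:orange",
}


def plot_effect_vs_predictor(
    effects: pd.DataFrame,
    variable: str,
    predictor_col: str,
    *,
    absolute: bool = False,
    ax=None,
    xlabel: str | None = None,
):
    """Scatter one climate variable's effect sizes against a predictor."""
    sub = effects[effects["variable"] == variable]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    y = sub["beta"].abs() if absolute else sub["beta"]
    x = sub[predictor_col]
    sizes = 20.0 / np.maximum(sub["se"], 1e-3)
    colors = [_TYPE_COLORS.get(t, "gray") for t in sub["plant_type"]]
    ax.scatter(x, y, s=np.clip(sizes, 5, 300), c=colors, alpha=0.6, edgecolors="none")
    if not absolute:
        ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel(xlabel or predictor_col)
    ax.set_ylabel(
        ("|effect|" if absolute else "effect") + f" of {variable} on log(λ)"
    )
    return ax


def plot_effects_bundle(effects: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Standard panel set: H2, H3 (signed) and H4 (absolute vs log T)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    effects = effects.copy()
    effects["logT"] = np.log(effects["generation_time"])
    panels = [
        ("precip", "wai", False, "water availability index (mm/yr)", "effects_precip_wai.png"),
        ("temp", "mat", False, "mean annual temperature (°C)", "effects_temp_mat.png"),
        ("precip", "logT", True, "log generation time", "effects_precip_logT.png"),
        ("temp", "logT", True, "log generation time", "effects_temp_logT.png"),
    ]
    paths = []
    for variable, col, absolute, label, fname in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        plot_effect_vs_predictor(
            effects, variable, col, absolute=absolute, ax=ax, xlabel=label
        )
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
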