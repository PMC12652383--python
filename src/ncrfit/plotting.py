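"""Plot helpers for pipeline output tables."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_delta_g"]

_LIMITATION_COLORS = {
    "carbon": "tab:green",
    "nitrogen": "tab:blue",
    "phosphorus": "tab:red",
    "sulfur": "tab:orange",
    "potassium": "tab:purple",
    "iron": "tab:brown",
}


def plot_delta_g(table: pd.DataFrame, ax=None):
    """Scatter dG_X/S versus dilution rate, colored by nutrient limitation.

    Expects the combined pipeline table (columns ``dilution_rate``,
    ``delta_g_x_s``, ``limitation``, optional ``bracket_lower/upper``).
    Recovery brackets, where available, are drawn as error bars.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for limitation, group in table.groupby(table["limitation"].fillna("unknown")):
        color = _LIMITATION_COLORS.get(limitation, "tab:gray")
        x = group["dilution_rate"]
        y = group["delta_g_x_s"]
        ax.scatter(x, y, color=color, label=f"{limitation}-limited", zorder=3)
        if {"bracket_lower", "bracket_upper"} <= set(group.columns):
            has = group["bracket_available"].fillna(False).astype(bool)
            sel = group[has]
            if len(sel):
                point = sel["delta_g_x_s"].to_numpy(float)
                yerr = [
                    point - sel["bracket_lower"].to_numpy(float),
                    sel["bracket_upper"].to_numpy(float) - point,
                ]
                ax.errorbar(
                    sel["dilution_rate"].to_numpy(float), point, yerr=yerr,
                    fmt="none", ecolor=color, alpha=0.6, capsize=3, zorder=2,
                )
    ax.set_xlabel("dilution rate (1/h)")
    ax.set_ylabel(r"$\Delta G_{X/S}$ (kJ per C-mol biomass)")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.legend(fontsize=8)
    return ax
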