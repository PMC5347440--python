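"""Plotting helpers for layer-specific trajectory analyses.

Thin matplotlib wrappers producing the standard panels: averaged
pressure/diameter curves over the (rescaled) normalized path length per
analysis layer, transit statistics versus cortical depth, and the
per-type pressure-drop decomposition.
"""

from __future__ import annotations

import numpy as np

AL_COLORS = ["#e6c300", "#8fce00", "#2e7d32", "#4fc3f7", "#1a3fa0"]


def plot_averaged_curves(curves: dict, ax=None, ylabel: str = "pressure [mmHg]"):
    """Layer-averaged curves from :func:`mvnflow.analysis.averaged_curves`,
    abscissa rescaled by each layer's mean total path length; capillary
    start/end positions are marked with circles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for al, data in sorted(curves.items()):
        color = AL_COLORS[(al - 1) % len(AL_COLORS)]
        ax.plot(data["s_scaled"] * 1e-3, data["mean_curve"], color=color, lw=2, label=f"AL {al}")
        for mark in ("mean_capillary_start_s_norm", "mean_capillary_end_s_norm"):
            s = data[mark]
            y = np.interp(s, data["s_norm"], data["mean_curve"])
            ax.plot([s * data["mean_s_tot"] * 1e-3], [y], "o", color=color, mfc="white")
    ax.set_xlabel("path length [mm]")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def plot_transit_statistics(layer_table, axes=None):
    """Three stacked panels: capillary transit time, transit path length
    and capillary RBC velocity per analysis layer (mean ± std)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(3, 1, sharex=True, figsize=(4, 7))
    panels = [
        ("tt_mean_s", "tt_std_s", "transit time [s]"),
        ("ts_mean_mm", "ts_std_mm", "transit path [mm]"),
        ("v_rbc_mean_mms", "v_rbc_std_mms", "RBC velocity [mm/s]"),
    ]
    x = layer_table["layer"]
    for ax, (mean, std, label) in zip(axes, panels):
        ax.errorbar(x, layer_table[mean], yerr=layer_table[std], fmt="o-", color="#2e7d32")
        ax.set_ylabel(label)
    axes[-1].set_xlabel("analysis layer")
    axes[-1].set_xticks(list(x))
    return axes


def plot_pressure_drop_by_type(drop_table, layer: int, ax=None):
    """Mean inlet pressure vs mean path length for one analysis layer,
    with error bars per vessel-type group."""
    import matplotlib.pyplot as plt

    group_colors = {"PA": "#b71c1c", "DA+A": "#e64a19", "C": "#2e7d32", "V+AV": "#1565c0", "PV": "#283593"}
    if ax is None:
        _, ax = plt.subplots()
    sub = drop_table[drop_table["layer"] == layer].sort_values("stage")
    ax.plot(sub["path_length_mean"] * 1e-3, sub["inlet_pressure_mean"], "-", color="0.6")
    for _, row in sub.iterrows():
        ax.errorbar(
            row["path_length_mean"] * 1e-3,
            row["inlet_pressure_mean"],
            yerr=row["inlet_pressure_std"] if np.isfinite(row["inlet_pressure_std"]) else None,
            fmt="o",
            color=group_colors[row["group"]],
            label=row["group"],
        )
    ax.set_xlabel("path length at type inlet [mm]")
    ax.set_ylabel("pressure [mmHg]")
    ax.set_title(f"AL {layer}")
    ax.legend(frameon=False, fontsize=8)
    return ax
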