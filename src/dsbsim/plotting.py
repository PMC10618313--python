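"""Matplotlib panels for sweep and frame diagnostics.

Small helpers that render the standard views of the analysis output:
cavity statistics and entanglements versus density, single-frame density
profiles, g(r) with the contact distances marked, and chain shape metrics
versus density.  All functions accept and return matplotlib Axes so they
compose into multi-panel figures.
"""
from __future__ import annotations

import numpy as np


def plot_cavities_vs_density(agg, ax=None):
    """n_cavities / V^C_max / V^C_total against ρ (aggregated sweep)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax2 = ax.twinx()
    ax.errorbar(agg["rho"], agg["n_cavities"],
                yerr=agg.get("n_cavities_err"), fmt="o-", color="tab:blue",
                label="number of cavities")
    ax2.errorbar(agg["rho"], agg["v_c_max"], yerr=agg.get("v_c_max_err"),
                 fmt="s--", color="tab:red", label="$V^C_{max}$")
    ax.set_xlabel(r"$\rho$ (nm$^{-3}$)")
    ax.set_ylabel("number of cavities")
    ax2.set_ylabel(r"$V^C_{max}$ (nm$^3$)")
    return ax


def plot_density_profile(edges, counts, ax=None, axis_label="Y"):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.stairs(counts, edges)
    ax.set_xlabel(f"{axis_label} (Å)")
    ax.set_ylabel("residue count")
    return ax


def plot_rdf(r, g, ax=None, mark_contacts=(5.0, 6.8)):
    """g(r) with the bb / bs contact distances marked."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(r, g)
    for x, name in zip(mark_contacts, ("bb", "bs")):
        ax.axvline(x, ls=":", color="gray")
        ax.annotate(name, (x, ax.get_ylim()[1] * 0.9))
    ax.set_xlabel("r (Å)")
    ax.set_ylabel("g(r)")
    return ax


def plot_shape_vs_density(agg, ax=None):
    """R_ee, R_g and W against ρ (three stacked panels)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, axes = plt.subplots(3, 1, sharex=True)
    else:
        axes = np.atleast_1d(ax)
    for a, col, label in zip(axes, ("ree", "rg", "w"),
                             (r"$R_{ee}$ (Å)", r"$R_g$ (Å)", "W")):
        a.errorbar(agg["rho"], agg[col], yerr=agg.get(f"{col}_err"),
                   fmt="o-")
        a.set_ylabel(label)
    axes[-1].set_xlabel(r"$\rho$ (nm$^{-3}$)")
    return axes
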