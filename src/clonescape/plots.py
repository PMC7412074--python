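"""Figures for the clonal-structure analysis (matplotlib, Axes-returning)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_mismatch_histogram",
    "plot_kinship_profiles",
    "plot_footprint_map",
    "plot_patch_regressions",
    "plot_richness_surface",
]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_mismatch_histogram(hist, ax=None):
    """Pairwise allelic mismatch histogram used to pick the MLL threshold."""
    ax = _ax(ax)
    ax.bar(np.arange(len(hist)), hist, color="0.4")
    ax.set_xlabel("pairwise allelic mismatches")
    ax.set_ylabel("number of pairs")
    return ax


def plot_kinship_profiles(ramet=None, genet=None, ax=None):
    """Overlay ramet- and genet-level distance-class kinship profiles."""
    ax = _ax(ax)
    for prof, color, marker in ((ramet, "black", "o"), (genet, "red", "^")):
        if prof is None:
            continue
        t = prof.table
        ax.plot(t["max_distance"], t["mean_fij"], color=color, marker=marker, label=prof.level)
        ax.fill_between(t["max_distance"], t["lower"], t["upper"], color=color, alpha=0.15)
        sig = t[t["significant"]]
        ax.scatter(sig["max_distance"], sig["mean_fij"], color=color, s=70, zorder=3)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("distance class upper bound (m)")
    ax.set_ylabel(r"kinship $F_{ij}$")
    ax.legend()
    return ax


def plot_footprint_map(units, partition, footprints, ax=None):
    """Map of genet footprints: circles = unique MLGs, triangles = pairs,
    x within polygon = genets with three or more ramets."""
    ax = _ax(ax)
    sizes = partition.clone_sizes()
    for f in footprints:
        xs, ys = f.polygon.exterior.xy
        if sizes[f.mlg_id] >= 3:
            ax.fill(xs, ys, alpha=0.3)
        else:
            ax.plot(xs, ys, lw=0.5, color="0.6")
    markers = {1: "o", 2: "^"}
    for u in units:
        ng = sizes[partition.mlg_of(u.sample_id)]
        ax.scatter(u.x, u.y, marker=markers.get(min(ng, 3), "x"), s=12, color="black")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_patch_regressions(stats, regressions, ax=None):
    """Scatter of R_p, E_H and S_mix against patch area with fitted lines."""
    ax = _ax(ax)
    complete = stats.dropna(subset=["A_P"])
    style = {"R_p": ("o", "-"), "E_H": ("s", "--"), "S_mix": ("^", ":")}
    xs = np.linspace(complete["A_P"].min(), complete["A_P"].max(), 50)
    for reg in regressions:
        m, ls = style[reg.response]
        ax.scatter(complete["A_P"], complete[reg.response], marker=m, s=18, label=reg.response)
        ax.plot(xs, reg.intercept + reg.slope * xs, ls=ls, color="0.2")
    ax.set_xlabel(r"patch area $A_P$ (m$^2$)")
    ax.set_ylabel("index value")
    ax.legend()
    return ax


def plot_richness_surface(surface, ax=None):
    """Masked local genotypic richness surface (grey = no species)."""
    ax = _ax(ax)
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("RdYlGn_r").copy()
    cmap.set_bad("0.8")
    vals = np.ma.masked_invalid(surface.values)
    im = ax.pcolormesh(surface.x, surface.y, vals, cmap=cmap, shading="nearest")
    ax.figure.colorbar(im, ax=ax, label="local genotypic richness")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax
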