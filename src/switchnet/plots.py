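"""Diagnostic figures: APCC hub histogram, heat cartography, degree
distribution, removal curves, and clustered distance heatmaps.

Colors follow the heat-cartography convention: red for positive APCC,
blue for negative.  All functions return the matplotlib Figure and
optionally save it to ``path``.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .cartography import RegionBounds

__all__ = [
    "plot_apcc_distribution",
    "plot_heat_cartography",
    "plot_degree_distribution",
    "plot_removal_curves",
    "plot_distance_heatmap",
]


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_apcc_distribution(ct: pd.DataFrame, path=None):
    """Histogram of hub APCC values; on trimodal data the negative mode is
    the fight-club population."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    hubs = ct[ct["hub"]]
    ax.hist(hubs["APCC"], bins=30, range=(-1, 1), color="#4878a8", edgecolor="white")
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("APCC (mean correlation with neighbors)")
    ax.set_ylabel("hub count")
    ax.set_title(f"APCC distribution of {len(hubs)} hubs")
    return _finish(fig, path)


def plot_heat_cartography(
    ct: pd.DataFrame, bounds: RegionBounds = RegionBounds(), path=None
):
    """(K_pi, z_g) scatter colored by APCC (red positive, blue negative),
    with the seven region boundaries drawn and switch genes circled."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    sc = ax.scatter(
        ct["K_pi"], ct["z_g"], c=ct["APCC"], cmap="RdBu_r", vmin=-1, vmax=1,
        s=18, edgecolor="none",
    )
    fig.colorbar(sc, ax=ax, label="APCC")
    switches = ct[ct["switch"]]
    if len(switches):
        ax.scatter(
            switches["K_pi"], switches["z_g"], facecolor="none",
            edgecolor="black", s=70, linewidths=1.2, label="switch genes",
        )
        ax.legend(loc="upper left", fontsize=8)
    z_lo, z_hi = ax.get_ylim()
    z_lo, z_hi = min(z_lo, -2), max(z_hi, 4)
    zc = bounds.z_cut
    ax.axhline(zc, color="k", lw=0.8)
    for x in (bounds.r1, bounds.r2, bounds.r3):
        ax.plot([x, x], [z_lo, zc], color="k", lw=0.8)
    for x in (bounds.r5, bounds.r6):
        ax.plot([x, x], [zc, z_hi], color="k", lw=0.8)
    labels_low = {"R1": bounds.r1 / 2, "R2": (bounds.r1 + bounds.r2) / 2,
                  "R3": (bounds.r2 + bounds.r3) / 2, "R4": (bounds.r3 + 1) / 2}
    labels_high = {"R5": bounds.r5 / 2, "R6": (bounds.r5 + bounds.r6) / 2,
                   "R7": (bounds.r6 + 1) / 2}
    for name, x in labels_low.items():
        ax.text(x, z_lo + 0.1, name, ha="center", fontsize=8, color="gray")
    for name, x in labels_high.items():
        ax.text(x, z_hi - 0.3, name, ha="center", fontsize=8, color="gray")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(z_lo, z_hi)
    ax.set_xlabel(r"clusterphobic coefficient $K_\pi$")
    ax.set_ylabel(r"global within-module degree $z_g$")
    ax.set_title("heat cartography map")
    return _finish(fig, path)


def plot_degree_distribution(hist: pd.DataFrame, path=None):
    """Degree frequency on log-log axes (heavy tails show as a line)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    nz = hist[hist["degree"] > 0]
    ax.scatter(nz["degree"], nz["count"], s=16, color="#4878a8")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("degree k")
    ax.set_ylabel("number of nodes")
    ax.set_title("degree distribution")
    return _finish(fig, path)


def plot_removal_curves(curves: pd.DataFrame, path=None):
    """ASP versus removed fraction, one line per strategy."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for name, sub in curves.groupby("strategy"):
        ax.plot(sub["fraction"], sub["asp"], marker="o", ms=3.5, label=name)
    ax.set_xlabel("fraction of category removed")
    ax.set_ylabel("average shortest path")
    ax.legend(fontsize=8)
    ax.set_title("network robustness to targeted removal")
    return _finish(fig, path)


def plot_distance_heatmap(dist: pd.DataFrame, z: np.ndarray, path=None):
    """Symmetric distance heatmap (white near, red far inverted per the
    usual convention: decreasing distance rendered white -> red) with the
    dataset dendrogram on top."""
    order_fig, order_ax = plt.subplots()
    dend = dendrogram(z, labels=list(dist.columns), ax=order_ax, no_plot=True)
    plt.close(order_fig)
    order = dend["ivl"]
    d = dist.loc[order, order]
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(5.5, 7), gridspec_kw={"height_ratios": [1, 3]}
    )
    dendrogram(z, labels=list(dist.columns), ax=ax_d, color_threshold=0)
    ax_d.set_yticks([])
    im = ax_h.imshow(1 - d / max(d.to_numpy().max(), 1e-12), cmap="Reds", vmin=0, vmax=1)
    ax_h.set_xticks(range(len(order)), order, rotation=90, fontsize=8)
    ax_h.set_yticks(range(len(order)), order, fontsize=8)
    fig.colorbar(im, ax=ax_h, label="similarity (1 - scaled Hamming)")
    return _finish(fig, path)
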