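"""Report figures for the three experiments.

Styles mirror the standard presentation of this kind of data: a loss
trajectory with SEM error bars, loss proportion against corrected depth
with per-replicate LOESS curves and a scaled biomass envelope, a per-bead
loss-ratio boxplot (median, quartiles, 1.5 IQR whiskers, outlier points),
and log10 aggregate size against normalized distance with the 95%
confidence band of the regression line.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy import stats as sps  # noqa: E402

__all__ = [
    "plot_trajectory",
    "plot_loss_depth",
    "plot_ratio_box",
    "plot_size_distance",
]


def _save(fig, path):
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(summary, path):
    """Mean plasmid-free fraction per day with SEM error bars, one line per
    (strain, plasmid)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for (strain, plasmid), sub in summary.groupby(["strain", "plasmid"]):
        sub = sub.sort_values("day")
        ax.errorbar(sub["day"], sub["mean"], yerr=sub["sem"], marker="o",
                    capsize=3, label=f"{strain} / {plasmid}")
    ax.set_xlabel("day")
    ax.set_ylabel("plasmid-free fraction")
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def plot_loss_depth(profiles, curves, path):
    """Loss proportion vs corrected z: points sized by biomass, one LOESS
    line per replicate, shaded total-biomass envelope scaled to max 100%."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    total_b = None
    for prof in profiles:
        b = prof.biomass
        total_b = b if total_b is None else total_b  # envelope from first
        from .flowcell import loss_proportion

        p = loss_proportion(prof)
        keep = np.isfinite(p)
        sizes = 40 * b[keep] / max(b.max(), 1)
        ax.scatter(prof.z_corrected[keep], p[keep], s=sizes, alpha=0.4,
                   color="grey", edgecolors="none")
    for curve in curves:
        ax.plot(curve.x, curve.fitted, color="red", lw=1.5,
                label=curve.replicate or None)
    if profiles:
        prof = profiles[0]
        b = prof.biomass / prof.biomass.max()
        ax.fill_between(prof.z_corrected, 0, b * ax.get_ylim()[1],
                        alpha=0.12, color="tab:blue", zorder=0)
    ax.set_xlabel("corrected z position (layers)")
    ax.set_ylabel("proportion plasmid-free")
    fig.tight_layout()
    _save(fig, path)


def plot_ratio_box(ratio_table, path, by: str = "strain"):
    """Boxplot of per-bead free:carrier aggregate ratios."""
    fig, ax = plt.subplots(figsize=(4, 4))
    groups = sorted(ratio_table[by].unique())
    data = [ratio_table.loc[ratio_table[by] == g, "ratio"]
            .replace([np.inf, -np.inf], np.nan).dropna().to_numpy()
            for g in groups]
    ax.boxplot(data, tick_labels=groups, whis=1.5)
    ax.set_ylabel("plasmid-free : plasmid-carrying aggregates")
    fig.tight_layout()
    _save(fig, path)


def plot_size_distance(table, regression, path, level: float = 0.95):
    """log10 aggregate volume vs normalized distance with the fitted line
    and its confidence band."""
    t = table[table["retained"]]
    fig, ax = plt.subplots(figsize=(5, 4))
    for channel, color in (("green", "tab:green"), ("red", "tab:red")):
        sub = t[t["channel"] == channel]
        ax.scatter(sub["normalized_distance"], np.log10(sub["volume_um3"]),
                   s=12, alpha=0.6, color=color, label=channel)
    fit = regression["fit"]
    xs = np.linspace(0, 1, 50)
    X0 = np.column_stack([np.ones_like(xs), xs])
    pred = X0 @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X0, fit.cov, X0))
    q = sps.t.ppf(0.5 + level / 2, fit.df_resid)
    ax.plot(xs, pred, color="black")
    ax.fill_between(xs, pred - q * se, pred + q * se, alpha=0.2,
                    color="grey")
    ax.set_xlabel("normalized distance from bead centre")
    ax.set_ylabel("log10 aggregate volume (um^3)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)
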