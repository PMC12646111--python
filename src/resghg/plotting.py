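"""Breakdown, embedding and frontier plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_breakdown", "plot_embedding", "plot_frontier"]


def plot_breakdown(attribution, path=None, max_features: int = 10):
    """Waterfall-style breakdown plot of one prediction's attributions."""
    contrib = sorted(
        attribution.contributions.items(), key=lambda kv: -abs(kv[1])
    )
    shown = contrib[:max_features]
    rest = sum(v for _, v in contrib[max_features:])
    labels = [k for k, _ in shown]
    values = [v for _, v in shown]
    if contrib[max_features:]:
        labels.append("+ all other factors")
        values.append(rest)
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(labels) + 2))
    colors = ["forestgreen" if v >= 0 else "firebrick" for v in values]
    y = np.arange(len(labels))
    ax.barh(y, values, color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_yticks(y, labels)
    ax.invert_yaxis()
    ax.set_xlabel("contribution to prediction (gCO2e/m2/yr)")
    ax.set_title(
        f"intercept {attribution.intercept:.1f}  ->  "
        f"prediction {attribution.prediction:.1f}"
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_embedding(embedding, path=None):
    """Scatter of the first two attribution PCA components by category."""
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        embedding.scores[:, 0], embedding.scores[:, 1],
        c=embedding.categories, cmap="viridis", s=25,
    )
    span = np.abs(embedding.scores[:, :2]).max()
    for name in embedding.top_features:
        j = embedding.feature_names.index(name)
        vx, vy = embedding.loadings[j, 0], embedding.loadings[j, 1]
        ax.annotate(
            name, xy=(vx * span, vy * span), xytext=(0, 0),
            arrowprops=dict(arrowstyle="<-", color="gray"),
        )
    evr = embedding.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    fig.colorbar(sc, label="driver category")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_frontier(report, path=None):
    """Emission intensity vs hydropower production along the frontier."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    sc = ax.scatter(
        report["hp_production_gwh"], report["emission_intensity_g_per_kwh"],
        c=report["cropland_loss_km2"] + report["forest_loss_km2"],
        s=20 + 120 * report["firm_power_ratio"], cmap="plasma",
    )
    ax.set_xlabel("hydropower production (GWh/yr)")
    ax.set_ylabel("emission intensity (gCO2e/kWh)")
    fig.colorbar(sc, label="land loss (km2)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
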