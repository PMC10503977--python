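"""Diagnostic plots: Williams plot, predicted-vs-observed, contributions.

All functions draw on a provided matplotlib Axes (or create one) and return
it; nothing is saved or shown implicitly.
"""

from __future__ import annotations

import numpy as np

from .domain import ADResult
from .report import CorrelationReport

__all__ = ["williams_plot", "pred_obs_plot", "contribution_plot", "affinity_plot"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def williams_plot(ad: ADResult, *, sigma_mult: float = 2.0, ax=None):
    """Leverage vs standardized residual with the h* and ±σ cut lines."""
    ax = _ax(ax)
    ids = list(ad.leverages)
    h = np.array([ad.leverages[i] for i in ids])
    sr = np.array([ad.std_residuals[i] for i in ids])
    colors = ["tab:red" if ad.labels.get(i, "inside") != "inside" else "tab:blue" for i in ids]
    ax.scatter(h, sr, c=colors)
    for cid, xi, yi in zip(ids, h, sr):
        if ad.labels.get(cid, "inside") != "inside":
            ax.annotate(cid, (xi, yi), textcoords="offset points", xytext=(4, 4))
    ax.axvline(ad.h_star, ls="--", color="gray")
    ax.axhline(sigma_mult, ls="--", color="gray")
    ax.axhline(-sigma_mult, ls="--", color="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    return ax


def pred_obs_plot(observed: dict, predicted: dict, *, ax=None, label=None):
    """Scatter of predicted against observed activity with the y=x line."""
    ax = _ax(ax)
    ids = list(observed)
    x = np.array([observed[i] for i in ids])
    y = np.array([predicted[i] for i in ids])
    ax.scatter(x, y, label=label)
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lims, lims, ls=":", color="gray")
    ax.set_xlabel("observed pIC50")
    ax.set_ylabel("predicted pIC50")
    if label:
        ax.legend()
    return ax


def contribution_plot(contributions: dict[str, float], *, ax=None):
    """Horizontal bar chart of relative descriptor contributions."""
    ax = _ax(ax)
    names = sorted(contributions, key=contributions.get)
    ax.barh(names, [contributions[n] for n in names])
    ax.set_xlabel("relative contribution")
    return ax


def affinity_plot(ds, corr: CorrelationReport | None = None, *, ax=None):
    """Binding affinity vs activity scatter with the regression line."""
    ax = _ax(ax)
    pairs = [
        (r.binding_affinity, r.activity)
        for r in ds.records
        if r.activity is not None and r.binding_affinity is not None
    ]
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    ax.scatter(x, y)
    if corr is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, corr.intercept + corr.slope * xs, color="tab:orange",
                label=f"r² = {corr.r2:.2f}")
        ax.legend()
    ax.set_xlabel("binding affinity (kcal/mol)")
    ax.set_ylabel("pIC50")
    return ax
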