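"""Plotting helpers for panel models and QC diagnostics (matplotlib)."""

from __future__ import annotations

import numpy as np

from .discriminant import PanelDiscriminantResults


def plot_roc_pr(results: PanelDiscriminantResults, ax_pair=None):
    """ROC and PR curves of the combined panel on the held-out set."""
    import matplotlib.pyplot as plt

    curves = results.roc_pr()
    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
    ax_roc, ax_pr = ax_pair
    ax_roc.plot(curves["fpr"], curves["tpr"], label=f"AUC = {curves['roc_auc']:.2f}")
    ax_roc.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax_roc.set(xlabel="false positive rate", ylabel="true positive rate", title="ROC")
    ax_roc.legend()
    ax_pr.step(curves["recall"], curves["precision"], where="post",
               label=f"AUC = {curves['pr_auc']:.2f}")
    ax_pr.set(xlabel="recall", ylabel="precision", title="Precision–recall")
    ax_pr.legend()
    return ax_pair


def plot_drift(table, protein: str, ax=None):
    """Value vs injection order for one protein (drift diagnostic)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    order = table.metadata["injection_order"].astype(float)
    y = table.values[protein]
    ok = y.notna() & order.notna()
    ax.scatter(order[ok], y[ok], s=12)
    coef = np.polyfit(order[ok], y[ok], 1)
    xs = np.linspace(order[ok].min(), order[ok].max(), 50)
    ax.plot(xs, np.polyval(coef, xs), c="crimson", lw=1)
    ax.set(xlabel="injection order", ylabel=protein, title=f"{protein} vs run order")
    return ax
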