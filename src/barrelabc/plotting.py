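"""Plot helpers for posteriors, epsilon schedules and confusion matrices."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_posterior", "plot_epsilon", "plot_confusion"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_posterior(result, ax=None):
    """Bar plot of the posterior mass over candidate models."""
    ax = _get_ax(ax)
    models = list(result.model_posterior)
    masses = [result.model_posterior[m] for m in models]
    ax.bar(range(len(models)), masses, color="0.3")
    ax.set_xticks(range(len(models)))
    ax.set_xticklabels(models, rotation=45, ha="right")
    ax.set_ylabel("posterior $p(m\\,|\\,C^{\\#})$")
    ax.set_ylim(0, 1)
    return ax


def plot_epsilon(result, ax=None):
    """Acceptance-threshold trajectory across SMC generations."""
    ax = _get_ax(ax)
    eps = result.epsilon_trajectory
    ax.plot(range(len(eps)), eps, "o-", color="0.2")
    ax.set_xlabel("generation")
    ax.set_ylabel(r"$\epsilon_{ABC}$")
    return ax


def plot_confusion(cm, ax=None):
    """Heatmap of the model confusion matrix (rows: generating model)."""
    ax = _get_ax(ax)
    im = ax.imshow(cm.matrix, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(cm.models)))
    ax.set_xticklabels(cm.models, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.models)))
    ax.set_yticklabels(cm.models)
    ax.set_xlabel("posterior model")
    ax.set_ylabel("generating model")
    for i in range(len(cm.models)):
        for j in range(len(cm.models)):
            ax.text(j, i, f"{cm.matrix[i, j]:.2f}", ha="center", va="center",
                    color="w" if cm.matrix[i, j] < 0.6 else "k", fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="posterior mass")
    return ax
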