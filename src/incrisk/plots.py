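"""Basic ROC overlay for a model comparison."""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .metrics import auc_mann_whitney


def roc_points(scores, labels):
    """(FPR, TPR) pairs over all score thresholds, highest threshold first."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise DataError("need at least one event and one non-event")
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tpr = np.concatenate([[0.0], np.cumsum(ys) / y.sum()])
    fpr = np.concatenate([[0.0], np.cumsum(~ys) / (~y).sum()])
    return fpr, tpr


def plot_roc_overlay(scores_by_model: dict, labels, ax=None, title: str | None = None):
    """Overlay ROC curves for several models scored on the same cases.

    ``scores_by_model`` maps a display label to its score vector. Returns the
    matplotlib Axes; imports matplotlib lazily so headless use of the rest of
    the package never touches a plotting backend.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, scores in scores_by_model.items():
        fpr, tpr = roc_points(scores, labels)
        auc = auc_mann_whitney(scores, labels).auc
        ax.plot(fpr, tpr, label=f"{label} (AUC {auc:.3f})", drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    return ax
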