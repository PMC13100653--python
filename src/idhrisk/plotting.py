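"""Matplotlib views of trajectories, the dynamic threshold and ROC curves."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_trajectories_by_cluster(sessions, cluster_result, ax=None, max_per_cluster=50):
    """RBV trajectories coloured by cluster (one line per session)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    colors = plt.cm.tab10.colors
    by_sid = dict(zip(cluster_result.session_ids, cluster_result.labels))
    counts: Dict[int, int] = {}
    for s in sessions:
        c = by_sid[s.session_id]
        counts[c] = counts.get(c, 0) + 1
        if counts[c] > max_per_cluster:
            continue
        ax.plot(s.t_min, s.rbv_pct, color=colors[(c - 1) % 10], alpha=0.35, lw=0.8)
    for c in sorted(set(cluster_result.labels)):
        ax.plot([], [], color=colors[(c - 1) % 10],
                label=f"cluster {c} ({cluster_result.risk_group[c]}-risk)")
    ax.set_xlabel("session time (min)")
    ax.set_ylabel("RBV (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_threshold_curve(curve, ax=None):
    """Raw Youden cutoffs, LOESS smooth and bootstrap band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(curve.t_grid, curve.raw, s=12, color="0.6", label="raw cutoff")
    ax.plot(curve.t_grid, curve.smooth, color="C3", lw=2, label="LOESS smooth")
    if curve.ci_low is not None:
        ax.fill_between(curve.t_grid, curve.ci_low, curve.ci_high,
                        color="C3", alpha=0.2, label="95% bootstrap CI")
    ax.set_xlabel("session time (min)")
    ax.set_ylabel("RBV threshold (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_roc(scores: Sequence[float], labels: Sequence[int], ax=None, label: Optional[str] = None):
    from sklearn.metrics import roc_curve

    from .evaluation import roc_auc

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr, tpr, _ = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    auc = roc_auc(scores, labels)
    ax.plot(fpr, tpr, label=f"{label or 'model'} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", color="0.6")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False, fontsize=8)
    return ax
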