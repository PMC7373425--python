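"""Simple diagnostic figures: feature distributions and importance bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .feature_extraction import FEATURE_NAMES


def plot_importance(importance: pd.DataFrame, path: str | Path) -> None:
    """Horizontal bar chart of Akaike-weight variable importance."""
    fig, ax = plt.subplots(figsize=(6, 4))
    data = importance.sort_values("importance")
    ax.barh(data["feature"], data["importance"], color="#4477aa")
    ax.set_xlabel("Akaike-weight importance")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_feature_distributions(features: pd.DataFrame, path: str | Path) -> None:
    """Per-feature histograms split by tumor outcome."""
    fig, axes = plt.subplots(3, 3, figsize=(10, 8))
    for ax, feat in zip(axes.ravel(), FEATURE_NAMES):
        for outcome, color in ((False, "#4477aa"), (True, "#ee6677")):
            sub = features[features["outcome"] == outcome][feat].dropna()
            if len(sub):
                ax.hist(sub, bins=12, alpha=0.6, color=color, label=str(outcome))
        ax.set_title(feat, fontsize=8)
        ax.tick_params(labelsize=7)
    axes[0, 0].legend(title="tumor", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
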