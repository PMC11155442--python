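"""Optional matplotlib figures: stress-strain maps, group boxplots, ROC.

Requires the ``plot`` extra (matplotlib); imported lazily so the core
pipeline stays free of a plotting dependency.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stats import delong_ci
from .stress_strain import StressStrainMap


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_stress_strain_map(ssmap: StressStrainMap, path: str | Path,
                           fit_slope: float | None = None,
                           fit_length: float | None = None) -> None:
    """Linear-grayscale echo-amplitude map over (depth, pressure).

    Optionally overlays the fitted slope line whose horizontal-axis
    intersection is the cervical length.
    """
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    order = np.argsort(ssmap.pressure_bins_kpa)
    ax.pcolormesh(ssmap.depth_bins_mm, ssmap.pressure_bins_kpa[order],
                  ssmap.amplitude[order], cmap="gray", shading="nearest")
    if fit_slope is not None and fit_length is not None:
        p = np.linspace(0, ssmap.pressure_bins_kpa.max(), 50)
        ax.plot(fit_length - p / fit_slope, p, "b--", lw=1.5,
                label=f"slope {fit_slope:.2f} kPa/mm")
        ax.legend(loc="upper right")
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel("applied pressure (kPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_boxplots(analysis: pd.DataFrame, path: str | Path) -> None:
    """Preterm-vs-term boxplots of average elasticity and length."""
    plt = _plt()
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, col, label in zip(
            axes, ("elasticity_avg_kpa_mm", "length_avg_mm"),
            ("average elasticity (kPa/mm)", "average length (mm)")):
        groups = [analysis.loc[analysis["group"] == g, col].dropna()
                  for g in ("sptb", "term")]
        ax.boxplot(groups, tick_labels=["preterm", "term"])
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(elasticities, labels, path: str | Path, cutoff: float = 1.0) -> None:
    """Empirical ROC of the low-elasticity rule with the AUC annotated."""
    from sklearn.metrics import roc_curve
    plt = _plt()
    scores = -np.asarray(elasticities, float)
    fpr, tpr, _ = roc_curve(np.asarray(labels, bool), scores)
    res = delong_ci(scores, labels)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC {100 * res.auc:.1f}% "
                 f"(95% CI {100 * res.ci_low:.1f}-{100 * res.ci_high:.1f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
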