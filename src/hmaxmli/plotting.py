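"""Matplotlib views of the experiment outputs (accuracy bars, psychometric
curves, feature-influence scatter, filtering triptych)."""

from __future__ import annotations

import numpy as np
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_size_sweep(results: dict):
    """Accuracy vs network size with SEM error bars."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sizes = sorted(results)
    means = [results[d].mean for d in sizes]
    sems = [results[d].sem for d in sizes]
    ax.errorbar(sizes, means, yerr=sems, marker="o", capsize=3)
    ax.set_xlabel("network size (S2 units)")
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(50, 100)
    fig.tight_layout()
    return fig


def plot_accuracy_comparison(results: dict):
    """Control vs illusion accuracy per category with SEM error bars."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    conditions = [k for k in results if k in ("LR", "ML")]
    width = 0.35
    for i, cond in enumerate(conditions):
        res = results[cond]
        cats = ["LONG", "SHORT"]
        x = np.arange(len(cats)) + i * width
        ax.bar(x, [res.category_mean(c) for c in cats], width,
               yerr=[res.category_sem(c) for c in cats], capsize=3,
               label=cond)
    ax.set_xticks(np.arange(2) + width / 2)
    ax.set_xticklabels(["LONG", "SHORT"])
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(50, 100)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_psychometric(conditions: dict):
    """Proportion-LONG curves with their fitted logistics per condition."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    grid = None
    for name, data in conditions.items():
        curve, fit = data["curve"], data["fit"]
        if grid is None:
            grid = np.linspace(curve.diffs.min(), curve.diffs.max(), 200)
        pts = ax.plot(curve.diffs, 100 * curve.proportion_long, "o",
                      label=f"{name} (PSE {fit.midpoint:.1f} px)")
        ax.plot(grid, 100 * fit.predict(grid), "-",
                color=pts[0].get_color())
    ax.axhline(50, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("top − bottom length difference (px)")
    ax.set_ylabel("% classified LONG")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_influence_bbox(influences, k: int = 20):
    """Receptive-box sizes of the k most influential features vs all."""
    from .introspection import top_k
    fig, ax = plt.subplots(figsize=(5, 3.5))
    all_boxes = [f.bbox_side for f in influences]
    top_boxes = [f.bbox_side for f in top_k(influences, k)]
    ax.hist(all_boxes, bins=20, density=True, alpha=0.4,
            label=f"all {len(influences)} features")
    ax.hist(top_boxes, bins=20, density=True, alpha=0.6,
            label=f"top {k} by |SVM weight|")
    ax.set_xlabel("receptive-field bounding box (px)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_frequency_triptych(image, cutoff: float = 5.0):
    """Original, high-pass and low-pass versions of one stimulus."""
    from .introspection import frequency_filter_demo
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    views = [("original", image),
             (f"high-pass {cutoff:g} c/img",
              frequency_filter_demo(image, cutoff, "high")),
             (f"low-pass {cutoff:g} c/img",
              frequency_filter_demo(image, cutoff, "low"))]
    for ax, (title, img) in zip(axes, views):
        ax.imshow(img, cmap="gray")
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    return fig
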