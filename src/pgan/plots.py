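"""Figure outputs: attack histograms, embedding overlays, ROC and loss plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .privacy import ORIGINS, AttackScoreTable
from .utility import EvalReport

_ORIGIN_COLORS = {"train": "tab:blue", "validation": "tab:orange",
                  "test": "tab:green"}
_CLASS_COLORS = {1: "tab:blue", 2: "tab:green", 3: "tab:red"}
_CLASS_NAMES = {1: "cervical", 2: "thoracic", 3: "lumbar"}


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_score_histograms(table: AttackScoreTable, path: str | Path) -> Path:
    """Per-origin distributions of attack scores (min distance / cluster size)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for origin in ORIGINS:
        vals = table.scores[table.origins == origin].astype(float)
        if len(vals):
            ax.hist(vals, bins=30, alpha=0.5, density=True,
                    label=origin, color=_ORIGIN_COLORS[origin])
    xlabel = ("min candidate-synthetic distance" if table.attack == "pairwise"
              else "synthetic neighbours within threshold")
    ax.set_xlabel(f"{xlabel} ({table.space} space)")
    ax.set_ylabel("density")
    ax.legend()
    ax.set_title(f"{table.attack} attack scores by candidate origin")
    return _save(fig, path)


def plot_embedding_overlay(real_coords: np.ndarray, real_labels: np.ndarray,
                           synth_coords: np.ndarray, path: str | Path) -> Path:
    """2-D embedding: real points coloured by class over a synthetic density."""
    fig, ax = plt.subplots(figsize=(6, 5))
    if len(synth_coords):
        ax.hexbin(synth_coords[:, 0], synth_coords[:, 1], gridsize=40,
                  cmap="YlOrRd", mincnt=1)
    for k in (1, 2, 3):
        m = real_labels == k
        if m.any():
            ax.scatter(real_coords[m, 0], real_coords[m, 1], s=6,
                       c=_CLASS_COLORS[k], label=_CLASS_NAMES[k], alpha=0.7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(markerscale=2)
    ax.set_title("synthetic density (shaded) vs real samples (dots)")
    return _save(fig, path)


def plot_macro_roc(reports: list[EvalReport], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        ax.plot(rep.roc.fpr_grid, rep.roc.macro_tpr,
                label=f"{rep.arm} (AUC {rep.macro_auc.estimate:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    ax.set_title("macro-average one-vs-rest ROC")
    return _save(fig, path)


def plot_loss_history(history, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("d_loss", "g_loss", "d_adv", "d_class"):
        if col in history:
            ax.plot(history["iteration"], history[col], label=col, lw=0.9)
    ax.set_xlabel("iteration")
    ax.set_ylabel("loss / log-probability")
    ax.legend()
    ax.set_title("adversarial training history")
    return _save(fig, path)


def plot_morph_grid(images: np.ndarray, path: str | Path,
                    slice_index: int | None = None) -> Path:
    """One row of images morphing a frozen latent between two regions."""
    n, s, h, w = images.shape
    slice_index = s // 2 if slice_index is None else slice_index
    fig, axes = plt.subplots(1, n, figsize=(1.6 * n, 1.8))
    axes = np.atleast_1d(axes)
    for i, ax in enumerate(axes):
        ax.imshow(images[i, slice_index], cmap="gray", vmin=-1, vmax=1)
        ax.set_xticks([]), ax.set_yticks([])
        ax.set_title(f"step {i}", fontsize=8)
    return _save(fig, path)
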