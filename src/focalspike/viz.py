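"""Plotting: ROC curves, confusion heatmaps, embedding scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import BinaryReport, MulticlassReport

_CLASS_COLORS = {
    "frontal": "tab:green",
    "temporal": "tab:blue",
    "occipital": "tab:orange",
    "non_ied": "tab:red",
}


def plot_roc(report: BinaryReport, path: str | Path, title: str = "ROC") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    if report.roc_points:
        fpr, tpr = zip(*report.roc_points)
        ax.plot(fpr, tpr, label=f"AUC {report.auc:.1f}%")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_confusion(report: MulticlassReport, path: str | Path, title: str = "") -> None:
    conf = np.asarray(report.confusion)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(conf, cmap="Blues")
    ax.set_xticks(range(len(report.class_order)), report.class_order, rotation=45)
    ax.set_yticks(range(len(report.class_order)), report.class_order)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            ax.text(j, i, str(conf[i, j]), ha="center", va="center",
                    color="white" if conf[i, j] > conf.max() / 2 else "black")
    ax.set_title(title or f"accuracy {report.accuracy:.1f}%")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_embedding(coords: np.ndarray, labels, path: str | Path) -> None:
    labels = np.asarray(labels, dtype=object)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for cls in sorted(set(labels.tolist()), key=str):
        mask = labels == cls
        ax.scatter(coords[mask, 0], coords[mask, 1], s=4, alpha=0.6,
                   color=_CLASS_COLORS.get(cls), label=str(cls))
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(markerscale=3)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
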