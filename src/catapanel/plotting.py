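"""Figure rendering: Sammon replicate map, symmetric CA map, spider diagram.

All functions take an explicit output path and write SVG (or any format the
extension implies) with deterministic metadata so re-runs are reproducible.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .embedding import SammonEmbedding
from .products import CAResult

__all__ = ["plot_sammon", "plot_ca_symmetric", "plot_spider"]

_SAVE_KW = {"metadata": {"Date": None}}


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = dict(_SAVE_KW) if path.suffix == ".svg" else {}
    fig.savefig(path, bbox_inches="tight", **kwargs)
    plt.close(fig)


def plot_sammon(embedding: SammonEmbedding, labels, path) -> None:
    """Scatter the embedded product x replicate profiles, labelled."""
    with plt.rc_context({"svg.hashsalt": "catapanel"}):
        fig, ax = plt.subplots(figsize=(7, 6))
        xy = embedding.coordinates
        ax.scatter(xy[:, 0], xy[:, 1], s=18, color="tab:blue")
        for (x, y), label in zip(xy, labels):
            text = label if isinstance(label, str) else ":".join(map(str, label))
            ax.annotate(text, (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel("Dim 1")
        ax.set_ylabel("Dim 2")
        ax.set_title(f"Sammon mapping of replicate profiles (stress {embedding.stress:.3g})")
        _save(fig, path)


def plot_ca_symmetric(ca: CAResult, path, dims=(0, 1)) -> None:
    """Symmetric CA map: rows and columns both in principal coordinates."""
    d1, d2 = dims
    with plt.rc_context({"svg.hashsalt": "catapanel"}):
        fig, ax = plt.subplots(figsize=(7, 6))
        F, G = ca.row_coordinates, ca.col_coordinates
        ax.scatter(F[:, d1], F[:, d2], color="tab:blue", marker="o", s=20, label="rows")
        ax.scatter(G[:, d1], G[:, d2], color="tab:red", marker="^", s=20, label="columns")
        for (x, y), label in zip(F[:, [d1, d2]], ca.row_labels):
            ax.annotate(str(label), (x, y), fontsize=7, color="tab:blue",
                        xytext=(3, 3), textcoords="offset points")
        for (x, y), label in zip(G[:, [d1, d2]], ca.col_labels):
            ax.annotate(str(label), (x, y), fontsize=7, color="tab:red",
                        xytext=(3, 3), textcoords="offset points")
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel(f"Dim {d1 + 1} ({ca.explained_inertia[d1]:.1f}%)")
        ax.set_ylabel(f"Dim {d2 + 1} ({ca.explained_inertia[d2]:.1f}%)")
        ax.legend(frameon=False, fontsize=8)
        ax.set_title("Correspondence analysis, symmetric plot")
        _save(fig, path)


def plot_spider(proportions: pd.DataFrame, path) -> None:
    """Radar chart of per-cluster mean citation proportions."""
    attributes = list(proportions.columns)
    angles = np.linspace(0, 2 * np.pi, len(attributes), endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    with plt.rc_context({"svg.hashsalt": "catapanel"}):
        fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"projection": "polar"})
        for cluster, row in proportions.iterrows():
            values = row.to_numpy()
            ax.plot(closed, np.concatenate([values, values[:1]]), label=str(cluster))
        ax.set_xticks(angles)
        ax.set_xticklabels(attributes, fontsize=7)
        ax.set_title("Mean citation proportion per cluster")
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.05), fontsize=8)
        _save(fig, path)
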