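"""Scatter and overlay plots for ordination and curvature results."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import chi2

from .classify import PCAResult
from .curvature import CurveLandmarks
from .morphodata import Clade

_COLORS = {
    Clade.SMALL_APES: "tab:blue",
    Clade.LANGURS: "tab:green",
    Clade.ODD_NOSED: "tab:purple",
    Clade.MACAQUES: "tab:orange",
}


def _confidence_ellipse(ax, xy: np.ndarray, color: str, level: float = 0.95) -> None:
    """95% normal-theory ellipse of a 2-D point cloud."""
    if len(xy) < 3:
        return
    cov = np.cov(xy.T)
    mean = xy.mean(axis=0)
    vals, vecs = np.linalg.eigh(cov)
    r2 = chi2.ppf(level, df=2)
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    pts = mean + (circle * np.sqrt(np.maximum(vals, 0) * r2)) @ vecs.T
    ax.plot(pts[:, 0], pts[:, 1], color=color, lw=1, alpha=0.8)


def scatter_scores(
    scores: np.ndarray,
    clades: Sequence[Clade],
    path: str | Path,
    *,
    fossil_scores: np.ndarray | None = None,
    xlabel: str = "axis 1",
    ylabel: str = "axis 2",
    title: str = "",
) -> None:
    """Two-axis score scatter with per-clade 95% confidence ellipses."""
    fig, ax = plt.subplots(figsize=(6, 5))
    clades = list(clades)
    for clade in Clade.comparative():
        mask = np.array([c is clade for c in clades])
        if not mask.any():
            continue
        xy = scores[mask][:, :2]
        ax.scatter(xy[:, 0], xy[:, 1], s=18, color=_COLORS[clade],
                   label=clade.value, alpha=0.8)
        _confidence_ellipse(ax, xy, _COLORS[clade])
    if fossil_scores is not None and len(fossil_scores):
        f = np.atleast_2d(fossil_scores)
        ax.scatter(f[:, 0], f[:, 1], marker="s", s=60, color="red", label="fossil")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_pca(result: PCAResult, path: str | Path) -> None:
    v = result.variance_fraction
    scatter_scores(
        result.scores, result.clades, path,
        fossil_scores=result.fossil_scores[:, :2] if len(result.fossil_scores) else None,
        xlabel=f"PC1 ({100 * v[0]:.1f}%)",
        ylabel=f"PC2 ({100 * v[1]:.1f}%)",
        title="PCA of log-shape ratios",
    )


def curvature_overlay(
    taxa_means: Mapping[str, CurveLandmarks],
    fossil: CurveLandmarks | None,
    path: str | Path,
) -> None:
    """Registered mean curves per taxon, fossil overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for taxon, shape in sorted(taxa_means.items()):
        ax.plot(shape.points[:, 0], shape.points[:, 1], marker="o", ms=3, lw=1,
                label=taxon)
    if fossil is not None:
        ax.plot(fossil.points[:, 0], fossil.points[:, 1], marker="s", ms=4,
                lw=2, color="red", label=fossil.specimen_id)
    ax.set_xlabel("baseline x")
    ax.set_ylabel("baseline y")
    ax.set_title("Baseline-registered shaft curvature")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
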