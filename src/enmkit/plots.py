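"""Matplotlib views of ENM outputs (optional; all analyses are TSV-first)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .gnm import CrossCorrelationMap
from .mode_analysis import HingeReport
from .structures import DomainAnnotation

__all__ = ["plot_correlation_map", "plot_slow_mode_profile"]


def plot_correlation_map(cmap: CrossCorrelationMap, path) -> None:
    """Heat map of the cross-correlation matrix, blue→red anchored at ±1."""
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    im = ax.imshow(cmap.matrix, cmap="coolwarm", vmin=-1.0, vmax=1.0,
                   origin="lower", interpolation="nearest")
    start, count = cmap.mode_range
    ax.set_xlabel("node index")
    ax.set_ylabel("node index")
    ax.set_title(f"cross-correlations, modes {start}..{start + count - 1}")
    fig.colorbar(im, ax=ax, label="C$_{ij}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_slow_mode_profile(
    profile: np.ndarray,
    path,
    annotation: DomainAnnotation | None = None,
    hinges: HingeReport | None = None,
) -> None:
    """Slow-mode fluctuation profile with domain shading and hinge markers."""
    fig, ax = plt.subplots(figsize=(6.4, 3.2))
    ax.plot(profile, lw=1.2, color="tab:blue")
    if annotation is not None:
        for k, (label, start, end) in enumerate(annotation.segments):
            ax.axvspan(start - 0.5, end + 0.5, alpha=0.12,
                       color=f"C{k % 10}")
            ax.text((start + end) / 2, ax.get_ylim()[1] * 0.95, label,
                    ha="center", va="top", fontsize=7)
    if hinges is not None and hinges.hinge_nodes:
        ax.plot(hinges.hinge_nodes, profile[hinges.hinge_nodes], "v",
                color="tab:red", ms=6, label="hinge")
        ax.legend(loc="upper right", fontsize=7)
    ax.set_xlabel("node index")
    ax.set_ylabel("normalized squared fluctuation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
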