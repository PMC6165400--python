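"""Convenience figures; numeric CSVs remain the canonical outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .benchmark import pca_reduce
from .features import FeatureMatrix

__all__ = ["confidence_credibility_scatter", "pca_scatter"]


def confidence_credibility_scatter(report_df, path, title=None) -> None:
    """Per-sample confidence vs credibility, hits and misses distinguished."""
    conf = report_df["confidence"].to_numpy(dtype=float)
    cred = report_df["credibility"].to_numpy(dtype=float)
    correct = (
        report_df["true_label"].to_numpy() == report_df["forced_prediction"].to_numpy()
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(conf[correct], cred[correct], s=14, alpha=0.6, label="correct")
    if (~correct).any():
        ax.scatter(
            conf[~correct], cred[~correct], s=20, alpha=0.8, marker="x",
            color="crimson", label="wrong",
        )
    ax.set_xlabel("confidence")
    ax.set_ylabel("credibility")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(features: FeatureMatrix, path, title=None) -> None:
    """Samples projected onto the first two principal components."""
    reduced, evr = pca_reduce(features, 2)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in np.unique(reduced.labels):
        mask = reduced.labels == lab
        ax.scatter(
            reduced.values[mask, 0], reduced.values[mask, 1], s=14, alpha=0.7,
            label=str(lab),
        )
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}% var)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}% var)")
    ax.legend(loc="best", fontsize="small", ncol=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
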