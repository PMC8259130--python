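"""Quick-look plots: feature histograms/scatters and image previews."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["feature_histogram", "feature_scatter", "save_image_preview"]


def feature_histogram(
    features: pd.DataFrame, axis: str, path, by_label: bool = True, bins: int = 60
) -> None:
    """Histogram of one feature, optionally split by truth label."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    data = features[np.isfinite(features[axis])]
    if by_label and "truth_label" in data and data["truth_label"].nunique() > 1:
        for lbl, grp in data.groupby("truth_label"):
            ax.hist(grp[axis], bins=bins, alpha=0.6, label=str(lbl))
        ax.legend(fontsize=8)
    else:
        ax.hist(data[axis], bins=bins)
    ax.set_xlabel(axis)
    ax.set_ylabel("events")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def feature_scatter(
    features: pd.DataFrame, x: str, y: str, path, by_label: bool = True
) -> None:
    """Scatter of two features, optionally colored by truth label."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    data = features[np.isfinite(features[x]) & np.isfinite(features[y])]
    if by_label and "truth_label" in data and data["truth_label"].nunique() > 1:
        for lbl, grp in data.groupby("truth_label"):
            ax.scatter(grp[x], grp[y], s=8, alpha=0.7, label=str(lbl))
        ax.legend(fontsize=8)
    else:
        ax.scatter(data[x], data[y], s=8, alpha=0.7)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_image_preview(values: np.ndarray, path, pitch_y: float = 1.0,
                       pitch_z: float = 1.0) -> None:
    """Grayscale PNG preview of a reconstructed transmission image with
    physically scaled axes."""
    fig, ax = plt.subplots(figsize=(4, 4))
    nz, ny = values.shape
    ax.imshow(
        values,
        cmap="gray",
        extent=(0, ny * pitch_y, nz * pitch_z, 0),
        vmin=min(0.4, float(values.min())),
        vmax=max(1.1, float(values.max())),
    )
    ax.set_xlabel("scan axis (um)")
    ax.set_ylabel("flow axis (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
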