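"""Diagnostic plots: proximity profiles and residual-stain tile maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .destain import QCRecord
from .proximity import ProximityProfile

__all__ = ["plot_proximity_profile", "plot_residual_tiles"]


def plot_proximity_profile(profile: ProximityProfile, path: str | Path) -> None:
    """Counts and stacked relative-percentage panels vs distance bin."""
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 3.5))
    centers = 0.5 * (profile.bin_edges_um[:-1] + profile.bin_edges_um[1:])
    for col in profile.counts.columns:
        ax0.plot(centers, profile.counts[col], marker="o", label=col)
    ax0.set_xlabel("distance to pathology (µm)")
    ax0.set_ylabel("cells")
    ax0.set_title(f"counts near {profile.pathology_kind}")
    pct = profile.row_percent.fillna(0.0)
    bottom = np.zeros(len(pct))
    width = np.diff(profile.bin_edges_um)
    for col in pct.columns:
        ax1.bar(centers, pct[col], width=width * 0.9, bottom=bottom, label=col)
        bottom += pct[col].to_numpy()
    ax1.set_xlabel("distance to pathology (µm)")
    ax1.set_ylabel("% of cells in bin")
    ax1.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residual_tiles(record: QCRecord, path: str | Path) -> None:
    """Heat map of per-tile residual percentages (blocking uniformity)."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(record.tile_residual, cmap="magma", vmin=0)
    fig.colorbar(im, ax=ax, label="residual %")
    ax.set_title(f"{record.marker}: residual {record.residual_percent:.3f}%")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
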