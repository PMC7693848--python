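"""Plotting helpers: flow fields with streamlines, stream distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .distributions import StreamDistribution
from .flow import FlowField

__all__ = ["plot_flow_field", "plot_distributions"]


def plot_flow_field(fld: FlowField, path: str | Path, streamlines: bool = True):
    """Speed map of the solved field with overlaid streamlines."""
    fig, ax = plt.subplots(figsize=(12, 4.2))
    speed = np.hypot(fld.u, fld.v)
    im = ax.imshow(
        speed,
        origin="lower",
        extent=(0, fld.domain.length, 0, fld.domain.width),
        aspect="auto",
        cmap="viridis",
    )
    if streamlines:
        ax.streamplot(
            fld.x, fld.y, fld.u, fld.v, density=2.0, color="w", linewidth=0.5
        )
    fig.colorbar(im, ax=ax, label="speed (m/s)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return Path(path)


def plot_distributions(
    dists: dict[str, StreamDistribution],
    path: str | Path,
    channel_width: float = 300.0,
):
    """Cross-channel stream distributions (Gaussian curves or seed bins)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    y = np.linspace(0, channel_width, 600)
    for label, d in dists.items():
        if d.mean is not None and d.sigma is not None:
            curve = np.exp(-0.5 * ((y - d.mean) / d.sigma) ** 2)
            ax.plot(y, curve, label=f"{label} (peak {d.peak:.0f} µm)")
        if d.bins is not None:
            ax.bar(d.bins[:, 0], d.bins[:, 1] / d.bins[:, 1].max(),
                   width=1.0, alpha=0.3)
    ax.set_xlabel("position across channel (µm)")
    ax.set_ylabel("normalized density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return Path(path)
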