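"""Perfusion heatmap rendering.

The device convention is fixed: warm colors (red/yellow) mark high flow,
cool colors (blue) mark low flow.  Clamping to the display range happens
only here — stored RPU/flow values are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps


class HeatmapError(ValueError):
    pass


@dataclass
class HeatmapRender:
    image: np.ndarray  # (H, W, 3) uint8
    colormap: str
    clim: tuple[float, float]


def render_heatmap(
    values: np.ndarray,
    clim: tuple[float, float] = (0.0, 100.0),
    colormap: str = "turbo",
) -> HeatmapRender:
    """Map values linearly onto a warm-high perceptual colormap."""
    v = np.asarray(values, dtype=np.float64)
    if not np.isfinite(v).all():
        raise HeatmapError("heatmap input must be finite")
    lo, hi = clim
    if not hi > lo:
        raise HeatmapError(f"degenerate display range {clim}")
    cmap = colormaps[colormap]
    norm = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    rgb = (cmap(norm)[..., :3] * 255).round().astype(np.uint8)
    return HeatmapRender(image=rgb, colormap=colormap, clim=(float(lo), float(hi)))


def save_heatmap(
    path: str | Path,
    values: np.ndarray,
    clim: tuple[float, float] = (0.0, 100.0),
    colormap: str = "turbo",
    title: str = "",
    cbar_label: str = "RPU (%)",
) -> Path:
    """Write a heatmap PNG with an embedded color scale bar."""
    render = render_heatmap(values, clim, colormap)  # validates inputs
    fig, ax = plt.subplots(figsize=(7, 4), dpi=110)
    im = ax.imshow(np.asarray(values, dtype=float), cmap=colormap, vmin=clim[0], vmax=clim[1])
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label=cbar_label, shrink=0.85)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
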