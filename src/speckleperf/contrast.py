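"""Speckle contrast estimation and flow-index maps.

Contrast ``K`` is the population standard deviation over mean of the
intensity in a sliding spatial window (or along the time axis).  The raw
flow index is ``1 / max(K, k_floor)^2``; the relative-perfusion
quantification downstream is invariant to affine rescaling of this
quantity, which is what makes the particular raw-value choice safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence
import warnings

import numpy as np
from scipy import ndimage


class ContrastError(ValueError):
    pass


@dataclass
class ContrastMap:
    """Per-pixel speckle contrast with its estimation window descriptor."""

    values: np.ndarray
    window: str  # e.g. "spatial7x7" or "temporal8"
    source_frames: tuple[int, ...] = ()
    n_unphysical: int = 0  # pixels with K > ~1.2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ContrastError("contrast must be non-negative")
        self.n_unphysical = int((self.values > 1.2).sum())


@dataclass
class FlowIndexMap:
    """Raw flow values (``1/K^2``) feeding the relative-perfusion ratio."""

    values: np.ndarray
    k_floor: float = 0.05
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ContrastError("flow index must be finite everywhere")
        if (self.values < 0).any():
            raise ContrastError("flow index must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _sigma_mu(mean: np.ndarray, meansq: np.ndarray) -> np.ndarray:
    var = np.maximum(meansq - mean**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(mean > 0, np.sqrt(var) / np.where(mean > 0, mean, 1.0), 0.0)
    return k


def spatial_contrast(frame: np.ndarray, w: int = 7) -> ContrastMap:
    """Sliding-window spatial contrast of one frame.

    Population sigma/mean over each ``w x w`` neighbourhood with reflect
    padding at the borders; zero-mean neighbourhoods get K = 0.
    """
    if w % 2 == 0 or w < 3:
        raise ContrastError("window size must be odd and >= 3")
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim != 2:
        raise ContrastError("frame must be 2-D")
    if not np.isfinite(f).all():
        raise ContrastError("frame must be finite")
    mean = ndimage.uniform_filter(f, size=w, mode="reflect")
    meansq = ndimage.uniform_filter(f * f, size=w, mode="reflect")
    return ContrastMap(values=_sigma_mu(mean, meansq), window=f"spatial{w}x{w}")


def temporal_contrast(frames: np.ndarray, n_frames: int) -> ContrastMap:
    """Per-pixel contrast along the time axis of the first ``n_frames``."""
    stack = np.asarray(frames, dtype=np.float64)
    if stack.ndim != 3:
        raise ContrastError("expected an (n, H, W) stack")
    if n_frames < 2:
        raise ContrastError("temporal contrast needs n_frames >= 2")
    if n_frames > len(stack):
        raise ContrastError(f"n_frames {n_frames} exceeds stack length {len(stack)}")
    sub = stack[:n_frames]
    mean = sub.mean(axis=0)
    meansq = (sub**2).mean(axis=0)
    return ContrastMap(
        values=_sigma_mu(mean, meansq),
        window=f"temporal{n_frames}",
        source_frames=tuple(range(n_frames)),
    )


def flow_index(kmap: ContrastMap, k_floor: float = 0.05) -> FlowIndexMap:
    """Raw flow index ``1 / max(K, k_floor)^2``; monotone decreasing in K."""
    if k_floor <= 0:
        raise ContrastError("k_floor must be positive")
    k = np.maximum(kmap.values, k_floor)
    return FlowIndexMap(
        values=1.0 / (k * k),
        k_floor=k_floor,
        provenance={"window": kmap.window, "source_frames": list(kmap.source_frames)},
    )


def smooth_temporal(maps: Sequence[FlowIndexMap], window: int) -> list[FlowIndexMap]:
    """Per-pixel moving average over a window of flow-index maps.

    Returns ``len(maps) - window + 1`` maps ('valid' alignment); a window
    of 1 is the identity.
    """
    if len(maps) == 0:
        raise ContrastError("empty flow-index sequence")
    if window < 1 or window > len(maps):
        raise ContrastError(f"window {window} invalid for sequence of {len(maps)}")
    if window == 1:
        return list(maps)
    stack = np.stack([m.values for m in maps])
    csum = np.cumsum(stack, axis=0)
    csum = np.concatenate([np.zeros((1, *stack.shape[1:])), csum])
    out = []
    for i in range(len(maps) - window + 1):
        avg = (csum[i + window] - csum[i]) / window
        prov = dict(maps[i].provenance)
        prov["smoothed_over"] = window
        prov["first_source"] = i
        out.append(FlowIndexMap(values=avg, k_floor=maps[i].k_floor, provenance=prov))
    return out


def video_to_flow_maps(
    frames: np.ndarray,
    spatial_window: int = 7,
    smooth_window: int = 5,
    k_floor: float = 0.05,
) -> list[FlowIndexMap]:
    """Default pipeline: per-frame spatial contrast -> flow index ->
    temporal smoothing.  Returns the smoothed flow-map sequence."""
    maps = [
        flow_index(spatial_contrast(frame, spatial_window), k_floor) for frame in frames
    ]
    if smooth_window > len(maps):
        warnings.warn(
            f"smooth window {smooth_window} longer than stack ({len(maps)}); "
            "using the full stack",
            stacklevel=2,
        )
        smooth_window = len(maps)
    return smooth_temporal(maps, smooth_window)
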