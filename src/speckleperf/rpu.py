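"""Relative Perfusion Unit (RPU) quantification.

RPU places a region's raw flow value on a scene-relative percent scale
anchored by a maximally perfused ("Hot") and minimally perfused ("Cold")
reference region:

    RPU = 100 * (ROI_raw - Cold_raw) / (Hot_raw - Cold_raw)

All regions (ROIs and references) are discrete disks of a fixed pixel
area (default 317).  Values are quantified on single flow maps and then
averaged over a small number of representative frames (default 5) spread
across one cardiac-cycle window so pulsatile phases average out.  RPU is
never clipped: regions brighter than Hot legitimately read slightly above
100.  References are user-supplied coordinates (manual selection);
:func:`validate_references` only advises.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .contrast import FlowIndexMap

DEFAULT_AREA_PX = 317
ALTERNATE_AREA_PX = 21  # second region area printed in the source methods


class RegionError(ValueError):
    pass


class DegenerateReferenceError(ValueError):
    """Hot reference does not strictly exceed the Cold reference."""


@dataclass
class RegionSample:
    """A sampled region: center, member pixels, and its mean raw value."""

    center: tuple[float, float]
    mean_raw: float
    pixels: np.ndarray | None = None  # (area, 2) int array of (row, col)
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_raw):
            raise RegionError("mean_raw must be finite")

    @property
    def area(self) -> int | None:
        return None if self.pixels is None else len(self.pixels)


@dataclass
class ReferencePair:
    hot: RegionSample
    cold: RegionSample

    def __post_init__(self) -> None:
        if not self.hot.mean_raw > self.cold.mean_raw:
            raise DegenerateReferenceError(
                f"hot reference ({self.hot.mean_raw:.4g}) must strictly exceed "
                f"cold reference ({self.cold.mean_raw:.4g})"
            )

    @classmethod
    def from_values(cls, hot_raw: float, cold_raw: float) -> "ReferencePair":
        """Reference pair from fixed raw values (e.g. frozen baseline refs)."""
        return cls(
            hot=RegionSample(center=(np.nan, np.nan), mean_raw=float(hot_raw)),
            cold=RegionSample(center=(np.nan, np.nan), mean_raw=float(cold_raw)),
        )

    @property
    def separation(self) -> float:
        return self.hot.mean_raw - self.cold.mean_raw


@dataclass
class RPUMeasurement:
    """Per-frame RPU values for one ROI and their arithmetic mean."""

    roi_center: tuple[float, float]
    rpu_per_frame: np.ndarray
    frame_indices: tuple[int, ...]
    mean_rpu: float = dc_field(init=False)

    def __post_init__(self) -> None:
        self.rpu_per_frame = np.asarray(self.rpu_per_frame, dtype=np.float64)
        self.mean_rpu = float(self.rpu_per_frame.mean())

    @property
    def n_frames_averaged(self) -> int:
        return len(self.rpu_per_frame)


# ---------------------------------------------------------------------------
# discrete-disk region extraction
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def disk_offsets(area_px: int = DEFAULT_AREA_PX) -> np.ndarray:
    """Offsets of the ``area_px`` pixels nearest the origin.

    Ties at equal radius are broken by angle (counter-clockwise from the
    +col axis) and then row-major order, so the region shape is unique and
    reproducible.
    """
    if area_px < 1:
        raise RegionError("area_px must be >= 1")
    r = int(math.ceil(math.sqrt(area_px / math.pi))) + 2
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    dr, dc = dr.ravel(), dc.ravel()
    dist2 = dr * dr + dc * dc
    ang = np.mod(np.arctan2(dr, dc), 2 * np.pi)
    order = np.lexsort((dc, dr, ang, dist2))
    chosen = order[:area_px]
    return np.stack([dr[chosen], dc[chosen]], axis=1)


def extract_region(
    fmap: FlowIndexMap | np.ndarray,
    center: tuple[float, float],
    area_px: int = DEFAULT_AREA_PX,
    frame_index: int | None = None,
) -> RegionSample:
    """Sample the discrete disk of ``area_px`` pixels around ``center``.

    The center is rounded to the nearest pixel; the full region must lie
    inside the map.
    """
    values = fmap.values if isinstance(fmap, FlowIndexMap) else np.asarray(fmap)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    off = disk_offsets(area_px)
    rr, cc = r0 + off[:, 0], c0 + off[:, 1]
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= values.shape[0] or cc.max() >= values.shape[1]:
        raise RegionError(
            f"region of {area_px} px at center ({center[0]:.1f}, {center[1]:.1f}) "
            f"clips the map border {values.shape}"
        )
    pix = np.stack([rr, cc], axis=1)
    return RegionSample(
        center=(float(center[0]), float(center[1])),
        mean_raw=float(values[rr, cc].mean()),
        pixels=pix,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# the RPU ratio
# ---------------------------------------------------------------------------


def compute_rpu(roi_raw: float | np.ndarray, refs: ReferencePair) -> float | np.ndarray:
    """The relative-perfusion ratio, in percent.  Never clipped.

    Invariant under affine rescaling ``x -> a + b x`` (b > 0) applied to
    the ROI and both references alike.
    """
    sep = refs.separation
    if sep <= 0:  # ReferencePair construction already guards this
        raise DegenerateReferenceError("hot raw must strictly exceed cold raw")
    out = 100.0 * (np.asarray(roi_raw, dtype=np.float64) - refs.cold.mean_raw) / sep
    return float(out) if np.ndim(roi_raw) == 0 else out


def select_frames(
    n_available: int,
    n: int = 5,
    cardiac_window_s: float = 0.5,
    frame_rate: float = 120.0,
) -> tuple[int, ...]:
    """Default representative-frame selector.

    Spreads ``n`` frames evenly over one cardiac-cycle span (default 0.5 s)
    so systolic and diastolic phases average out; if fewer frames are
    available the whole sequence is spanned.
    """
    if n_available < n:
        raise RegionError(f"need at least {n} frames, got {n_available}")
    span = min(n_available, max(n, int(round(cardiac_window_s * frame_rate))))
    idx = np.round(np.linspace(0, span - 1, n)).astype(int)
    return tuple(int(i) for i in idx)


def rpu_over_frames(
    maps: Sequence[FlowIndexMap],
    refs: ReferencePair | tuple[tuple[float, float], tuple[float, float]],
    roi_center: tuple[float, float],
    n: int = 5,
    selector: Callable[[int, int], Sequence[int]] | Sequence[int] | None = None,
    area_px: int = DEFAULT_AREA_PX,
    cardiac_window_s: float = 0.5,
    frame_rate: float = 120.0,
) -> RPUMeasurement:
    """RPU of one ROI averaged over ``n`` representative frames.

    ``refs`` may be a pair of (hot, cold) center coordinates — references
    are then re-sampled on each selected frame — or a fixed
    :class:`ReferencePair` of raw values (e.g. frozen at an occlusion
    baseline).
    """
    if len(maps) < n:
        raise RegionError(f"need at least {n} flow maps, got {len(maps)}")
    if selector is None:
        indices = select_frames(len(maps), n, cardiac_window_s, frame_rate)
    elif callable(selector):
        indices = tuple(int(i) for i in selector(len(maps), n))
    else:
        indices = tuple(int(i) for i in selector)
    if len(indices) != n:
        raise RegionError(f"selector returned {len(indices)} frames, expected {n}")

    fixed = isinstance(refs, ReferencePair)
    rpus = []
    for i in indices:
        roi = extract_region(maps[i], roi_center, area_px, frame_index=i)
        if fixed:
            pair = refs
        else:
            hot_c, cold_c = refs
            pair = ReferencePair(
                hot=extract_region(maps[i], hot_c, area_px, frame_index=i),
                cold=extract_region(maps[i], cold_c, area_px, frame_index=i),
            )
        rpus.append(compute_rpu(roi.mean_raw, pair))
    return RPUMeasurement(
        roi_center=(float(roi_center[0]), float(roi_center[1])),
        rpu_per_frame=np.asarray(rpus),
        frame_indices=indices,
    )


# ---------------------------------------------------------------------------
# advisory reference validation
# ---------------------------------------------------------------------------


@dataclass
class ReferenceReport:
    separation: float
    hot_percentile: float
    cold_percentile: float
    map_range: float
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_references(
    refs: ReferencePair,
    fmap: FlowIndexMap | np.ndarray,
    mask: np.ndarray | None = None,
    min_separation_frac: float = 0.2,
) -> ReferenceReport:
    """Advisory check of a manually selected reference pair.

    Reports the hot-cold separation and the percentile of each reference
    within the map's tissue values, warning (never failing) when the
    separation is below ``min_separation_frac`` of the map range.
    """
    values = fmap.values if isinstance(fmap, FlowIndexMap) else np.asarray(fmap)
    tissue = values[mask] if mask is not None else values.ravel()
    vrange = float(tissue.max() - tissue.min())
    msgs: list[str] = []
    sep = refs.separation
    if vrange > 0 and sep < min_separation_frac * vrange:
        msgs.append(
            f"hot-cold separation {sep:.3g} is below {min_separation_frac:.0%} "
            f"of the map range {vrange:.3g}"
        )
    hot_pct = float((tissue <= refs.hot.mean_raw).mean() * 100.0)
    cold_pct = float((tissue <= refs.cold.mean_raw).mean() * 100.0)
    if hot_pct < 90.0:
        msgs.append(f"hot reference sits at the {hot_pct:.1f}th percentile (< 90th)")
    if cold_pct > 10.0:
        msgs.append(f"cold reference sits at the {cold_pct:.1f}th percentile (> 10th)")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return ReferenceReport(
        separation=sep,
        hot_percentile=hot_pct,
        cold_percentile=cold_pct,
        map_range=vrange,
        warnings=msgs,
    )
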