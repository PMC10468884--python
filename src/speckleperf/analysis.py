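"""Statistical readouts of the perfusion experiments.

Reproduces the study's analyses on recovered RPU data: segment
classification along the ischemia gradient (one-way ANOVA), paired
mesenteric vs antimesenteric arc comparison, two-piece breakpoint
detection of the perfusion decline onset, ordinary least squares of mean
RPU on mean arterial pressure, and the paired anastomosis comparison.
All tests are two-sided; matched-point designs use paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .contrast import FlowIndexMap
from .rpu import ReferencePair, RegionError, rpu_over_frames
from .scene import PerfusionScene

DEFAULT_SEGMENTS: dict[str, tuple[float, float]] = {
    "ischemic": (0.0, 2.0),
    "watershed": (4.0, 6.0),
    "perfused": (8.0, 10.0),
}


class AnalysisError(ValueError):
    pass


@dataclass
class GradientProfile:
    """Ordered (distance, RPU) samples along a named arc."""

    distances_cm: np.ndarray
    rpu: np.ndarray
    arc: str = ""
    segments: Mapping[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )

    def __post_init__(self) -> None:
        self.distances_cm = np.asarray(self.distances_cm, dtype=np.float64)
        self.rpu = np.asarray(self.rpu, dtype=np.float64)
        if self.distances_cm.shape != self.rpu.shape:
            raise AnalysisError("distances and RPU values must align")
        if np.any(np.diff(self.distances_cm) <= 0):
            raise AnalysisError("profile distances must be strictly increasing")

    def __len__(self) -> int:
        return len(self.distances_cm)

    def segment_values(self, name: str) -> np.ndarray:
        lo, hi = self.segments[name]
        sel = (self.distances_cm >= lo - 1e-9) & (self.distances_cm <= hi + 1e-9)
        return self.rpu[sel]


@dataclass
class OcclusionSeries:
    """Per-step (MAP, mean RPU) pairs for one bowel segment."""

    kind: str
    segment: str
    map_mmhg: np.ndarray
    rpu: np.ndarray

    def __post_init__(self) -> None:
        self.map_mmhg = np.asarray(self.map_mmhg, dtype=np.float64)
        self.rpu = np.asarray(self.rpu, dtype=np.float64)
        if len(self.map_mmhg) < 3:
            raise AnalysisError("an occlusion series needs at least 3 points")
        if np.any(np.diff(self.map_mmhg) >= 0):
            raise AnalysisError("MAP must be strictly decreasing over steps")


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    paired: bool
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise AnalysisError("p-value outside [0, 1]")


@dataclass
class RegressionResult:
    slope: float  # RPU percent per mmHg
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise AnalysisError("R^2 outside [0, 1]")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------


def arc_profile(
    maps: Sequence[FlowIndexMap],
    scene: PerfusionScene,
    arc: str,
    refs: ReferencePair | tuple[tuple[float, float], tuple[float, float]],
    spacing_cm: float = 0.5,
    d_max_cm: float | None = None,
    n_frames: int = 5,
    area_px: int = 317,
    frame_rate: float = 120.0,
    segments: Mapping[str, tuple[float, float]] | None = None,
) -> GradientProfile:
    """Measure an RPU-vs-distance profile along a scene arc.

    Region centers are placed every ``spacing_cm`` from the arc origin;
    samples whose region would clip the map border are dropped with a
    warning rather than silently.
    """
    if spacing_cm <= 0:
        raise AnalysisError("spacing_cm must be positive")
    if arc not in scene.arcs:
        raise AnalysisError(f"scene has no arc named {arc!r}")
    length = scene.arc_length_cm(arc)
    if d_max_cm is not None:
        length = min(length, d_max_cm)
    dists = np.arange(0.0, length + 1e-9, spacing_cm)
    if len(dists) == 0:
        dists = np.array([0.0])

    kept_d, kept_rpu, dropped = [], [], []
    for d in dists:
        center = scene.arc_point(arc, d)
        try:
            m = rpu_over_frames(
                maps, refs, tuple(center), n=n_frames, area_px=area_px, frame_rate=frame_rate
            )
        except RegionError:
            dropped.append(float(d))
            continue
        kept_d.append(float(d))
        kept_rpu.append(m.mean_rpu)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} clipped profile sample(s) on arc {arc!r} "
            f"at {dropped} cm",
            stacklevel=2,
        )
    if not kept_d:
        raise AnalysisError(f"no valid profile samples along arc {arc!r}")
    return GradientProfile(
        distances_cm=np.asarray(kept_d),
        rpu=np.asarray(kept_rpu),
        arc=arc,
        segments=dict(segments or DEFAULT_SEGMENTS),
    )


def ground_truth_profile(
    scene: PerfusionScene, arc: str, spacing_cm: float = 0.5, d_max_cm: float | None = None
) -> GradientProfile:
    """Profile of the scene's ground-truth field along an arc (no imaging)."""
    length = scene.arc_length_cm(arc)
    if d_max_cm is not None:
        length = min(length, d_max_cm)
    dists = np.arange(0.0, length + 1e-9, spacing_cm)
    vals = scene.value_at_distance(arc, dists)
    return GradientProfile(distances_cm=dists, rpu=np.asarray(vals), arc=arc)


# ---------------------------------------------------------------------------
# segment summaries and comparisons
# ---------------------------------------------------------------------------


@dataclass
class SegmentSummary:
    per_segment: dict[str, tuple[float, float, int]]  # name -> (mean, sd, n)
    anova: ComparisonResult


def segment_summary(
    profiles: GradientProfile | Sequence[GradientProfile],
) -> SegmentSummary:
    """Per-segment mean +/- SD and a one-way ANOVA across the segments.

    Samples falling in the gaps between labelled segments are excluded;
    each segment needs at least 2 samples.
    """
    if isinstance(profiles, GradientProfile):
        profiles = [profiles]
    segs = profiles[0].segments
    groups: dict[str, np.ndarray] = {}
    for name in segs:
        vals = np.concatenate([p.segment_values(name) for p in profiles])
        if len(vals) < 2:
            raise AnalysisError(f"segment {name!r} has fewer than 2 samples")
        groups[name] = vals
    f_stat, p = stats.f_oneway(*groups.values())
    if not np.isfinite(f_stat):  # identical values in every group
        f_stat, p = 0.0, 1.0
    per_segment = {
        name: (float(v.mean()), float(v.std(ddof=1)), int(len(v)))
        for name, v in groups.items()
    }
    anova = ComparisonResult(
        test_name="one-way ANOVA",
        statistic=float(f_stat),
        p_value=float(p),
        group_means=tuple(per_segment[n][0] for n in groups),
        group_sds=tuple(per_segment[n][1] for n in groups),
        paired=False,
        n=int(sum(len(v) for v in groups.values())),
    )
    return SegmentSummary(per_segment=per_segment, anova=anova)


def _paired_t(a: np.ndarray, b: np.ndarray, name: str) -> ComparisonResult:
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
        if not np.isfinite(p):
            warnings.warn("degenerate paired t-test (zero-variance differences)", stacklevel=3)
            p = np.nan
    return ComparisonResult(
        test_name=name,
        statistic=float(t),
        p_value=float(p),
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        paired=True,
        n=len(a),
    )


def compare_arcs(
    profile_mes: GradientProfile,
    profile_antimes: GradientProfile,
    segments: Sequence[str] = ("watershed", "perfused"),
) -> ComparisonResult:
    """Paired t-test of mesenteric vs antimesenteric RPU at matched
    distances, restricted to the given segments (default: the zones where
    the arcs are meaningfully perfused)."""
    d1, d2 = profile_mes.distances_cm, profile_antimes.distances_cm
    common = np.intersect1d(np.round(d1, 6), np.round(d2, 6))
    bands = [profile_mes.segments[s] for s in segments]
    keep = np.zeros(len(common), dtype=bool)
    for lo, hi in bands:
        keep |= (common >= lo - 1e-9) & (common <= hi + 1e-9)
    common = common[keep]
    if len(common) < 3:
        raise AnalysisError("need at least 3 matched distances for the arc comparison")
    a = profile_mes.rpu[np.isin(np.round(d1, 6), common)]
    b = profile_antimes.rpu[np.isin(np.round(d2, 6), common)]
    return _paired_t(a, b, "paired t-test (mesenteric vs antimesenteric)")


def compare_anastomoses(
    am_points: Sequence[float], m_points: Sequence[float]
) -> ComparisonResult:
    """Paired t-test over matched points of the two anastomoses."""
    a = np.asarray(am_points, dtype=np.float64)
    b = np.asarray(m_points, dtype=np.float64)
    if a.shape != b.shape:
        raise AnalysisError(f"matched point sets differ in length: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise AnalysisError("need at least 3 matched points")
    return _paired_t(a, b, "paired t-test (antimesenteric vs mesenteric anastomosis)")


# ---------------------------------------------------------------------------
# decline-onset detection
# ---------------------------------------------------------------------------


def _two_piece_fit(d: np.ndarray, y: np.ndarray, b: float) -> tuple[float, float, float]:
    """Least-squares continuous two-piece linear fit with break at ``b``.

    Returns (sse, left_slope, right_slope).
    """
    X = np.column_stack([np.ones_like(d), d - b, np.maximum(d - b, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), float(beta[1]), float(beta[1] + beta[2])


def detect_decline_onset(
    profile: GradientProfile,
    fit_window_cm: tuple[float, float] = (2.0, 8.0),
    slope_ratio: float = 2.0,
) -> float | None:
    """Breakpoint of a continuous two-piece linear model of RPU vs distance.

    Candidate breakpoints are the sample positions strictly inside the fit
    window (with at least two samples on each side); the candidate
    minimising the total squared error wins.  The proximal (toward the
    staple line) slope must exceed the distal slope in magnitude by
    ``slope_ratio``, otherwise no onset is reported (``None``).
    """
    lo, hi = fit_window_cm
    sel = (profile.distances_cm >= lo - 1e-9) & (profile.distances_cm <= hi + 1e-9)
    d = profile.distances_cm[sel]
    y = profile.rpu[sel]
    if len(d) < 6 or d.min() > lo + 1e-6 or d.max() < hi - 1e-6:
        raise AnalysisError(
            f"onset detection needs >= 6 samples spanning {lo}-{hi} cm "
            f"(got {len(d)} over {d.min() if len(d) else float('nan'):.1f}-"
            f"{d.max() if len(d) else float('nan'):.1f})"
        )
    best: tuple[float, float, float, float] | None = None  # sse, b, sl, sr
    for b in d[2:-2]:
        sse, sl, sr = _two_piece_fit(d, y, float(b))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(b), sl, sr)
    assert best is not None
    _, b, sl, sr = best
    if abs(sl) < slope_ratio * abs(sr):
        return None
    return b


# ---------------------------------------------------------------------------
# MAP regression
# ---------------------------------------------------------------------------


def map_rpu_regression(series: OcclusionSeries) -> RegressionResult:
    """Ordinary least squares of mean RPU on MAP; R^2 = 1 - SSE/SST."""
    x, y = series.map_mmhg, series.rpu
    if np.allclose(x.std(), 0.0):
        raise AnalysisError("zero MAP variance; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )
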