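"""Synthetic perfusion scenes for the three porcine bowel experiments.

A :class:`PerfusionScene` stores a ground-truth per-pixel perfusion field on
the relative 0-100 scale (percent of the maximally perfused reference), a
tissue mask, the physical scale, named measurement arcs and named landmark
points.  Three builders produce the study phantoms:

* :func:`build_gradient_scene` - a stapled, partially devascularized bowel
  loop with a perfused plateau, a slope break at the decline onset, and an
  ischemic zone at the staple line, plus distinct mesenteric /
  antimesenteric arc levels.
* :func:`build_occlusion_schedule` - MAP-coupled global perfusion scaling
  under progressive arterial or venous occlusion.
* :func:`build_anastomosis_scene` - two side-to-side anastomoses with ten
  matched measurement points each.

Geometry is simplified to rectangular bands with parallel arcs: every
reported quantity depends only on distance along an arc, not on the
photographed loop shape.  Fields are deterministic functions of their
configuration; the only randomness in this module is the occlusion
schedule noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .defaults import paper_defaults


class SceneConfigError(ValueError):
    """A scene configuration violates its invariants."""


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------


@dataclass
class PerfusionScene:
    """Ground-truth perfusion field with geometry metadata.

    Attributes
    ----------
    field
        2-D float array of perfusion values in [0, 110] (percent scale).
    mask
        Boolean tissue mask; True wherever ``field`` can be nonzero.
    px_per_cm
        Spatial scale in pixels per cm.
    arcs
        Named polylines, each an ``(N, 2)`` float array of (row, col)
        vertices ordered by increasing distance from the arc origin
        (the stapled-edge landmark for bowel scenes).
    landmarks
        Named (row, col) points, e.g. ``hot_reference`` / ``cold_reference``.
    meta
        Provenance: builder name, configuration, matched distances, etc.
    """

    field: np.ndarray
    mask: np.ndarray
    px_per_cm: float
    arcs: dict[str, np.ndarray] = dc_field(default_factory=dict)
    landmarks: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.field.shape != self.mask.shape:
            raise SceneConfigError("field and mask shapes differ")
        if self.px_per_cm <= 0:
            raise SceneConfigError("px_per_cm must be positive")
        if self.field.min() < 0 or self.field.max() > 110:
            raise SceneConfigError("field values must lie in [0, 110]")
        if np.any((self.field > 0) & ~self.mask):
            raise SceneConfigError("mask must be true wherever field > 0")
        for name, arc in self.arcs.items():
            arc = np.asarray(arc, dtype=np.float64)
            if arc.ndim != 2 or arc.shape[1] != 2 or len(arc) < 2:
                raise SceneConfigError(f"arc {name!r} must be an (N>=2, 2) polyline")
            self.arcs[name] = arc
            rr = np.clip(np.round(arc[:, 0]).astype(int), 0, self.field.shape[0] - 1)
            cc = np.clip(np.round(arc[:, 1]).astype(int), 0, self.field.shape[1] - 1)
            if not self.mask[rr, cc].all():
                raise SceneConfigError(f"arc {name!r} leaves the tissue mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape

    def arc_point(self, arc: str, distance_cm: float | np.ndarray) -> np.ndarray:
        """Interpolate (row, col) at a distance (cm) along a named arc."""
        poly = self.arcs[arc]
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])  # px along the polyline
        t = np.asarray(distance_cm, dtype=np.float64) * self.px_per_cm
        if np.any(t < -1e-9) or np.any(t > s[-1] + 1e-9):
            raise ValueError(f"distance outside arc {arc!r} (length {s[-1] / self.px_per_cm:.2f} cm)")
        r = np.interp(t, s, poly[:, 0])
        c = np.interp(t, s, poly[:, 1])
        return np.stack([r, c], axis=-1)

    def arc_length_cm(self, arc: str) -> float:
        poly = self.arcs[arc]
        return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum() / self.px_per_cm)

    def value_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinear ground-truth lookup at fractional (row, col) points.

        Agrees exactly with the grid at integer coordinates.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return ndimage.map_coordinates(self.field, pts.T, order=1, mode="nearest")

    def value_at_distance(self, arc: str, distance_cm: float | np.ndarray) -> np.ndarray:
        """Ground truth interpolated at a distance along an arc."""
        pts = np.atleast_2d(self.arc_point(arc, distance_cm))
        return self.value_at(pts)

    def scaled(self, factor: float) -> "PerfusionScene":
        """Scene with globally scaled perfusion (occlusion steps)."""
        if not 0.0 <= factor <= 1.0:
            raise ValueError("scale factor must lie in [0, 1]")
        meta = dict(self.meta)
        meta["scale_factor"] = factor
        return PerfusionScene(
            field=self.field * factor,
            mask=self.mask.copy(),
            px_per_cm=self.px_per_cm,
            arcs={k: v.copy() for k, v in self.arcs.items()},
            landmarks=dict(self.landmarks),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# gradient (devascularized loop) scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientSceneConfig:
    """Calibration of the progressively ischemic bowel-loop phantom.

    Levels are percent perfusion.  ``watershed_level`` is the target *mean*
    over the watershed window (4-6 cm); the profile value at the slope
    break is solved from it.  ``arc_offset`` is the mesenteric minus
    antimesenteric difference in the perfused zone and ``mesenteric_share``
    the fraction of it lying above the centerline level.
    """

    plateau_level: float = 98.8
    watershed_level: float = 78.3
    ischemic_level: float = 1.9
    decline_onset_cm: float = 5.0
    devasc_margin_cm: float = 4.0
    arc_offset: float = 16.6
    mesenteric_share: float = 1.2 / 16.6
    ischemic_end_cm: float = 2.0
    plateau_start_cm: float = 8.0
    watershed_band: tuple[float, float] = (4.0, 6.0)
    calibration_spacing_cm: float = 0.5
    calibration_area_px: int = 317
    length_cm: float = 11.0
    band_width_cm: float = 5.0
    cold_pad_cm: float = 1.25
    px_per_cm: float = 20.0
    seed: int = 0

    @classmethod
    def from_defaults(cls, **overrides) -> "GradientSceneConfig":
        d = paper_defaults("gradient")
        d.pop("px_per_cm_note", None)
        d.update(overrides)
        return cls(**d)

    def validate(self) -> None:
        if not (0 <= self.ischemic_level < self.watershed_level < self.plateau_level <= 105):
            raise SceneConfigError(
                "level ordering violated: need 0 <= ischemic < watershed < plateau <= 105"
            )
        if not (0 < self.decline_onset_cm < 10):
            raise SceneConfigError("decline_onset_cm must lie in (0, 10)")
        if not (self.ischemic_end_cm < self.decline_onset_cm < self.plateau_start_cm):
            raise SceneConfigError("decline onset must sit between ischemic end and plateau start")
        if not 0 <= self.mesenteric_share <= 1:
            raise SceneConfigError("mesenteric_share must lie in [0, 1]")
        if self.px_per_cm <= 0 or self.length_cm <= 0 or self.band_width_cm <= 0:
            raise SceneConfigError("geometry parameters must be positive")


def _solve_onset_level(cfg: GradientSceneConfig) -> float:
    """Profile value at the slope break such that the *measured* watershed
    mean equals ``watershed_level``.

    The measurement protocol averages disk regions (default 317 px) placed
    every 0.5 cm across the 4-6 cm window, so the calibration target is the
    disk-averaged profile at those discrete distances, not the continuous
    window integral.  The profile is piecewise linear, hence the target is
    affine in the unknown; two evaluations give the exact solution.
    """
    from .rpu import disk_offsets  # local import: rpu does not import scene

    lo, hi = cfg.watershed_band
    sample_d = np.arange(lo, hi + 1e-9, cfg.calibration_spacing_cm)
    off_cm = disk_offsets(cfg.calibration_area_px)[:, 1] / cfg.px_per_cm

    def window_mean(v: float) -> float:
        d = (sample_d[:, None] + off_cm[None, :]).ravel()
        return float(_longitudinal_profile(d, cfg, v).mean())

    m0 = window_mean(0.0)
    m1 = window_mean(1.0)
    if abs(m1 - m0) < 1e-12:  # watershed window does not see the break
        return cfg.watershed_level
    v = (cfg.watershed_level - m0) / (m1 - m0)
    if not (cfg.ischemic_level < v < cfg.plateau_level):
        raise SceneConfigError(
            f"watershed_level {cfg.watershed_level} unreachable with the configured "
            f"anchors (solved break value {v:.2f})"
        )
    return v


def _longitudinal_profile(
    d_cm: np.ndarray, cfg: GradientSceneConfig, onset_level: float
) -> np.ndarray:
    """Centerline perfusion vs distance from the stapled edge (cm).

    Flat ischemic floor to ``ischemic_end_cm``, steep linear rise to the
    break at ``decline_onset_cm``, gentle linear rise to the plateau at
    ``plateau_start_cm``, flat plateau beyond.  Distances < 0 (the dead
    cold pad behind the staple line) map to zero perfusion.
    """
    d = np.asarray(d_cm, dtype=np.float64)
    xp = [cfg.ischemic_end_cm, cfg.decline_onset_cm, cfg.plateau_start_cm]
    fp = [cfg.ischemic_level, onset_level, cfg.plateau_level]
    out = np.interp(d, xp, fp)  # clamps to ischemic_level / plateau_level
    out = np.where(d < 0, 0.0, out)
    return out


def gradient_base_profile(cfg: GradientSceneConfig, d_cm: np.ndarray) -> np.ndarray:
    """Public centerline ground-truth profile for a gradient configuration."""
    cfg.validate()
    return _longitudinal_profile(np.asarray(d_cm, dtype=float), cfg, _solve_onset_level(cfg))


def build_gradient_scene(cfg: GradientSceneConfig | None = None) -> PerfusionScene:
    """Build the progressively ischemic bowel-loop phantom.

    The band carries three longitudinal lanes: a mesenteric lane offset by
    ``+mesenteric_share * arc_offset``, a centerline lane at the base
    profile, and an antimesenteric lane offset by the remainder downward.
    Lateral offsets fade with the longitudinal ischemia fraction so the
    ischemic zone is uniformly dead.  A zero-flow cold pad sits behind the
    staple line and hosts the Cold reference landmark.
    """
    if cfg is None:
        cfg = GradientSceneConfig.from_defaults()
    cfg.validate()

    ppc = cfg.px_per_cm
    margin = 20
    left = 5
    pad_px = int(round(cfg.cold_pad_cm * ppc))
    staple_col = left + pad_px
    length_px = int(round(cfg.length_cm * ppc))
    band_px = int(round(cfg.band_width_cm * ppc))
    H = 2 * margin + band_px
    W = staple_col + length_px + 6
    r0, r1 = margin, margin + band_px - 1  # inclusive band rows

    cols = np.arange(W)
    d_cm = (cols - staple_col) / ppc
    onset_level = _solve_onset_level(cfg)
    base = _longitudinal_profile(d_cm, cfg, onset_level)

    # ischemia fraction controls how much of the arc offset survives
    frac = np.clip(
        (base - cfg.ischemic_level) / (cfg.plateau_level - cfg.ischemic_level), 0.0, 1.0
    )

    lane = band_px // 3
    mes_rows = (r0, r0 + lane - 1)
    anti_rows = (r1 - lane + 1, r1)
    blend = max(3, lane // 10)
    off_mes = cfg.mesenteric_share * cfg.arc_offset
    off_anti = -(1.0 - cfg.mesenteric_share) * cfg.arc_offset
    rows = np.arange(H)
    row_knots = [
        mes_rows[1] - blend,
        mes_rows[1] + blend + 1,
        anti_rows[0] - blend - 1,
        anti_rows[0] + blend,
    ]
    lateral = np.interp(rows, row_knots, [off_mes, 0.0, 0.0, off_anti])

    field = np.zeros((H, W))
    band = slice(r0, r1 + 1)
    field[band, :] = base[None, :] + lateral[band, None] * frac[None, :]
    field[:, : staple_col] = 0.0  # cold pad + left margin: dead
    field = np.clip(field, 0.0, 110.0)

    end_col = staple_col + length_px
    mask = np.zeros((H, W), dtype=bool)
    mask[band, left : end_col + 1] = True
    field[~mask] = 0.0

    mes_row = float((mes_rows[0] + mes_rows[1]) // 2)
    anti_row = float((anti_rows[0] + anti_rows[1]) // 2)
    mid_row = float(r0 + band_px // 2)
    arcs = {
        "mesenteric": np.array([[mes_row, staple_col], [mes_row, end_col]], dtype=float),
        "centerline": np.array([[mid_row, staple_col], [mid_row, end_col]], dtype=float),
        "antimesenteric": np.array([[anti_row, staple_col], [anti_row, end_col]], dtype=float),
    }
    landmarks = {
        "stapled_edge": (mid_row, float(staple_col)),
        "devascularization_margin": (mid_row, staple_col + cfg.devasc_margin_cm * ppc),
        "hot_reference": (mes_row, staple_col + 9.5 * ppc),
        "cold_reference": (mid_row, float(staple_col - pad_px // 2)),
    }
    return PerfusionScene(
        field=field,
        mask=mask,
        px_per_cm=ppc,
        arcs=arcs,
        landmarks=landmarks,
        meta={
            "builder": "gradient",
            "config": cfg.__dict__ | {"watershed_band": list(cfg.watershed_band)},
            "onset_level": onset_level,
            "staple_col": staple_col,
        },
    )


# ---------------------------------------------------------------------------
# occlusion schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OcclusionConfig:
    """MAP coupling of a progressive-occlusion schedule.

    The MAP scale is invented (the source experiments print none):
    baseline 65 mmHg, kind-specific end value.  The global perfusion scale
    factor is linear in MAP with slope ``sensitivity`` per mmHg plus
    Gaussian noise of ``noise_sd`` percent of full scale.
    """

    map_baseline_mmhg: float = 65.0
    map_end_mmhg: float = 20.0
    end_scale: float = 0.05
    noise_sd: float = 6.4

    @classmethod
    def from_defaults(cls, kind: str, **overrides) -> "OcclusionConfig":
        d = paper_defaults("occlusion")
        if kind not in ("arterial", "venous"):
            raise ValueError(f"unknown occlusion kind {kind!r}")
        merged = {
            "map_baseline_mmhg": d["map_baseline_mmhg"],
            "end_scale": d["end_scale"],
            "map_end_mmhg": d[kind]["map_end_mmhg"],
            "noise_sd": d[kind]["noise_sd"],
        }
        merged.update(overrides)
        return cls(**merged)

    @property
    def sensitivity(self) -> float:
        """Perfusion-scale drop per mmHg of MAP decline."""
        return (1.0 - self.end_scale) / (self.map_baseline_mmhg - self.map_end_mmhg)


@dataclass
class OcclusionSchedule:
    """Ordered occlusion steps: fraction, MAP (mmHg), perfusion scale."""

    kind: str
    occlusion_fraction: np.ndarray
    map_mmhg: np.ndarray
    scale: np.ndarray
    sensitivity: float
    noise_sd: float

    def __post_init__(self) -> None:
        self.occlusion_fraction = np.asarray(self.occlusion_fraction, dtype=float)
        self.map_mmhg = np.asarray(self.map_mmhg, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.kind not in ("arterial", "venous"):
            raise ValueError(f"unknown occlusion kind {self.kind!r}")
        if np.any(np.diff(self.map_mmhg) >= 0):
            raise SceneConfigError("MAP must be strictly decreasing over steps")
        if self.scale.min() < 0 or self.scale.max() > 1:
            raise SceneConfigError("scale factors must lie in [0, 1]")
        if np.any(np.diff(self.scale) > 1e-12):
            raise SceneConfigError("scale factors must be non-increasing")

    def __len__(self) -> int:
        return len(self.scale)


def build_occlusion_schedule(
    kind: str,
    n_steps: int = 10,
    cfg: OcclusionConfig | None = None,
    seed: int = 0,
) -> OcclusionSchedule:
    """Progressive arterial/venous occlusion schedule.

    Venous congestion is the more sensitive condition: its default
    configuration reaches the same near-zero residual scale over a much
    smaller MAP drop, i.e. a steeper scale-per-mmHg slope.  The baseline
    step is noise-free (scale exactly 1), the final step is clamped to
    ``end_scale``, and monotonicity is enforced on the noisy factors.
    """
    if kind not in ("arterial", "venous"):
        raise ValueError(f"unknown occlusion kind {kind!r}")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    if cfg is None:
        cfg = OcclusionConfig.from_defaults(kind)
    rng = np.random.default_rng(seed)

    occ = np.linspace(0.0, 1.0, n_steps)
    mp = cfg.map_baseline_mmhg - (cfg.map_baseline_mmhg - cfg.map_end_mmhg) * occ
    clean = 1.0 - cfg.sensitivity * (cfg.map_baseline_mmhg - mp)
    noise = rng.normal(0.0, cfg.noise_sd / 100.0, size=n_steps)
    noise[0] = 0.0
    scale = np.clip(clean + noise, 0.0, 1.0)
    scale[occ >= 1.0] = np.minimum(scale[occ >= 1.0], cfg.end_scale)
    scale = np.minimum.accumulate(scale)
    return OcclusionSchedule(
        kind=kind,
        occlusion_fraction=occ,
        map_mmhg=mp,
        scale=scale,
        sensitivity=cfg.sensitivity,
        noise_sd=cfg.noise_sd,
    )


# ---------------------------------------------------------------------------
# anastomosis scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnastomosisSceneConfig:
    """Two side-to-side anastomoses with ten matched points over 0-4.5 cm."""

    am_profile: tuple[float, ...] = tuple(paper_defaults("anastomosis")["am_profile"])
    m_profile: tuple[float, ...] = tuple(paper_defaults("anastomosis")["m_profile"])
    span_cm: float = 4.5
    band_width_cm: float = 1.55
    px_per_cm: float = 20.0
    seed: int = 0

    @classmethod
    def from_defaults(cls, **overrides) -> "AnastomosisSceneConfig":
        d = paper_defaults("anastomosis")
        d["am_profile"] = tuple(d["am_profile"])
        d["m_profile"] = tuple(d["m_profile"])
        d.update(overrides)
        return cls(**d)

    def validate(self) -> None:
        if len(self.am_profile) != 10 or len(self.m_profile) != 10:
            raise SceneConfigError("anastomosis profiles must have exactly 10 points")
        am = np.asarray(self.am_profile)
        m = np.asarray(self.m_profile)
        if np.any(am <= m):
            raise SceneConfigError(
                "antimesenteric profile must exceed mesenteric at every matched point"
            )
        if am.min() < 0 or am.max() > 110 or m.min() < 0 or m.max() > 110:
            raise SceneConfigError("profile values must lie in [0, 110]")

    @property
    def matched_distances_cm(self) -> np.ndarray:
        return np.linspace(0.0, self.span_cm, 10)


def build_anastomosis_scene(cfg: AnastomosisSceneConfig | None = None) -> PerfusionScene:
    """Build the paired-anastomoses phantom.

    Two horizontal bands (antimesenteric on top, mesenteric below) carry
    linearly interpolated point profiles along their arcs, extrapolated
    slightly beyond the measured span so sampling disks at the end points
    see a locally linear field.  Hot (100) and Cold (0) reference pads sit
    to the right of the bands.
    """
    if cfg is None:
        cfg = AnastomosisSceneConfig.from_defaults()
    cfg.validate()

    ppc = cfg.px_per_cm
    band_px = int(round(cfg.band_width_cm * ppc))
    margin_cm = 0.75
    start_col = 25 + int(round(margin_cm * ppc))
    span_px = int(round(cfg.span_cm * ppc))
    pad_w = 40
    W = start_col + span_px + int(round(margin_cm * ppc)) + pad_w + 30
    H = 4 * 25 + 2 * band_px

    am_r0 = 25
    m_r0 = 25 + band_px + 50
    d = cfg.matched_distances_cm
    cols = np.arange(W)
    d_cols = (cols - start_col) / ppc

    def profile_line(values: Sequence[float]) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        slope0 = (v[1] - v[0]) / (d[1] - d[0])
        slope1 = (v[-1] - v[-2]) / (d[-1] - d[-2])
        out = np.interp(d_cols, d, v)
        lo = d_cols < d[0]
        hi = d_cols > d[-1]
        out[lo] = v[0] + slope0 * (d_cols[lo] - d[0])
        out[hi] = v[-1] + slope1 * (d_cols[hi] - d[-1])
        return np.clip(out, 0.0, 110.0)

    field = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=bool)
    band_cols = slice(start_col - int(margin_cm * ppc), start_col + span_px + int(margin_cm * ppc) + 1)
    for r0, prof in ((am_r0, cfg.am_profile), (m_r0, cfg.m_profile)):
        rows = slice(r0, r0 + band_px)
        field[rows, band_cols] = profile_line(prof)[band_cols]
        mask[rows, band_cols] = True

    pad_col0 = W - pad_w - 10
    pads = {
        "hot_reference": (slice(am_r0, am_r0 + band_px), 100.0),
        "cold_reference": (slice(m_r0, m_r0 + band_px), 0.0),
    }
    landmarks: dict[str, tuple[float, float]] = {}
    for name, (rows, level) in pads.items():
        field[rows, pad_col0 : pad_col0 + pad_w] = level
        mask[rows, pad_col0 : pad_col0 + pad_w] = True
        rmid = (rows.start + rows.stop - 1) / 2.0
        landmarks[name] = (rmid, pad_col0 + pad_w / 2.0)

    am_row = am_r0 + (band_px - 1) / 2.0
    m_row = m_r0 + (band_px - 1) / 2.0
    arcs = {
        "anastomosis_AM": np.array([[am_row, start_col], [am_row, start_col + span_px]], dtype=float),
        "anastomosis_M": np.array([[m_row, start_col], [m_row, start_col + span_px]], dtype=float),
    }
    return PerfusionScene(
        field=field,
        mask=mask,
        px_per_cm=ppc,
        arcs=arcs,
        landmarks=landmarks,
        meta={
            "builder": "anastomosis",
            "config": {
                "am_profile": list(cfg.am_profile),
                "m_profile": list(cfg.m_profile),
                "span_cm": cfg.span_cm,
                "band_width_cm": cfg.band_width_cm,
                "px_per_cm": cfg.px_per_cm,
                "seed": cfg.seed,
            },
            "matched_distances_cm": d.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# flat calibration scenes (testing / linearity checks)
# ---------------------------------------------------------------------------


def build_flat_scene(
    levels: Sequence[float],
    patch_px: int = 41,
    gap_px: int = 12,
    px_per_cm: float = 20.0,
) -> PerfusionScene:
    """Row of uniform square patches at the given perfusion levels.

    Patch centers are exposed as landmarks ``patch_0`` ... ``patch_{n-1}``;
    if 100 and 0 are among the levels their patches are additionally
    labelled ``hot_reference`` / ``cold_reference``.  Used for calibration
    and end-to-end recovery checks.
    """
    levels = list(levels)
    if not levels:
        raise SceneConfigError("need at least one level")
    if min(levels) < 0 or max(levels) > 110:
        raise SceneConfigError("levels must lie in [0, 110]")
    n = len(levels)
    H = patch_px + 2 * gap_px
    W = n * patch_px + (n + 1) * gap_px
    field = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=bool)
    landmarks: dict[str, tuple[float, float]] = {}
    for i, lev in enumerate(levels):
        c0 = gap_px + i * (patch_px + gap_px)
        field[gap_px : gap_px + patch_px, c0 : c0 + patch_px] = lev
        mask[gap_px : gap_px + patch_px, c0 : c0 + patch_px] = True
        center = (gap_px + (patch_px - 1) / 2.0, c0 + (patch_px - 1) / 2.0)
        landmarks[f"patch_{i}"] = center
        if lev == 100.0 and "hot_reference" not in landmarks:
            landmarks["hot_reference"] = center
        if lev == 0.0 and "cold_reference" not in landmarks:
            landmarks["cold_reference"] = center
    return PerfusionScene(
        field=field,
        mask=mask,
        px_per_cm=px_per_cm,
        arcs={},
        landmarks=landmarks,
        meta={"builder": "flat", "levels": levels},
    )
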