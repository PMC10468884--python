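"""End-to-end experiment drivers and the umbrella pipeline.

Each driver runs the full measurement chain — build scene, render raw
speckle video, compute flow-index maps, place Hot/Cold references at the
scene landmarks, quantify RPU — and then applies the scenario's
statistics.  :func:`run_pipeline` wraps a driver and writes all artifacts
(stacks, maps, CSVs, heatmaps, JSON summary) with provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    ComparisonResult,
    GradientProfile,
    OcclusionSeries,
    RegressionResult,
    SegmentSummary,
    arc_profile,
    compare_anastomoses,
    compare_arcs,
    detect_decline_onset,
    map_rpu_regression,
    segment_summary,
    DEFAULT_SEGMENTS,
)
from .contrast import FlowIndexMap, video_to_flow_maps
from .defaults import paper_defaults
from .io import config_hash, save_scene, write_flow_maps, write_video
from .render import OpticsConfig, render_video
from .rpu import ReferencePair, extract_region, rpu_over_frames, select_frames
from .scene import (
    AnastomosisSceneConfig,
    GradientSceneConfig,
    OcclusionSchedule,
    PerfusionScene,
    build_anastomosis_scene,
    build_gradient_scene,
    build_occlusion_schedule,
)
from .viz import save_heatmap

log = logging.getLogger("speckleperf")


class PipelineError(RuntimeError):
    pass


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def scene_flow_maps(
    scene: PerfusionScene,
    optics: OpticsConfig,
    n_frames: int,
    seed: int,
    spatial_window: int = 7,
    smooth_window: int = 5,
    k_floor: float = 0.05,
) -> list[FlowIndexMap]:
    """Render a scene and return its smoothed flow-index map sequence."""
    video = render_video(scene, optics, n_frames=n_frames, seed=seed)
    return video_to_flow_maps(video.frames, spatial_window, smooth_window, k_floor)


# ---------------------------------------------------------------------------
# gradient experiment
# ---------------------------------------------------------------------------


@dataclass
class GradientResult:
    scene: PerfusionScene
    profiles: dict[str, GradientProfile]
    summary: SegmentSummary
    arc_comparison: ComparisonResult
    onset_cm: float | None
    seed: int


def run_gradient_experiment(
    seed: int = 0,
    cfg: GradientSceneConfig | None = None,
    optics: OpticsConfig | None = None,
    n_frames: int = 64,
    spacing_cm: float = 0.5,
    keep_maps: bool = False,
) -> GradientResult:
    """Devascularized-loop scenario: gradient profiles along all three
    arcs, segment summary (centerline), arc comparison, decline onset."""
    cfg = cfg or GradientSceneConfig.from_defaults()
    optics = optics or OpticsConfig(**paper_defaults("optics"))
    cd = paper_defaults("contrast")
    rd = paper_defaults("rpu")

    scene = build_gradient_scene(cfg)
    maps = scene_flow_maps(
        scene, optics, n_frames, seed, cd["spatial_window"], cd["smooth_window"], cd["k_floor"]
    )
    refs = (scene.landmarks["hot_reference"], scene.landmarks["cold_reference"])
    profiles = {
        arc: arc_profile(
            maps,
            scene,
            arc,
            refs,
            spacing_cm=spacing_cm,
            d_max_cm=10.0,
            n_frames=rd["n_frames"],
            area_px=rd["area_px"],
            frame_rate=optics.frame_rate,
        )
        for arc in ("centerline", "mesenteric", "antimesenteric")
    }
    summary = segment_summary(profiles["centerline"])
    comparison = compare_arcs(profiles["mesenteric"], profiles["antimesenteric"])
    ad = paper_defaults("analysis")
    onset = detect_decline_onset(
        profiles["centerline"],
        fit_window_cm=tuple(ad["onset_window_cm"]),
        slope_ratio=ad["onset_slope_ratio"],
    )
    result = GradientResult(
        scene=scene,
        profiles=profiles,
        summary=summary,
        arc_comparison=comparison,
        onset_cm=onset,
        seed=seed,
    )
    if keep_maps:
        result.maps = maps  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# occlusion experiment
# ---------------------------------------------------------------------------


@dataclass
class OcclusionResult:
    kind: str
    schedule: OcclusionSchedule
    series: dict[str, OcclusionSeries]
    regressions: dict[str, RegressionResult]
    seed: int


def run_occlusion_experiment(
    kind: str = "arterial",
    seed: int = 0,
    n_steps: int = 10,
    cfg: GradientSceneConfig | None = None,
    optics: OpticsConfig | None = None,
    frames_per_step: int = 16,
    segments: Sequence[str] = ("perfused", "watershed"),
    rois_per_segment: int = 3,
) -> OcclusionResult:
    """Progressive-occlusion scenario.

    The gradient scene is globally scaled by each schedule step's
    perfusion factor and re-imaged.  References are *frozen at the
    baseline step*: re-sampling Hot/Cold on occluded frames would cancel
    the global change out of the ratio and no MAP correlation could be
    measured.  Per-segment mean RPU is regressed on MAP.
    """
    cfg = cfg or GradientSceneConfig.from_defaults()
    optics = optics or OpticsConfig(**paper_defaults("optics"))
    cd = paper_defaults("contrast")
    rd = paper_defaults("rpu")
    seeds = _child_seeds(seed, n_steps + 1)
    schedule = build_occlusion_schedule(kind, n_steps, seed=seeds[0])

    scene = build_gradient_scene(cfg)
    hot_c = scene.landmarks["hot_reference"]
    cold_c = scene.landmarks["cold_reference"]

    roi_centers: dict[str, list[tuple[float, float]]] = {}
    for seg in segments:
        lo, hi = DEFAULT_SEGMENTS[seg]
        ds = np.linspace(lo, hi, rois_per_segment)
        roi_centers[seg] = [tuple(scene.arc_point("centerline", d)) for d in ds]

    baseline_refs: ReferencePair | None = None
    seg_rpu: dict[str, list[float]] = {seg: [] for seg in segments}
    for i, factor in enumerate(schedule.scale):
        maps = scene_flow_maps(
            scene.scaled(float(factor)),
            optics,
            frames_per_step,
            seeds[i + 1],
            cd["spatial_window"],
            cd["smooth_window"],
            cd["k_floor"],
        )
        if i == 0:
            idx = select_frames(len(maps), rd["n_frames"], rd["cardiac_window_s"], optics.frame_rate)
            hot_raw = float(np.mean([extract_region(maps[j], hot_c, rd["area_px"]).mean_raw for j in idx]))
            cold_raw = float(np.mean([extract_region(maps[j], cold_c, rd["area_px"]).mean_raw for j in idx]))
            baseline_refs = ReferencePair.from_values(hot_raw, cold_raw)
        assert baseline_refs is not None
        for seg in segments:
            vals = [
                rpu_over_frames(
                    maps, baseline_refs, c, n=rd["n_frames"], area_px=rd["area_px"], frame_rate=optics.frame_rate
                ).mean_rpu
                for c in roi_centers[seg]
            ]
            seg_rpu[seg].append(float(np.mean(vals)))

    series = {
        seg: OcclusionSeries(kind=kind, segment=seg, map_mmhg=schedule.map_mmhg, rpu=np.asarray(vals))
        for seg, vals in seg_rpu.items()
    }
    regressions = {seg: map_rpu_regression(s) for seg, s in series.items()}
    return OcclusionResult(kind=kind, schedule=schedule, series=series, regressions=regressions, seed=seed)


# ---------------------------------------------------------------------------
# anastomosis experiment
# ---------------------------------------------------------------------------


@dataclass
class AnastomosisResult:
    scene: PerfusionScene
    distances_cm: np.ndarray
    am_rpu: np.ndarray
    m_rpu: np.ndarray
    comparison: ComparisonResult
    seed: int

    @property
    def am_mean(self) -> float:
        return float(self.am_rpu.mean())

    @property
    def m_mean(self) -> float:
        return float(self.m_rpu.mean())


def run_anastomosis_experiment(
    seed: int = 0,
    cfg: AnastomosisSceneConfig | None = None,
    optics: OpticsConfig | None = None,
    n_frames: int = 64,
) -> AnastomosisResult:
    """Paired-anastomoses scenario: RPU at the ten matched points on each
    anastomosis arc, then a paired comparison."""
    cfg = cfg or AnastomosisSceneConfig.from_defaults()
    optics = optics or OpticsConfig(**paper_defaults("optics"))
    cd = paper_defaults("contrast")
    rd = paper_defaults("rpu")

    scene = build_anastomosis_scene(cfg)
    maps = scene_flow_maps(
        scene, optics, n_frames, seed, cd["spatial_window"], cd["smooth_window"], cd["k_floor"]
    )
    refs = (scene.landmarks["hot_reference"], scene.landmarks["cold_reference"])
    dists = np.asarray(scene.meta["matched_distances_cm"])
    out = {}
    for arc in ("anastomosis_AM", "anastomosis_M"):
        vals = []
        for d in dists:
            c = tuple(scene.arc_point(arc, float(d)))
            vals.append(
                rpu_over_frames(
                    maps, refs, c, n=rd["n_frames"], area_px=rd["area_px"], frame_rate=optics.frame_rate
                ).mean_rpu
            )
        out[arc] = np.asarray(vals)
    comparison = compare_anastomoses(out["anastomosis_AM"], out["anastomosis_M"])
    return AnastomosisResult(
        scene=scene,
        distances_cm=dists,
        am_rpu=out["anastomosis_AM"],
        m_rpu=out["anastomosis_M"],
        comparison=comparison,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# umbrella pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    scenario: str  # gradient | occlusion | anastomosis
    seed: int = 0
    out_dir: str | Path = "pipeline_out"
    n_frames: int = 32
    occlusion_kind: str = "arterial"
    write_stacks: bool = False

    def validate(self) -> None:
        if self.scenario not in ("gradient", "occlusion", "anastomosis"):
            raise PipelineError(f"unknown scenario {self.scenario!r}")


def _comparison_dict(c: ComparisonResult) -> dict:
    return {
        "test": c.test_name,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "group_means": list(c.group_means),
        "group_sds": list(c.group_sds),
        "paired": c.paired,
        "n": c.n,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run a named scenario end to end, writing all artifacts + summary.

    Deterministic per (config, seed): re-running reproduces the same
    summary JSON byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config_hash(
            {k: str(v) for k, v in config.__dict__.items() if k != "out_dir"}
        ),
        "version": __version__,
    }
    summary: dict = {"provenance": provenance}
    log.info("pipeline: scenario=%s seed=%d", config.scenario, config.seed)

    if config.scenario == "gradient":
        res = run_gradient_experiment(seed=config.seed, n_frames=config.n_frames)
        save_scene(res.scene, out / "scene")
        save_heatmap(out / "ground_truth.png", res.scene.field, title="Ground-truth perfusion")
        rows = []
        for arc, prof in res.profiles.items():
            for d, v in zip(prof.distances_cm, prof.rpu):
                rows.append({"arc": arc, "distance_cm": d, "rpu": v})
        pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)
        summary["segments"] = {
            name: {"mean": m, "sd": s, "n": n} for name, (m, s, n) in res.summary.per_segment.items()
        }
        summary["anova"] = _comparison_dict(res.summary.anova)
        summary["arc_comparison"] = _comparison_dict(res.arc_comparison)
        summary["onset_cm"] = res.onset_cm
    elif config.scenario == "occlusion":
        res = run_occlusion_experiment(
            kind=config.occlusion_kind, seed=config.seed, frames_per_step=config.n_frames
        )
        rows = []
        for seg, series in res.series.items():
            for mp, v in zip(series.map_mmhg, series.rpu):
                rows.append({"segment": seg, "map_mmhg": mp, "rpu": v})
        pd.DataFrame(rows).to_csv(out / "occlusion_series.csv", index=False)
        summary["kind"] = res.kind
        summary["regressions"] = {
            seg: {"slope": r.slope, "intercept": r.intercept, "r_squared": r.r_squared, "n": r.n}
            for seg, r in res.regressions.items()
        }
    else:
        res = run_anastomosis_experiment(seed=config.seed, n_frames=config.n_frames)
        save_scene(res.scene, out / "scene")
        save_heatmap(out / "ground_truth.png", res.scene.field, title="Ground-truth perfusion")
        pd.DataFrame(
            {
                "distance_cm": res.distances_cm,
                "antimesenteric_rpu": res.am_rpu,
                "mesenteric_rpu": res.m_rpu,
            }
        ).to_csv(out / "anastomosis_points.csv", index=False)
        summary["means"] = {"antimesenteric": res.am_mean, "mesenteric": res.m_mean}
        summary["comparison"] = _comparison_dict(res.comparison)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
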