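"""File formats: multi-frame TIFF stacks with JSON sidecars, scene
serialization, and ROI/reference coordinate CSVs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .contrast import FlowIndexMap
from .render import OpticsConfig, SpeckleVideo
from .scene import PerfusionScene


class StackFormatError(ValueError):
    pass


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, frames: np.ndarray, meta: dict | None = None) -> Path:
    """Write a grayscale (n, H, W) stack as a multi-frame TIFF + sidecar."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise StackFormatError("expected a 2-D frame or (n, H, W) stack")
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = {"n_frames": int(len(frames)), "dtype": str(frames.dtype), "version": __version__}
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-frame grayscale TIFF stack and its sidecar (if any).

    RGB pages and malformed/truncated files raise :class:`StackFormatError`
    naming the offending page; no partial data is returned.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            for i, page in enumerate(tif.pages):
                if page.samplesperpixel != 1:
                    raise StackFormatError(
                        f"{path.name}: page {i} is not grayscale "
                        f"({page.samplesperpixel} samples/pixel)"
                    )
                try:
                    pages.append(page.asarray())
                except Exception as exc:
                    raise StackFormatError(f"{path.name}: cannot decode page {i}: {exc}") from exc
            if not pages:
                raise StackFormatError(f"{path.name}: no image pages")
            frames = np.stack(pages)
    except StackFormatError:
        raise
    except Exception as exc:
        raise StackFormatError(f"{path.name}: malformed TIFF: {exc}") from exc
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        expected = meta.get("n_frames")
        if expected is not None and expected != len(frames):
            raise StackFormatError(
                f"{path.name}: truncated stack — sidecar promises {expected} "
                f"frames, file holds {len(frames)} (failing page {len(frames)})"
            )
    return frames, meta


def write_video(path: str | Path, video: SpeckleVideo) -> Path:
    return write_stack(
        path,
        video.frames,
        meta={
            "optics": video.optics.__dict__,
            "scene_id": video.scene_id,
            "seed": video.seed,
        },
    )


def write_flow_maps(path: str | Path, maps: Sequence[FlowIndexMap]) -> Path:
    stack = np.stack([m.values for m in maps]).astype(np.float32)
    return write_stack(
        path,
        stack,
        meta={"k_floor": maps[0].k_floor, "provenance": maps[0].provenance},
    )


def read_flow_maps(path: str | Path) -> list[FlowIndexMap]:
    frames, meta = read_stack(path)
    k_floor = float(meta.get("k_floor", 0.05))
    return [FlowIndexMap(values=f, k_floor=k_floor, provenance=dict(meta.get("provenance", {}))) for f in frames]


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


def save_scene(scene: PerfusionScene, out_dir: str | Path) -> Path:
    """Serialize a scene: field/mask TIFFs + a JSON geometry sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "field.tif", scene.field.astype(np.float32))
    tifffile.imwrite(out / "mask.tif", scene.mask.astype(np.uint8))
    geo = {
        "px_per_cm": scene.px_per_cm,
        "arcs": {k: np.asarray(v).tolist() for k, v in scene.arcs.items()},
        "landmarks": {k: list(v) for k, v in scene.landmarks.items()},
        "meta": scene.meta,
        "version": __version__,
    }
    (out / "scene.json").write_text(json.dumps(geo, indent=2, default=str))
    return out


def load_scene(in_dir: str | Path) -> PerfusionScene:
    src = Path(in_dir)
    geo = json.loads((src / "scene.json").read_text())
    return PerfusionScene(
        field=tifffile.imread(src / "field.tif"),
        mask=tifffile.imread(src / "mask.tif").astype(bool),
        px_per_cm=float(geo["px_per_cm"]),
        arcs={k: np.asarray(v, dtype=float) for k, v in geo["arcs"].items()},
        landmarks={k: tuple(v) for k, v in geo["landmarks"].items()},
        meta=geo.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# ROI / reference coordinates
# ---------------------------------------------------------------------------


def write_rois(path: str | Path, rois: dict[str, tuple[float, float]], area_px: int = 317) -> Path:
    df = pd.DataFrame(
        [{"name": k, "row": r, "col": c, "area_px": area_px} for k, (r, c) in rois.items()]
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_rois(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"name", "row", "col"}
    if not required.issubset(df.columns):
        raise StackFormatError(f"ROI CSV must have columns {sorted(required)}")
    if "area_px" not in df.columns:
        df["area_px"] = 317
    return df
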