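"""Time-resolved raw speckle rendering from a perfusion scene.

The proprietary device algorithm behind the source data is unpublished, so
this module adopts the standard single-exposure speckle-contrast physics
(Fercher/Briers, Lorentzian velocity spectrum): at exposure time ``T`` and
correlation time ``tau_c`` the squared speckle contrast is

    K^2(T, tau_c) = (tau_c / 2T) * [2 - (tau_c / T) * (1 - exp(-2T/tau_c))]

Perfusion (0-100 relative scale) maps to ``tau_c`` by numerically
inverting this closed form so that the downstream flow index ``1/K^2`` is
*affine* in perfusion — the generator's calibration contract.  Two render
modes exist:

* ``analytic`` — per-pixel integrated intensities drawn from the gamma
  approximation of single-exposure speckle (shape ``1/K^2``); fast, the
  default for tests and experiments.
* ``dynamic`` — a complex speckle field evolving as a per-pixel AR(1)
  process with field correlation ``exp(-dt/tau_c)``, exposure-integrated
  over substeps; slower, serves as the physics oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Callable
import warnings

import numpy as np
from scipy import ndimage, optimize

from .scene import PerfusionScene


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition model: camera timing, intensity scale and speckle physics.

    ``tau_static`` caps the correlation time at zero flow (quasi-static
    speckle, contrast near 1); ``tau_full_perfusion`` anchors perfusion
    100.  Between the anchors the flow index ``1/K^2`` is affine in
    perfusion.  ``exposure_time`` must fit inside the frame period.
    """

    frame_rate: float = 120.0
    exposure_time: float = 0.005
    speckle_grain_px: float = 1.0
    bit_depth: int = 16
    mean_intensity: float = 1000.0
    mode: str = "analytic"
    substeps_per_frame: int = 64
    tau_static: float = 0.1
    tau_full_perfusion: float = 1.0e-4
    read_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.exposure_time > 1.0 / self.frame_rate + 1e-12:
            raise RenderError("exposure_time exceeds the frame period")
        if self.mode not in ("analytic", "dynamic"):
            raise RenderError(f"unknown render mode {self.mode!r}")
        if self.mode == "dynamic" and self.substeps_per_frame < 8:
            raise RenderError("dynamic mode needs substeps_per_frame >= 8")
        if self.bit_depth not in (8, 16):
            raise RenderError("bit_depth must be 8 or 16")
        if not (0 < self.tau_full_perfusion < self.tau_static):
            raise RenderError("need 0 < tau_full_perfusion < tau_static")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_count(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class SpeckleVideo:
    """Ordered stack of raw grayscale speckle frames plus provenance."""

    frames: np.ndarray  # (n_frames, H, W), integer dtype
    optics: OpticsConfig
    scene_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise RenderError("frames must be a non-empty (n, H, W) stack")
        if self.frames.max() > self.optics.max_count:
            raise RenderError("frame intensities exceed the bit depth")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# closed-form contrast model and its inversion
# ---------------------------------------------------------------------------


def contrast_sq(exposure: float, tau: np.ndarray | float) -> np.ndarray | float:
    """Squared single-exposure speckle contrast ``K^2(T, tau_c)``.

    Monotone increasing in ``tau``; tends to 0 as ``tau/T -> 0`` and to 1
    as ``tau/T -> inf``.
    """
    x = np.asarray(tau, dtype=np.float64) / exposure
    with np.errstate(over="ignore", under="ignore"):
        k2 = (x / 2.0) * (2.0 - x * (1.0 - np.exp(-2.0 / x)))
    return k2 if np.ndim(tau) else float(k2)


def _flow_index_anchors(optics: OpticsConfig) -> tuple[float, float]:
    f0 = 1.0 / contrast_sq(optics.exposure_time, optics.tau_static)
    f100 = 1.0 / contrast_sq(optics.exposure_time, optics.tau_full_perfusion)
    return f0, f100


def target_flow_index(p: np.ndarray | float, optics: OpticsConfig) -> np.ndarray | float:
    """Ground-truth flow index (``1/K^2``) as an affine function of perfusion."""
    f0, f100 = _flow_index_anchors(optics)
    return f0 + (f100 - f0) * np.asarray(p, dtype=np.float64) / 100.0


def perfusion_to_correlation_time(p: float | np.ndarray, optics: OpticsConfig) -> float | np.ndarray:
    """Correlation time (s) realising an affine-in-perfusion flow index.

    Solves ``K^2(T, tau) = 1 / f(p)`` by bracketed root finding, where
    ``f(p)`` interpolates the anchor flow indices at perfusion 0 and 100.
    Strictly decreasing in ``p``; ``p = 0`` returns the static cap.
    """
    scalar = np.ndim(p) == 0
    pa = np.atleast_1d(np.asarray(p, dtype=np.float64))
    if pa.min() < 0 or pa.max() > 110:
        raise RenderError("perfusion must lie in [0, 110]")
    k2_target = 1.0 / np.asarray(target_flow_index(pa, optics))
    T = optics.exposure_time
    lo = optics.tau_full_perfusion * 1e-3
    hi = optics.tau_static
    out = np.empty_like(pa)
    for i, k2 in enumerate(k2_target):
        if k2 >= contrast_sq(T, hi):
            out[i] = hi
            continue
        out[i] = optimize.brentq(lambda t: contrast_sq(T, t) - k2, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(out[0]) if scalar else out


def correlation_time_from_contrast(k: float, optics: OpticsConfig) -> float:
    """Invert the closed form: correlation time whose contrast equals ``k``."""
    T = optics.exposure_time
    k2 = k * k
    lo, hi = 1e-9, 1e3
    if k2 <= contrast_sq(T, lo):
        return lo
    if k2 >= contrast_sq(T, hi):
        return hi
    return optimize.brentq(lambda t: contrast_sq(T, t) - k2, lo, hi, xtol=1e-15, rtol=1e-12)


def _tau_map(p_field: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    """Fast vectorised perfusion -> tau lookup (fine monotone grid)."""
    grid = np.geomspace(optics.tau_full_perfusion * 1e-3, optics.tau_static, 4096)
    k2 = contrast_sq(optics.exposure_time, grid)
    k2_target = 1.0 / np.asarray(target_flow_index(p_field, optics))
    return np.interp(k2_target, k2, grid)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _quantize(frames: np.ndarray, optics: OpticsConfig, rng: np.random.Generator) -> np.ndarray:
    if optics.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, optics.read_noise_sd, size=frames.shape)
    return np.clip(np.round(frames), 0, optics.max_count).astype(optics.dtype)


def _render_analytic(
    p_field: np.ndarray, optics: OpticsConfig, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    if optics.speckle_grain_px != 1.0:
        warnings.warn(
            "analytic mode assumes a 1:1 pixel:speckle ratio; speckle_grain_px ignored",
            stacklevel=3,
        )
    shape = np.asarray(target_flow_index(p_field, optics))  # gamma shape = 1/K^2
    scale = optics.mean_intensity / shape
    frames = rng.gamma(shape[None, :, :], scale[None, :, :], size=(n_frames, *p_field.shape))
    return frames


def _grain_kernel_norm(sigma: float, shape: tuple[int, int]) -> float:
    delta = np.zeros(shape)
    delta[shape[0] // 2, shape[1] // 2] = 1.0
    k = ndimage.gaussian_filter(delta, sigma, mode="constant")
    return float(np.sqrt((k**2).sum()))


def _render_dynamic(
    p_field: np.ndarray, optics: OpticsConfig, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    tau = _tau_map(p_field, optics)
    n_sub = optics.substeps_per_frame
    dt = optics.exposure_time / n_sub
    if dt > tau.min() / 2.0:
        warnings.warn(
            f"substep {dt * 1e3:.3f} ms does not resolve the shortest correlation "
            f"time {tau.min() * 1e3:.3f} ms; rendered contrast will be biased",
            stacklevel=3,
        )
    rho_sub = np.exp(-dt / tau)
    gap = max(0.0, 1.0 / optics.frame_rate - optics.exposure_time)
    rho_gap = np.exp(-gap / tau)

    sigma = None
    knorm = 1.0
    if optics.speckle_grain_px > 1.0:
        sigma = optics.speckle_grain_px / 2.0
        knorm = _grain_kernel_norm(sigma, p_field.shape)

    def draw_complex() -> np.ndarray:
        z = (rng.standard_normal(p_field.shape) + 1j * rng.standard_normal(p_field.shape)) / np.sqrt(2.0)
        if sigma is not None:
            z = (ndimage.gaussian_filter(z.real, sigma) + 1j * ndimage.gaussian_filter(z.imag, sigma)) / knorm
        return z

    E = draw_complex()
    frames = np.empty((n_frames, *p_field.shape))
    for i in range(n_frames):
        acc = np.zeros(p_field.shape)
        for _ in range(n_sub):
            acc += np.abs(E) ** 2
            E = rho_sub * E + np.sqrt(1.0 - rho_sub**2) * draw_complex()
        frames[i] = acc / n_sub * optics.mean_intensity
        if gap > 0:
            E = rho_gap * E + np.sqrt(1.0 - rho_gap**2) * draw_complex()
    return frames


def render_video(
    scene: PerfusionScene,
    optics: OpticsConfig | None = None,
    n_frames: int = 5,
    seed: int | None = None,
) -> SpeckleVideo:
    """Render a raw speckle stack from a perfusion scene.

    Off-mask pixels are rendered as static (zero-flow) speckle at the same
    mean intensity, so contrast windows near tissue borders degrade
    gracefully.  Identical scene, optics and seed give byte-identical
    stacks.
    """
    if optics is None:
        optics = OpticsConfig()
    if n_frames < 1:
        raise RenderError("n_frames must be >= 1")
    if seed is None:
        seed = optics.seed if optics.seed is not None else 0
    rng = np.random.default_rng(seed)

    p_field = np.where(scene.mask, scene.field, 0.0)
    if optics.mode == "analytic":
        frames = _render_analytic(p_field, optics, n_frames, rng)
    else:
        frames = _render_dynamic(p_field, optics, n_frames, rng)
    frames = _quantize(frames, optics, rng)
    return SpeckleVideo(
        frames=frames,
        optics=optics,
        scene_id=str(scene.meta.get("builder", "scene")),
        seed=seed,
    )
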