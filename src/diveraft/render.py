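"""Render raft datasets as grayscale frame stacks.

Each surfaced bird is drawn as a bright soft-edged disk at its
perspective-projected pixel position; a dive is rendered as a splash that
swells briefly and then shrinks to nothing within two seconds, after
which the bird leaves no blob.  Optional per-pixel flicker emulates light
glinting on the water (what frame averaging exists to suppress).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .camera import CameraModel
from .dataset import RaftDataset

__all__ = ["RenderConfig", "render_frames", "save_frames", "load_frames"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering options.

    ``blob_radius_bl`` is the bird disk radius in body lengths; when None
    it is chosen so a mid-frame bird covers about ``target_area_px``
    pixels.  ``splash_grow_s`` / ``splash_end_s`` shape the dive splash
    (peak radius factor ``splash_peak`` at the end of the grow phase,
    gone by ``splash_end_s`` after the dive instant).
    """

    body_length_m: float = 0.7
    blob_radius_bl: float | None = None
    target_area_px: float = 20.0
    intensity: float = 230.0
    background: float = 20.0
    noise_sd: float = 0.0
    flicker_density: float = 0.0  # expected flicker speckles per frame / pixel
    flicker_intensity: float = 200.0
    splash_grow_s: float = 0.5
    splash_end_s: float = 1.5
    splash_peak: float = 1.6
    seed: int = 0


def _blob_radius_m(camera: CameraModel, cfg: RenderConfig) -> float:
    r_px = math.sqrt(cfg.target_area_px / math.pi)
    mpp = float(camera.metres_per_pixel(camera.cx, camera.cy))
    return r_px * mpp


def _draw_disk(frame: np.ndarray, u: float, v: float, r_px: float, value: float):
    h, w = frame.shape
    r_ext = int(math.ceil(r_px)) + 2
    u0, u1 = int(math.floor(u)) - r_ext, int(math.floor(u)) + r_ext + 1
    v0, v1 = int(math.floor(v)) - r_ext, int(math.floor(v)) + r_ext + 1
    u0c, u1c = max(u0, 0), min(u1, w)
    v0c, v1c = max(v0, 0), min(v1, h)
    if u0c >= u1c or v0c >= v1c:
        return
    uu = np.arange(u0c, u1c)[None, :]
    vv = np.arange(v0c, v1c)[:, None]
    d = np.hypot(uu - u, vv - v)
    patch = np.clip(r_px + 0.5 - d, 0.0, 1.0) * value
    np.maximum(frame[v0c:v1c, u0c:u1c], patch, out=frame[v0c:v1c, u0c:u1c])


def render_frames(
    dataset: RaftDataset,
    camera: CameraModel,
    config: RenderConfig | None = None,
    origin: tuple | None = None,
):
    """Render a dataset through a camera.

    Parameters
    ----------
    origin : optional (x_bl, y_bl, x_m, y_m)
        Dataset point mapped to ground point; by default the raft's mean
        position is centred on the camera's footprint centre.

    Returns
    -------
    frames : uint8 array, shape (n_frames, height, width)
    info : dict
        Mapping metadata: ``origin_bl``, ``origin_m``, ``body_length_m``,
        ``frame_times``, ``blob_radius_m`` and the count of clipped
        (out-of-frame) bird positions.
    """
    cfg = config or RenderConfig()
    rng = np.random.default_rng(cfg.seed)
    bl = cfg.body_length_m

    if origin is None:
        if len(dataset.tracks):
            cx_bl = float(dataset.tracks["x_bl"].mean())
            cy_bl = float(dataset.tracks["y_bl"].mean())
        else:
            cx_bl = cy_bl = 0.0
        gx, gy = camera.ground_center()
        origin = (cx_bl, cy_bl, gx, gy)
    ox_bl, oy_bl, ox_m, oy_m = origin

    def to_ground_m(x_bl, y_bl):
        return (np.asarray(x_bl) - ox_bl) * bl + ox_m, (
            np.asarray(y_bl) - oy_bl
        ) * bl + oy_m

    duration = dataset.duration
    n_frames = int(round(duration * camera.fps))
    frame_times = np.arange(n_frames) / camera.fps
    r_m = (
        cfg.blob_radius_bl * bl
        if cfg.blob_radius_bl is not None
        else _blob_radius_m(camera, cfg)
    )

    # per-bird sample arrays for fast lookup
    birds = []
    for (_, _), g in dataset.tracks.groupby(["raft_id", "bird_id"], sort=False):
        birds.append(
            (
                g["time_s"].to_numpy(float),
                g["x_bl"].to_numpy(float),
                g["y_bl"].to_numpy(float),
            )
        )
    dives = [
        (row.time_s, row.x_bl, row.y_bl) for row in dataset.dives.itertuples()
    ]

    frames = np.zeros((n_frames, camera.height, camera.width), dtype=np.uint8)
    clipped = 0
    eps = 0.5 / camera.fps
    for f, t in enumerate(frame_times):
        img = np.full((camera.height, camera.width), cfg.background, dtype=np.float32)
        for t_s, x_s, y_s in birds:
            if t < t_s[0] - eps or t > t_s[-1] + eps:
                continue
            i = int(np.searchsorted(t_s, t + eps)) - 1
            if i < 0:
                continue
            gx, gy = to_ground_m(x_s[i], y_s[i])
            u, v = camera.project(gx, gy)
            if not (np.isfinite(u) and np.isfinite(v)):
                clipped += 1
                continue
            r_px = r_m / float(camera.metres_per_pixel(u, np.clip(v, 0, camera.height - 1)))
            if u < -r_px or u > camera.width + r_px or v < -r_px or v > camera.height + r_px:
                clipped += 1
                continue
            _draw_disk(img, float(u), float(v), r_px, cfg.intensity)
        for t_d, x_d, y_d in dives:
            tau = t - t_d
            if tau < 0 or tau > cfg.splash_end_s:
                continue
            if tau <= cfg.splash_grow_s:
                factor = 1.0 + (cfg.splash_peak - 1.0) * tau / cfg.splash_grow_s
            else:
                factor = cfg.splash_peak * (
                    1.0 - (tau - cfg.splash_grow_s) / (cfg.splash_end_s - cfg.splash_grow_s)
                )
            if factor <= 0.05:
                continue
            gx, gy = to_ground_m(x_d, y_d)
            u, v = camera.project(gx, gy)
            if not (np.isfinite(u) and np.isfinite(v)):
                clipped += 1
                continue
            r_px = factor * r_m / float(
                camera.metres_per_pixel(u, np.clip(v, 0, camera.height - 1))
            )
            _draw_disk(img, float(u), float(v), r_px, cfg.intensity)
        if cfg.flicker_density > 0:
            n_spk = rng.poisson(cfg.flicker_density * img.size)
            if n_spk:
                ys = rng.integers(0, camera.height, n_spk)
                xs = rng.integers(0, camera.width, n_spk)
                img[ys, xs] = np.maximum(img[ys, xs], cfg.flicker_intensity)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)

    if clipped:
        log.warning("%d bird positions fell outside the camera footprint", clipped)
    info = {
        "origin_bl": (ox_bl, oy_bl),
        "origin_m": (ox_m, oy_m),
        "body_length_m": bl,
        "frame_times": frame_times,
        "blob_radius_m": r_m,
        "n_clipped": clipped,
    }
    return frames, info


def save_frames(frames: np.ndarray, out_dir, prefix: str = "frame") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def load_frames(in_dir, pattern: str = "*.png") -> np.ndarray:
    paths = sorted(Path(in_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern!r} in {in_dir}")
    return np.stack([iio.imread(p) for p in paths])
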