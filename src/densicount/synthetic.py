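"""Synthetic aerial-survey scenes for developing and testing the counter.

Real survey tiles of colonial animals have three awkward properties: the
objects are tiny (about 5 x 5 pixels), the background is heterogeneous rock/
guano/shadow texture with illumination gradients, and per-image counts range
from zero (pure background) to over a thousand in dense aggregations. The
generator reproduces that statistical regime — blob-like objects with shape
and intensity jitter on flat, textured, or illumination-gradient backgrounds,
with per-image counts drawn from the density-level bands L0 (0), L1 (1-100),
L2 (101-500), L3 (501-1000), L4 (1000+) — without attempting photorealism.
Objects are rendered as anisotropy-jittered Gaussian-profile blobs: what
matters for the counting problem is size, contrast and crowding, not
biological texture.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import PointAnnotationSet, write_annotations
from .targets import ConfigError

__all__ = ["SceneConfig", "LEVEL_BANDS", "generate_scene", "generate_dataset"]

# Ground-truth count bands of the density levels (inclusive).
LEVEL_BANDS: dict[str, tuple[int, int]] = {
    "L0": (0, 0),
    "L1": (1, 100),
    "L2": (101, 500),
    "L3": (501, 1000),
    "L4": (1001, 2000),
}

_BACKGROUNDS = ("flat", "textured", "illumination-gradient")


@dataclass
class SceneConfig:
    """One synthetic scene.

    ``n_objects`` may be an integer or a level name ("L0".."L4"), in which
    case the realized count is drawn uniformly from the level's band.
    ``object_size`` is the approximate blob diameter in pixels;
    ``object_contrast`` the mean intensity offset of objects against the
    local background (objects render darker, as dark-plumaged animals against
    pale ground); ``min_spacing`` the minimum center-to-center distance, 2 px
    by default so near-touching objects occur as they do in dense colonies.
    """

    image_size: tuple[int, int] = (448, 448)
    n_objects: int | str = 0
    object_size: float = 5.0
    object_contrast: float = 0.35
    background: str = "textured"
    min_spacing: float = 2.0
    margin: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.object_size < 2:
            raise ConfigError("object_size must be >= 2 pixels")
        if self.background not in _BACKGROUNDS:
            raise ConfigError(f"background must be one of {_BACKGROUNDS}")
        if isinstance(self.n_objects, str):
            if self.n_objects not in LEVEL_BANDS:
                raise ConfigError(f"unknown level {self.n_objects!r}")
        elif self.n_objects < 0:
            raise ConfigError("n_objects must be >= 0")


def _sample_positions(
    n: int, size: tuple[int, int], min_spacing: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample n points >= min_spacing apart via a spatial hash grid."""
    h, w = size
    lo_x, hi_x = margin, w - 1 - margin
    lo_y, hi_y = margin, h - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ConfigError("image too small for the requested margin")
    # generous feasibility guard: disc packing at min_spacing
    capacity = ((hi_x - lo_x) / min_spacing + 1) * ((hi_y - lo_y) / min_spacing + 1)
    if n > 0.7 * capacity:
        raise ConfigError(f"cannot place {n} objects with spacing {min_spacing} in {h}x{w}")
    cell = max(min_spacing, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while placed < n:
        if attempts >= max_attempts:
            raise ConfigError("object placement infeasible (spacing too tight)")
        attempts += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        ci, cj = int(x / cell), int(y / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    dx, dy = pts[idx, 0] - x, pts[idx, 1] - y
                    if dx * dx + dy * dy < min_spacing * min_spacing:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = (x, y)
            grid.setdefault((ci, cj), []).append(placed)
            placed += 1
    return pts


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_size
    base = rng.uniform(0.45, 0.65)
    lum = np.full((h, w), base)
    if cfg.background in ("textured", "illumination-gradient"):
        coarse = gaussian_filter(rng.standard_normal((h, w)), sigma=12.0)
        fine = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
        lum += 0.10 * coarse / max(coarse.std(), 1e-9)
        lum += 0.03 * fine / max(fine.std(), 1e-9)
    if cfg.background == "illumination-gradient":
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(theta) * xx / max(w - 1, 1)) + (np.sin(theta) * yy / max(h - 1, 1))
        lum += rng.uniform(0.1, 0.25) * (ramp - ramp.mean())
    lum += 0.01 * rng.standard_normal((h, w))  # sensor noise
    return lum


def _render_objects(
    lum: np.ndarray, pts: np.ndarray, cfg: SceneConfig, rng: np.random.Generator
) -> None:
    h, w = lum.shape
    r = int(np.ceil(cfg.object_size))  # window radius; blob sd ~ size/4
    for x, y in pts:
        sx = cfg.object_size / 4.0 * rng.uniform(0.8, 1.25)
        sy = cfg.object_size / 4.0 * rng.uniform(0.8, 1.25)
        rot = rng.uniform(0, np.pi)
        amp = cfg.object_contrast * rng.uniform(0.7, 1.3)
        cx, cy = int(np.floor(x)), int(np.floor(y))
        cols = np.arange(max(cx - r, 0), min(cx + r + 1, w))
        rows = np.arange(max(cy - r, 0), min(cy + r + 1, h))
        if len(cols) == 0 or len(rows) == 0:
            continue
        dx = cols[None, :] - x
        dy = rows[:, None] - y
        u = np.cos(rot) * dx + np.sin(rot) * dy
        v = -np.sin(rot) * dx + np.cos(rot) * dy
        blob = np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
        lum[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] -= amp * blob


def generate_scene(cfg: SceneConfig) -> tuple[np.ndarray, PointAnnotationSet]:
    """Render one scene; returns (uint8 RGB image, its point annotations)."""
    # independent streams: the background (and tint) must not depend on how
    # many objects are drawn, so matched scenes differ only at objects
    bg_rng, obj_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    if isinstance(cfg.n_objects, str):
        lo, hi = LEVEL_BANDS[cfg.n_objects]
        n = int(obj_rng.integers(lo, hi + 1))
    else:
        n = int(cfg.n_objects)
    lum = _background(cfg, bg_rng)
    # mild channel tint so the image is genuinely RGB
    tint = np.array([1.0, 0.97, 0.92]) * bg_rng.uniform(0.97, 1.03, size=3)
    pts = _sample_positions(n, cfg.image_size, cfg.min_spacing, cfg.margin, obj_rng)
    if n:
        _render_objects(lum, pts, cfg, obj_rng)
    lum = np.clip(lum, 0.0, 1.0)
    rgb = np.clip(lum[:, :, None] * tint[None, None, :], 0.0, 1.0)
    image = (rgb * 255.0 + 0.5).astype(np.uint8)
    ann = PointAnnotationSet(
        image_id=f"scene_{cfg.seed:06d}",
        points=[(float(x), float(y)) for x, y in pts],
        image_size=cfg.image_size,
    )
    return image, ann


def _apportion(n_images: int, level_mix: dict[str, float]) -> list[str]:
    """Largest-remainder apportionment of images to levels (exact histogram)."""
    levels = list(level_mix)
    total = sum(level_mix.values())
    if not np.isclose(total, 1.0):
        raise ConfigError(f"level mix must sum to 1, got {total}")
    raw = {lv: n_images * level_mix[lv] / total for lv in levels}
    counts = {lv: int(np.floor(raw[lv])) for lv in levels}
    short = n_images - sum(counts.values())
    for lv in sorted(levels, key=lambda l: raw[l] - counts[l], reverse=True)[:short]:
        counts[lv] += 1
    out: list[str] = []
    for lv in levels:
        out.extend([lv] * counts[lv])
    return out


def generate_dataset(
    n_images: int,
    level_mix: dict[str, float],
    seed: int,
    out_dir: str | Path | None = None,
    image_size: tuple[int, int] = (448, 448),
    object_size: float = 5.0,
    object_contrast: float = 0.35,
) -> list[tuple[np.ndarray, PointAnnotationSet]]:
    """Generate a dataset spanning the requested density-level mix.

    Level assignments follow the mix exactly (largest-remainder rounding);
    realized counts are uniform within each level's band; backgrounds cycle
    through flat / textured / illumination-gradient. When ``out_dir`` is
    given, PNG images, the annotation CSV and a JSON manifest are written.
    """
    ss = np.random.SeedSequence([int(seed), 0x5CE4E])
    order_rng = np.random.default_rng(ss)
    child_seeds = [int(s) for s in order_rng.integers(0, 2**31 - 1, size=n_images)]
    levels = _apportion(n_images, level_mix)
    order_rng.shuffle(levels)

    scenes: list[tuple[np.ndarray, PointAnnotationSet]] = []
    annotations: list[PointAnnotationSet] = []
    for i, (lv, child) in enumerate(zip(levels, child_seeds)):
        cfg = SceneConfig(
            image_size=image_size,
            n_objects=lv,
            object_size=object_size,
            object_contrast=object_contrast,
            background=_BACKGROUNDS[i % len(_BACKGROUNDS)],
            seed=child,
        )
        image, ann = generate_scene(cfg)
        ann.image_id = f"img_{i:04d}"
        scenes.append((image, ann))
        annotations.append(ann)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for image, ann in scenes:
            iio.imwrite(out / f"{ann.image_id}.png", image)
        write_annotations(annotations, out / "annotations.csv", out / "manifest.json")
        meta = {
            "n_images": n_images,
            "seed": int(seed),
            "level_mix": level_mix,
            "counts": {a.image_id: a.count for a in annotations},
        }
        (out / "dataset.json").write_text(json.dumps(meta, indent=1))
    return scenes
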