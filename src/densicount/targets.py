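"""Ground-truth generation: point annotations -> density maps and masks.

A density map is a non-negative 2-D field whose integral over any region is
the expected number of objects there. Each annotated point contributes a
truncated, discretely normalized isotropic Gaussian kernel, so summing the
whole map recovers the count. The full-resolution map ``D_gt`` is sum-pooled
by the network's output stride (8) into the learning target ``D_target``,
which in turn is thresholded into the binary segmentation target ``S_gt``.

Conventions used throughout the package: 0-based coordinates, x = column,
y = row, pixel centers at integer coordinates. Kernels overlapping the image
border are clipped without renormalization — mass outside the frame is
legitimately lost, which is also what makes tiling exact: an object straddling
a tile boundary splits fractional mass across the tiles it touches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .annotations import PointAnnotationSet

__all__ = [
    "GenerationConfig",
    "DensityMap",
    "SegmentationMap",
    "generate_density_map",
    "downsample_density",
    "make_segmentation_target",
    "tile_scene",
]


class ConfigError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class GenerationConfig:
    """Settings for density-map generation.

    sigma:
        Gaussian bandwidth in pixels. Default 4 — wide enough that ~5x5-px
        objects yield a trainable (non-sparse) target.
    truncation_radius:
        Kernel support half-width in multiples of sigma. The kernel is
        evaluated on a (2*truncation_radius*sigma + 1)^2 window and normalized
        to unit sum there, so interior points contribute exactly 1.0.
    downsample_factor:
        Output stride of the network; D_target = sum-pool of D_gt by this.
    seg_epsilon:
        Density threshold for the binary segmentation target (strict >).
    adaptive_bandwidth:
        Optional per-point bandwidth from neighbour distances instead of the
        fixed sigma (off by default; aerial animals are near-constant size).
    """

    sigma: float = 4.0
    truncation_radius: int = 4
    downsample_factor: int = 8
    seg_epsilon: float = 1e-3
    adaptive_bandwidth: bool = False
    adaptive_k: int = 3
    adaptive_beta: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigError(f"sigma must be positive, got {self.sigma}")
        if self.truncation_radius < 3:
            raise ConfigError("truncation_radius must be >= 3 (mass loss beyond 1e-6 otherwise)")
        if self.downsample_factor < 1:
            raise ConfigError("downsample_factor must be >= 1")
        if self.seg_epsilon <= 0:
            raise ConfigError("seg_epsilon must be positive")


@dataclass
class DensityMap:
    """Non-negative 2-D grid; integral over a region = expected count there."""

    values: np.ndarray
    resolution_divisor: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ContractError("density map must be 2-D")
        if np.any(self.values < 0):
            raise ContractError("density map must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class SegmentationMap:
    """2-D grid marking object-bearing locations.

    ``mode="binary"``: values exactly 0/1 (ground truth).
    ``mode="probability"``: values in [0, 1] (network output).
    """

    values: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ContractError("segmentation map must be 2-D")
        if self.mode == "binary":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ContractError("binary segmentation map must contain only 0 and 1")
        elif self.mode == "probability":
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ContractError("probability segmentation map must lie in [0, 1]")
        else:
            raise ContractError(f"unknown segmentation mode {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _point_sigmas(ann: PointAnnotationSet, cfg: GenerationConfig) -> np.ndarray:
    if not cfg.adaptive_bandwidth or len(ann) < 2:
        return np.full(len(ann), cfg.sigma)
    pts = np.asarray(ann.points, dtype=np.float64)
    k = min(cfg.adaptive_k, len(ann) - 1)
    dists, _ = cKDTree(pts).query(pts, k=k + 1)
    sigmas = cfg.adaptive_beta * dists[:, 1:].mean(axis=1)
    return np.maximum(sigmas, 0.5)  # floor: never narrower than one pixel


def generate_density_map(ann: PointAnnotationSet, cfg: GenerationConfig | None = None) -> DensityMap:
    """Build the full-resolution ground-truth density map D_gt.

    Each point places a 2-D isotropic Gaussian of bandwidth ``cfg.sigma``
    evaluated at pixel centers on its truncation window and divided by the
    window sum, so a point whose window lies inside the image contributes
    total mass exactly 1. Windows sticking out of the frame are clipped
    without renormalization.
    """
    cfg = cfg or GenerationConfig()
    h, w = ann.image_size
    density = np.zeros((h, w), dtype=np.float64)
    sigmas = _point_sigmas(ann, cfg)
    for (x, y), sig in zip(ann.points, sigmas):
        r = int(np.ceil(cfg.truncation_radius * sig))
        cx, cy = int(np.floor(x)), int(np.floor(y))
        cols = np.arange(cx - r, cx + r + 1)
        rows = np.arange(cy - r, cy + r + 1)
        kern = np.exp(
            -((cols[None, :] - x) ** 2 + (rows[:, None] - y) ** 2) / (2.0 * sig**2)
        )
        kern /= kern.sum()  # unit mass on the full (uncut) window
        r0, r1 = max(rows[0], 0), min(rows[-1] + 1, h)
        c0, c1 = max(cols[0], 0), min(cols[-1] + 1, w)
        density[r0:r1, c0:c1] += kern[r0 - rows[0] : r1 - rows[0], c0 - cols[0] : c1 - cols[0]]
    return DensityMap(density, resolution_divisor=1)


def downsample_density(d: DensityMap, factor: int) -> DensityMap:
    """Sum-aggregate non-overlapping factor x factor blocks; mass is preserved.

    Shapes not divisible by ``factor`` are zero-padded bottom/right first
    (padding adds no mass), matching the network's padding convention.
    """
    if factor < 1:
        raise ConfigError(f"downsample factor must be >= 1, got {factor}")
    v = d.values
    h, w = v.shape
    ph, pw = -h % factor, -w % factor
    if ph or pw:
        v = np.pad(v, ((0, ph), (0, pw)))
    h, w = v.shape
    pooled = v.reshape(h // factor, factor, w // factor, factor).sum(axis=(1, 3))
    return DensityMap(pooled, resolution_divisor=d.resolution_divisor * factor)


def make_segmentation_target(dt: DensityMap, epsilon: float = 1e-3) -> SegmentationMap:
    """Threshold a density map into the binary segmentation target.

    A cell is foreground iff its density strictly exceeds ``epsilon``; a cell
    exactly at the threshold is background.
    """
    return SegmentationMap((dt.values > epsilon).astype(np.float64), mode="binary")


def tile_scene(
    image: np.ndarray,
    ann: PointAnnotationSet,
    tile_size: int,
    cfg: GenerationConfig | None = None,
) -> list[tuple[np.ndarray, PointAnnotationSet, DensityMap]]:
    """Cut a scene into tiles with fractional-mass density semantics.

    The density map is generated once for the full scene and then cropped, so
    an object near a tile boundary contributes fractional mass to every tile
    its kernel overlaps — summed over tiles, the scene's total mass (and hence
    its count) is exact. Each annotation point is assigned to the single tile
    containing its center. The last row/column of tiles is zero-padded.
    """
    if tile_size < 16:
        raise ConfigError("tile_size must be >= 16")
    h, w = ann.image_size
    if image.shape[:2] != (h, w):
        raise ContractError(f"image shape {image.shape[:2]} != annotated size {(h, w)}")
    if tile_size > h or tile_size > w:
        warnings.warn("tile_size exceeds scene size; returning a single padded tile")
    density = generate_density_map(ann, cfg).values
    n_rows = max(1, -(-h // tile_size))
    n_cols = max(1, -(-w // tile_size))
    pad_h, pad_w = n_rows * tile_size - h, n_cols * tile_size - w
    pad_img = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (image.ndim - 2)
    image_p = np.pad(image, pad_img)
    density_p = np.pad(density, ((0, pad_h), (0, pad_w)))

    tiles = []
    for i in range(n_rows):
        for j in range(n_cols):
            r0, c0 = i * tile_size, j * tile_size
            pts = [
                (x - c0, y - r0)
                for x, y in ann.points
                if c0 <= x < c0 + tile_size and r0 <= y < r0 + tile_size
            ]
            tile_ann = PointAnnotationSet(
                image_id=f"{ann.image_id}_r{i}c{j}",
                points=pts,
                image_size=(tile_size, tile_size),
            )
            tiles.append(
                (
                    image_p[r0 : r0 + tile_size, c0 : c0 + tile_size],
                    tile_ann,
                    DensityMap(density_p[r0 : r0 + tile_size, c0 : c0 + tile_size]),
                )
            )
    return tiles
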