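"""Occlusion sensitivity maps for paired-image distances.

The same N x N patch is occluded at the same coordinates in *both* images of
a pair (each patch replaced by that image's own patch mean), the pair is
re-embedded, and the cell stores baseline_distance − occluded_distance.
With this sign convention a cell is positive where occlusion removes the
signal that made the images dissimilar, i.e. salient regions are hot.

For single-image severity, one map is computed against each anchor in the
pool and the cellwise median is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import matplotlib

matplotlib.use("Agg")
from PIL import Image  # noqa: E402

__all__ = [
    "OcclusionConfig",
    "OcclusionMap",
    "grid_shape",
    "occlude",
    "occlusion_map_pair",
    "occlusion_map_single",
    "render_heatmap",
]


@dataclass(frozen=True)
class OcclusionConfig:
    """Patch geometry: N x N patches on a stride grid anchored at (0, 0)."""

    patch_size: int = 8
    stride: int = 8

    def __post_init__(self):
        if self.patch_size < 1 or self.stride < 1:
            raise ValueError("patch_size and stride must be >= 1")


@dataclass(frozen=True)
class OcclusionMap:
    """Signed distance perturbations; cell (i, j) corresponds to the patch
    whose top-left corner is (i*stride, j*stride)."""

    grid: np.ndarray
    baseline_distance: float
    config: OcclusionConfig


def grid_shape(image_shape: tuple[int, int], config: OcclusionConfig) -> tuple[int, int]:
    """floor((H-N)/stride)+1 by floor((W-N)/stride)+1."""
    h, w = image_shape
    n, s = config.patch_size, config.stride
    if n > h or n > w:
        raise ValueError(f"patch size {n} exceeds image size {image_shape}")
    return ((h - n) // s + 1, (w - n) // s + 1)


def occlude(image: np.ndarray, top: int, left: int, n: int) -> np.ndarray:
    """Copy of ``image`` with the N x N patch at (top, left) set to the
    patch's own mean.  Pixels outside the patch are untouched."""
    h, w = image.shape
    if top < 0 or left < 0 or top + n > h or left + n > w:
        raise ValueError(f"patch ({top},{left},{n}) out of bounds for {image.shape}")
    out = image.copy()
    out[top : top + n, left : left + n] = image[top : top + n, left : left + n].mean()
    return out


def occlusion_map_pair(image1: np.ndarray, image2: np.ndarray, model,
                       config: OcclusionConfig | None = None) -> OcclusionMap:
    """Synchronized-occlusion map for a pair of equally sized images."""
    config = config or OcclusionConfig()
    if image1.shape != image2.shape:
        raise ValueError("paired images must have equal size")
    rows, cols = grid_shape(image1.shape, config)
    n, s = config.patch_size, config.stride

    emb = model.embed_batch(np.stack([image1, image2]))
    baseline = float(np.linalg.norm(emb[0].astype(np.float64) - emb[1].astype(np.float64)))

    # batch all occluded variants through the model
    occ1 = np.empty((rows * cols,) + image1.shape, dtype=np.float64)
    occ2 = np.empty_like(occ1)
    k = 0
    for i in range(rows):
        for j in range(cols):
            occ1[k] = occlude(image1, i * s, j * s, n)
            occ2[k] = occlude(image2, i * s, j * s, n)
            k += 1
    grid = np.empty(rows * cols)
    bs = 128
    for start in range(0, rows * cols, bs):
        stop = min(start + bs, rows * cols)
        e1 = model.embed_batch(occ1[start:stop]).astype(np.float64)
        e2 = model.embed_batch(occ2[start:stop]).astype(np.float64)
        d_occ = np.sqrt(((e1 - e2) ** 2).sum(axis=1))
        grid[start:stop] = baseline - d_occ
    return OcclusionMap(grid.reshape(rows, cols), baseline, config)


def occlusion_map_single(image: np.ndarray, pool, model, store,
                         config: OcclusionConfig | None = None) -> OcclusionMap:
    """Cellwise median of the pair maps against every anchor in the pool."""
    config = config or OcclusionConfig()
    if len(pool) == 0:
        raise ValueError("anchor pool is empty")
    maps = []
    baselines = []
    for path in pool.records["image_path"]:
        m = occlusion_map_pair(image, store.get(path), model, config)
        maps.append(m.grid)
        baselines.append(m.baseline_distance)
    return OcclusionMap(np.median(np.stack(maps), axis=0),
                        float(np.median(baselines)), config)


def render_heatmap(occ_map: OcclusionMap, base_image: np.ndarray, out_path,
                   alpha: float = 0.5, absolute: bool = False,
                   cmap: str = "jet") -> np.ndarray:
    """Upsample the map to image size, alpha-blend over the base image and
    write a PNG.  ``absolute=True`` renders |values| instead of signed ones.
    Returns the blended RGB array (uint8)."""
    grid = np.abs(occ_map.grid) if absolute else occ_map.grid
    lo, hi = float(grid.min()), float(grid.max())
    norm = np.zeros_like(grid) if hi - lo < 1e-12 else (grid - lo) / (hi - lo)

    h, w = base_image.shape
    gy = np.clip((np.arange(h) * grid.shape[0]) // h, 0, grid.shape[0] - 1)
    gx = np.clip((np.arange(w) * grid.shape[1]) // w, 0, grid.shape[1] - 1)
    up = norm[np.ix_(gy, gx)]

    colors = matplotlib.colormaps[cmap](up)[..., :3]
    base_rgb = np.repeat(np.clip(base_image, 0, 1)[..., None], 3, axis=2)
    blend_alpha = alpha * up[..., None]  # zero map value -> base image shows through
    blended = (1 - blend_alpha) * base_rgb + blend_alpha * colors
    out = np.round(blended * 255).astype(np.uint8)
    Image.fromarray(out, mode="RGB").save(out_path)
    return out
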