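"""Whole-volume inference: tile each b-scan, translate, stitch back.

Inference reuses the deterministic tiling of the preprocessing stage
(edge tiles shifted inward), applies the trained generator per tile and
reassembles with overlap blending.  The default inference stride is half
the patch size with average blending, which suppresses seam artifacts at
tile borders; no thresholding or filtering is applied after generation —
any denoising the networks learned is kept as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_volumes import Modality, PamVolume, ValueScale
from .preprocess import PatchSet, extract_patches
from .training import TrainedModel


class StitchError(ValueError):
    pass


@dataclass(frozen=True)
class StitchPlan:
    """Geometry for reassembling tiles into a 2D image."""

    origins: tuple[tuple[int, int], ...]
    patch_size: int
    target_shape: tuple[int, int]  # (n_x, n_z)
    blend: str = "average"         # {"average", "feathered"}

    def __post_init__(self) -> None:
        if self.blend not in ("average", "feathered"):
            raise StitchError(f"unknown blend mode {self.blend!r}")
        n_x, n_z = self.target_shape
        for x0, z0 in self.origins:
            if x0 < 0 or z0 < 0 or x0 + self.patch_size > n_x or z0 + self.patch_size > n_z:
                raise StitchError(
                    f"tile at {(x0, z0)} size {self.patch_size} exceeds target {self.target_shape}"
                )

    @classmethod
    def from_patchset(cls, patches: PatchSet, blend: str = "average") -> "StitchPlan":
        return cls(
            origins=tuple(patches.origins()),
            patch_size=patches.patch_size,
            target_shape=patches.source_shape,
            blend=blend,
        )


def _weight_window(size: int, blend: str) -> np.ndarray:
    if blend == "average":
        return np.ones((size, size))
    # feathered: separable triangular taper, strictly positive
    ramp = 1.0 - np.abs(np.linspace(-1.0, 1.0, size)) * (1.0 - 1.0 / size)
    return np.outer(ramp, ramp)


def stitch_patches(tiles: list[np.ndarray] | PatchSet, plan: StitchPlan) -> np.ndarray:
    """Weighted overlap blend of tiles back into the source geometry.

    Under ``average`` blending every pixel is the arithmetic mean of the
    tiles covering it, so unmodified tiles reassemble the source exactly.
    """
    arrays = [p.pixels for p in tiles.patches] if isinstance(tiles, PatchSet) else tiles
    if len(arrays) != len(plan.origins):
        raise StitchError(f"{len(arrays)} tiles but plan has {len(plan.origins)} origins")
    acc = np.zeros(plan.target_shape, dtype=np.float64)
    weight = np.zeros(plan.target_shape, dtype=np.float64)
    win = _weight_window(plan.patch_size, plan.blend)
    s = plan.patch_size
    for tile, (x0, z0) in zip(arrays, plan.origins):
        if tile.shape != (s, s):
            raise StitchError(f"tile shape {tile.shape} != ({s}, {s})")
        acc[x0 : x0 + s, z0 : z0 + s] += tile * win
        weight[x0 : x0 + s, z0 : z0 + s] += win
    if np.any(weight == 0):
        raise StitchError("plan does not cover the full target (zero-weight pixels)")
    return acc / weight


def enhance_bscan(
    bscan: np.ndarray,
    model: TrainedModel,
    patch_size: int = 256,
    stride: int | None = None,
    blend: str = "average",
    batch_size: int = 8,
) -> np.ndarray:
    """Translate one b-scan through the trained generator.

    Tiles are extracted per the preprocessing rules (default inference
    stride = patch_size / 2), mapped by G in batches, and stitched with
    overlap blending.  Output has the input shape, values in [0, 1].
    """
    bscan = np.asarray(bscan, dtype=np.float64)
    stride = stride or max(1, patch_size // 2)
    pset = extract_patches(bscan, patch_size, stride)
    plan = StitchPlan.from_patchset(pset, blend=blend)
    gen = model.generator
    tiles_in = np.stack([p.pixels for p in pset.patches])[:, None]
    tiles_out = []
    for start in range(0, len(tiles_in), batch_size):
        out = gen(tiles_in[start : start + batch_size])
        tiles_out.extend(out[:, 0])
    stitched = stitch_patches(list(tiles_out), plan)
    out = stitched[: bscan.shape[0], : bscan.shape[1]]  # drop padding if source < patch
    if not np.all(np.isfinite(out)):
        raise StitchError("non-finite values in enhanced b-scan")
    return np.clip(out, 0.0, 1.0)


def enhance_volume(
    vol: PamVolume,
    model: TrainedModel,
    patch_size: int = 256,
    stride: int | None = None,
    blend: str = "average",
) -> PamVolume:
    """Slice-wise enhancement along the slow-scan axis (no cross-slice state)."""
    data = vol.data.astype(np.float64)
    if vol.value_scale is ValueScale.UINT8:
        data = data / 255.0
    enhanced = np.stack([
        enhance_bscan(data[y], model, patch_size, stride, blend)
        for y in range(vol.n_y)
    ])
    return vol.with_data(enhanced, modality=Modality.GENERATED,
                         value_scale=ValueScale.FLOAT_UNIT)
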