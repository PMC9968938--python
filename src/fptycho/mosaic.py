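"""Patchwise tiling of camera frames and stitching of reconstructions.

A full camera frame (1460x1940 with the default instrument) is processed
as 100x100 patches — 266 of them with no overlap — each reconstructed to
q x size; stitching places the reconstructed patches on the q-scaled grid
and feathers overlapping bands linearly, so a 40-pixel LR overlap becomes
the 200-pixel HR overlap used to suppress the raster-grid artifact.  A
motorised-stage scan covering a larger slide area is planned the same way
at the field-of-view level (e.g. 17.1 x 9.8 mm -> 63 FoVs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import InstrumentConfig

__all__ = ["TilePlan", "MosaicPlan", "plan_tiles", "extract_tiles",
           "stitch_patches", "plan_fov_scan"]


@dataclass
class TilePlan:
    """Row-major grid of patch offsets covering one camera frame."""
    frame_shape: tuple[int, int]
    patch_size: int
    overlap_lr: int
    offsets: list[tuple[int, int]]

    @property
    def n_tiles(self) -> int:
        return len(self.offsets)


@dataclass
class MosaicPlan:
    """FoV grid needed to scan a target slide area with the stage."""
    target_mm: tuple[float, float]         # (width, height)
    fov_extent_mm: tuple[float, float]     # (rows_mm, cols_mm) of one FoV
    grid_rows: int
    grid_cols: int

    @property
    def n_fovs(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def target_area_mm2(self) -> float:
        return self.target_mm[0] * self.target_mm[1]


def _axis_offsets(length: int, patch: int, overlap: int) -> list[int]:
    if overlap == 0:
        return [i * patch for i in range(length // patch)]
    stride = patch - overlap
    offsets = list(range(0, length - patch + 1, stride))
    if offsets[-1] + patch < length:
        offsets.append(length - patch)   # clamp last tile to the edge
    return offsets


def plan_tiles(frame_shape: tuple[int, int], patch_size: int = 100,
               overlap_lr: int = 0) -> TilePlan:
    """Plan the patch grid for one frame.

    With ``overlap_lr=0`` the frame is cut into ``floor(R/p) * floor(C/p)``
    full patches (edge remainders dropped); with overlap the stride is
    ``p - overlap`` and the last tile per axis is clamped to the frame edge.
    """
    rows, cols = frame_shape
    if patch_size > rows or patch_size > cols:
        raise ValueError("patch_size exceeds the frame")
    if not 0 <= overlap_lr < patch_size:
        raise ValueError("overlap must satisfy 0 <= overlap < patch_size")
    r_off = _axis_offsets(rows, patch_size, overlap_lr)
    c_off = _axis_offsets(cols, patch_size, overlap_lr)
    offsets = [(r, c) for r in r_off for c in c_off]
    return TilePlan(frame_shape=(rows, cols), patch_size=patch_size,
                    overlap_lr=overlap_lr, offsets=offsets)


def extract_tiles(frame: np.ndarray, plan: TilePlan) -> list[np.ndarray]:
    """Cut a frame (or frame stack, leading axis kept) into planned patches."""
    p = plan.patch_size
    return [frame[..., r:r + p, c:c + p] for r, c in plan.offsets]


def _feather_weight(n: int, ramp: int) -> np.ndarray:
    """1D weight: linear ramps of length ``ramp`` at both ends, 1 inside."""
    if ramp <= 0:
        return np.ones(n)
    i = np.arange(n, dtype=float)
    return np.minimum(1.0, np.minimum((i + 1) / ramp, (n - i) / ramp))


def stitch_patches(patches: list[np.ndarray], plan: TilePlan, q: int,
                   align_phase: bool = False) -> np.ndarray:
    """Blend reconstructed patches into one HR mosaic.

    Patches are placed at ``q``-scaled offsets.  Overlapping bands (width
    ``q * overlap_lr``) are blended with separable linear feathering
    weights normalised to a partition of unity, so constant inputs
    reconstruct exactly and seams are suppressed.  With ``align_phase``
    (complex patches) each patch is first rotated by a constant phase
    matching it to the mosaic built so far on the overlap region —
    phase retrieval leaves each patch with its own global phase.
    """
    if len(patches) != plan.n_tiles:
        raise ValueError(f"expected {plan.n_tiles} patches, got {len(patches)}")
    p_hr = q * plan.patch_size
    for k, pa in enumerate(patches):
        if pa.shape != (p_hr, p_hr):
            raise ValueError(
                f"patch {k} has shape {pa.shape}, expected {(p_hr, p_hr)}")
    rows = max(r for r, _ in plan.offsets) * q + p_hr
    cols = max(c for _, c in plan.offsets) * q + p_hr
    ramp = q * plan.overlap_lr
    w1d = _feather_weight(p_hr, ramp)
    w2d = w1d[:, None] * w1d[None, :]
    dtype = complex if any(np.iscomplexobj(p) for p in patches) else float
    num = np.zeros((rows, cols), dtype=dtype)
    den = np.zeros((rows, cols))
    for (r, c), patch in zip(plan.offsets, patches):
        r0, c0 = r * q, c * q
        patch = patch.astype(dtype)
        if align_phase and dtype is complex:
            cur_den = den[r0:r0 + p_hr, c0:c0 + p_hr]
            ov = cur_den > 1e-9
            if ov.any():
                cur = num[r0:r0 + p_hr, c0:c0 + p_hr][ov] / cur_den[ov]
                inner = np.vdot(patch[ov], cur)
                if np.abs(inner) > 0:
                    patch = patch * (inner / np.abs(inner))
        num[r0:r0 + p_hr, c0:c0 + p_hr] += w2d * patch
        den[r0:r0 + p_hr, c0:c0 + p_hr] += w2d
    if (den <= 0).any():
        raise ValueError("tile plan leaves uncovered mosaic pixels")
    return num / den


def plan_fov_scan(target_mm: tuple[float, float],
                  cfg: InstrumentConfig) -> MosaicPlan:
    """FoV grid needed to cover ``target_mm = (width, height)``.

    The object-space FoV of one frame is the camera frame size times
    ``camera_pixel / magnification``; the scan needs the ceiling of
    target/extent FoVs per axis (width along the camera's long axis).
    """
    w, h = target_mm
    if w <= 0 or h <= 0:
        raise ValueError("target extent must be positive")
    fov_rows_mm, fov_cols_mm = cfg.fov_extent_mm
    return MosaicPlan(
        target_mm=(w, h),
        fov_extent_mm=(fov_rows_mm, fov_cols_mm),
        grid_rows=math.ceil(h / fov_rows_mm),
        grid_cols=math.ceil(w / fov_cols_mm),
    )
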