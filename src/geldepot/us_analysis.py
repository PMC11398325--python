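"""B-mode texture metrics and freehand 3D reconstruction of tracked frames.

Texture of the hyperechoic gel region is summarized by three ROI
statistics: acoustic intensity (mean pixel value), acoustic heterogeneity
(pixel standard deviation — population SD, since the ROI is the whole
region of interest, not a sample) and Shannon entropy of the 256-bin
grayscale histogram in bits, so an 8-bit image is bounded by 8 bits and a
constant region scores 0.

Freehand reconstruction bins every tracked pixel into a world-aligned
voxel grid: each pixel center is mapped through its frame's rigid pose,
contributions landing in the same voxel are averaged (arithmetic-mean
compounding; configurable elsewhere was considered and rejected — the mean
is order-invariant and unbiased under additive speckle), and empty voxels
are filled from their nearest filled neighbour within a radius (default
2x the inter-frame step) or left at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .io_formats import PlanarImage, TrackedFrame, VoxelVolume

__all__ = [
    "TextureMetrics",
    "ReconGrid",
    "shannon_entropy",
    "texture_metrics",
    "texture_time_series",
    "reconstruct_3d",
    "auto_grid",
    "roi_from_polygon",
]


def roi_from_polygon(shape: tuple[int, int], vertices_rc: np.ndarray) -> np.ndarray:
    """Rasterize a polygon ROI (pixel-index vertices, (row, col) order).

    ROIs are stored geometry (JSON vertex lists) rather than interactive
    drawings, so every analysis is replayable.
    """
    from skimage.draw import polygon

    vertices_rc = np.asarray(vertices_rc, dtype=float)
    if vertices_rc.ndim != 2 or vertices_rc.shape[1] != 2 or len(vertices_rc) < 3:
        raise ValidationError("polygon ROI needs >= 3 (row, col) vertices")
    rr, cc = polygon(vertices_rc[:, 0], vertices_rc[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


@dataclass
class TextureMetrics:
    acoustic_intensity: float  # mean pixel value, a.u.
    heterogeneity: float  # population SD in ROI, a.u.
    entropy_bits: float
    area_cm2: float  # ROI area


def shannon_entropy(values: np.ndarray, n_bins: int = 256,
                    hist_range: tuple[float, float] | None = None) -> float:
    """Histogram Shannon entropy in bits: -sum p_i log2 p_i, zero-count
    bins skipped.

    Integer-typed data defaults to the fixed 8-bit range [0, 256) so the
    score is comparable across frames; float data defaults to its own
    min/max range.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValidationError("entropy of an empty set")
    if hist_range is None:
        if np.issubdtype(values.dtype, np.integer):
            hist_range = (0.0, float(n_bins))
        else:
            lo, hi = float(values.min()), float(values.max())
            if lo == hi:
                return 0.0
            hist_range = (lo, hi)
    counts, _ = np.histogram(values, bins=n_bins, range=hist_range)
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def texture_metrics(
    image: PlanarImage | np.ndarray,
    roi: np.ndarray,
    pixel_spacing: tuple[float, float] | None = None,
    n_bins: int = 256,
    hist_range: tuple[float, float] | None = None,
) -> TextureMetrics:
    """ROI texture summary of one frame."""
    if isinstance(image, PlanarImage):
        data, spacing = image.data, image.pixel_spacing
    else:
        data = np.asarray(image)
        spacing = pixel_spacing or (1.0, 1.0)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != data.shape:
        raise ValidationError("ROI shape differs from image shape")
    if not roi.any():
        raise ValidationError("empty ROI")
    vals = data[roi]
    return TextureMetrics(
        acoustic_intensity=float(vals.mean()),
        heterogeneity=float(vals.std()),  # population SD (ddof=0)
        entropy_bits=shannon_entropy(vals, n_bins=n_bins, hist_range=hist_range),
        area_cm2=float(roi.sum()) * spacing[0] * spacing[1] / 100.0,
    )


def texture_time_series(
    images: list[PlanarImage | np.ndarray],
    rois: list[np.ndarray],
    times_min: np.ndarray | list[float],
    **kwargs,
) -> pd.DataFrame:
    """Tidy per-timepoint texture table (one ROI per timepoint)."""
    if not (len(images) == len(rois) == len(times_min)):
        raise ValidationError("images, rois and times must have equal length")
    rows = []
    for t, img, roi in zip(times_min, images, rois):
        m = texture_metrics(img, roi, **kwargs)
        rows.append(
            {
                "time_min": float(t),
                "acoustic_intensity_au": m.acoustic_intensity,
                "heterogeneity_au": m.heterogeneity,
                "entropy_bits": m.entropy_bits,
                "area_cm2": m.area_cm2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# freehand 3D reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconGrid:
    """Target voxel grid of a freehand reconstruction.

    ``bounds`` are world-mm ((xmin, xmax), (ymin, ymax), (zmin, zmax)) and
    must enclose all frame footprints. ``fill`` is 'nearest' (fill empty
    voxels from the nearest filled voxel within ``fill_radius_mm``) or
    'none' (leave them at zero).
    """

    spacing: tuple[float, float, float]  # mm
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    fill: str = "nearest"
    fill_radius_mm: float | None = None  # default: 2x median inter-frame step

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("grid spacing must be positive")
        if any(hi <= lo for lo, hi in self.bounds):
            raise ValidationError("grid bounds must be non-empty intervals")
        if self.fill not in ("nearest", "none"):
            raise ValidationError(f"unknown fill policy {self.fill!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(np.floor((hi - lo) / s)) + 1
            for (lo, hi), s in zip(self.bounds, self.spacing)
        )

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(lo for lo, _ in self.bounds)


def auto_grid(frames: list[TrackedFrame], spacing: tuple[float, float, float],
              fill: str = "nearest") -> ReconGrid:
    """Tight axis-aligned grid around all frame pixel footprints."""
    mins = np.full(3, np.inf)
    maxs = np.full(3, -np.inf)
    for f in frames:
        w = f.pixel_world_coords().reshape(-1, 3)
        mins = np.minimum(mins, w.min(axis=0))
        maxs = np.maximum(maxs, w.max(axis=0))
    bounds = tuple((float(lo), float(hi)) for lo, hi in zip(mins, maxs))
    return ReconGrid(spacing=spacing, bounds=bounds, fill=fill)


def _median_step(frames: list[TrackedFrame]) -> float:
    centers = np.array([f.translation for f in frames])
    if len(centers) < 2:
        return 1.0
    return float(np.median(np.linalg.norm(np.diff(centers, axis=0), axis=1)))


def reconstruct_3d(frames: list[TrackedFrame], grid: ReconGrid) -> VoxelVolume:
    """Bin tracked frames into a voxel grid (mean compounding).

    Each pixel center maps through its pose to world mm, then to the
    nearest grid voxel; the voxel value is the mean of all contributing
    pixels. Empty voxels are filled per the grid's policy. Raises when no
    pixel lands inside the grid.
    """
    if len(frames) < 2:
        raise ValidationError("reconstruction needs at least 2 frames")
    shape = grid.shape
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    acc = np.zeros(shape)
    cnt = np.zeros(shape, dtype=np.int64)
    for f in frames:
        w = f.pixel_world_coords().reshape(-1, 3)
        idx = np.rint((w - origin) / spacing).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        idx = idx[ok]
        vals = np.asarray(f.image.data, dtype=float).reshape(-1)[ok]
        np.add.at(acc, tuple(idx.T), vals)
        np.add.at(cnt, tuple(idx.T), 1)
    filled = cnt > 0
    if not filled.any():
        raise ValidationError("no frame pixel falls inside the reconstruction grid")
    data = np.zeros(shape)
    data[filled] = acc[filled] / cnt[filled]
    if grid.fill == "nearest" and not filled.all():
        radius = grid.fill_radius_mm
        if radius is None:
            radius = 2.0 * _median_step(frames)
        dist, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~filled, sampling=spacing, return_indices=True
        )
        nearest = data[ix, iy, iz]
        fillable = (~filled) & (dist <= radius)
        data[fillable] = nearest[fillable]
    return VoxelVolume(data=data, spacing=grid.spacing, origin=grid.origin, modality="US3D")
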