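"""Threshold segmentation of the gel depot and HU-to-iodine mapping.

The depot is radiopaque because the gel carries iodinated contrast; a
voxel's Hounsfield value is assumed linear in its iodine concentration
between two calibration points (``hu_baseline`` -> 0 mg/mL,
``hu_max`` -> ``c_max``, default 40 mg/mL). Mapped concentrations are
classified into the reporting bands

    0: < 7,  1: 7-13.4,  2: 13.4-27,  3: 27-40  (mg/mL)

with half-open edges [low, high) and the top band closed at ``c_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptySegmentationError, ValidationError
from .io_formats import PlanarImage, VoxelVolume

__all__ = [
    "BAND_EDGES_MG_ML",
    "SegmentationMask",
    "IodineCalibration",
    "IodineMap",
    "segment_depot",
    "iodine_from_hu",
    "band_areas",
    "volume_percent_series",
]

# Band edges of the three reported relative-iodine concentration ranges.
BAND_EDGES_MG_ML = (7.0, 13.4, 27.0)


@dataclass
class SegmentationMask:
    """Binary depot mask plus per-component labels.

    ``labels`` uses 26-connectivity in 3D (8-connectivity in 2D), with
    components below the minimum size already removed, so leakage
    components can be analyzed separately from the main depot.
    """

    mask: np.ndarray  # boolean, same shape as the source volume
    spacing: tuple[float, ...]  # mm, per axis of mask
    labels: np.ndarray | None = None  # int component labels, 0 = background
    n_components: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("mask spacing must be positive")
        if self.labels is not None and self.labels.shape != self.mask.shape:
            raise ValidationError("labels shape differs from mask shape")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        """Mask volume in mL (voxel count x voxel volume / 1000)."""
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def component_sizes(self) -> dict[int, int]:
        if self.labels is None:
            return {}
        vals, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def segment_depot(
    volume: VoxelVolume,
    hu_threshold: float,
    min_component_voxels: int = 1,
) -> SegmentationMask:
    """Threshold segmentation: voxels >= threshold, small components removed.

    Connectivity is 26-neighborhood. Raises EmptySegmentationError when
    nothing survives — deliberately distinct from an I/O failure.
    """
    data = np.asarray(volume.data)
    raw = data >= hu_threshold
    structure = np.ones((3,) * data.ndim, dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(raw, structure=structure)
    if n == 0:
        raise EmptySegmentationError(
            f"no voxels at or above threshold {hu_threshold} "
            f"(data range [{data.min():.1f}, {data.max():.1f}])"
        )
    if min_component_voxels > 1:
        counts = np.bincount(labels.ravel())
        keep = np.nonzero(counts >= min_component_voxels)[0]
        keep = keep[keep > 0]
        if keep.size == 0:
            raise EmptySegmentationError(
                f"all components below {min_component_voxels} voxels"
            )
        lut = np.zeros(n + 1, dtype=labels.dtype)
        lut[keep] = np.arange(1, keep.size + 1)
        labels = lut[labels]
        n = keep.size
    mask = labels > 0
    return SegmentationMask(mask=mask, spacing=volume.spacing, labels=labels, n_components=int(n))


@dataclass
class IodineCalibration:
    """Two-point linear HU -> iodine calibration."""

    hu_baseline: float  # HU mapping to 0 mg/mL
    hu_max: float  # HU mapping to c_max
    c_max: float = 40.0  # mg/mL

    def __post_init__(self) -> None:
        if self.hu_max <= self.hu_baseline:
            raise ValidationError("hu_max must exceed hu_baseline")
        if self.c_max <= 0:
            raise ValidationError("c_max must be positive")

    @classmethod
    def from_volume(
        cls,
        volume: VoxelVolume,
        depot_mask: np.ndarray,
        background_mask: np.ndarray | None = None,
        c_max: float = 40.0,
        percentile: float = 99.5,
    ) -> "IodineCalibration":
        """Per-acquisition calibration: baseline = robust median HU of a
        background region (the mask complement when none is supplied);
        hu_max = the ``percentile``-th HU inside the segmented depot, which
        resists single-voxel outliers."""
        data = np.asarray(volume.data)
        if background_mask is None:
            background_mask = ~np.asarray(depot_mask, dtype=bool)
        baseline = float(np.median(data[background_mask]))
        hu_max = float(np.percentile(data[np.asarray(depot_mask, dtype=bool)], percentile))
        return cls(hu_baseline=baseline, hu_max=hu_max, c_max=c_max)


@dataclass
class IodineMap:
    """Per-voxel (or per-pixel) iodine concentrations and band labels."""

    conc: np.ndarray  # mg/mL, clipped to [0, c_max]
    bands: np.ndarray  # int labels 0..3
    spacing: tuple[float, ...]  # mm per axis
    c_max: float = 40.0

    @property
    def ndim(self) -> int:
        return self.conc.ndim


def _band_labels(conc: np.ndarray) -> np.ndarray:
    # np.digitize with right=False implements [low, high) edges; clipping
    # to c_max closes the top band.
    return np.digitize(conc, BAND_EDGES_MG_ML, right=False)


def iodine_from_hu(
    source: VoxelVolume | PlanarImage | np.ndarray,
    cal: IodineCalibration,
    spacing: tuple[float, ...] | None = None,
) -> IodineMap:
    """Map HU linearly to mg/mL and classify into concentration bands.

    conc = c_max * (HU - hu_baseline) / (hu_max - hu_baseline), clipped to
    [0, c_max]; exactly linear between the calibration points and monotone
    non-decreasing everywhere.
    """
    if isinstance(source, VoxelVolume):
        data, spacing = source.data, source.spacing
    elif isinstance(source, PlanarImage):
        data, spacing = source.data, source.pixel_spacing
    else:
        data = np.asarray(source)
        if spacing is None:
            spacing = (1.0,) * data.ndim
    conc = cal.c_max * (np.asarray(data, dtype=float) - cal.hu_baseline) / (
        cal.hu_max - cal.hu_baseline
    )
    conc = np.clip(conc, 0.0, cal.c_max)
    return IodineMap(conc=conc, bands=_band_labels(conc), spacing=tuple(spacing), c_max=cal.c_max)


def band_areas(map2d: IodineMap, pixel_spacing: tuple[float, float] | None = None) -> pd.Series:
    """Cross-sectional area per concentration band on a 2D map, in cm^2.

    area(band) = pixel count in band x pixel area. Returns a Series indexed
    by band label 0..3 (band 0 = below the lowest reported range).
    """
    if map2d.ndim != 2:
        raise ValidationError("band_areas needs a 2D map")
    spacing = pixel_spacing or map2d.spacing
    px_cm2 = float(spacing[0] * spacing[1]) / 100.0  # mm^2 -> cm^2
    counts = np.bincount(map2d.bands.ravel(), minlength=len(BAND_EDGES_MG_ML) + 1)
    return pd.Series(counts * px_cm2, index=range(len(counts)), name="area_cm2")


def volume_percent_series(masks: list[SegmentationMask]) -> np.ndarray:
    """Depot volume per timepoint as a percentage of the first timepoint:
    percent(t) = 100 * V(t) / V(0)."""
    if len(masks) == 0:
        raise ValidationError("need at least one timepoint")
    v0 = masks[0].volume_ml
    if v0 == 0:
        raise ValidationError("reference (t=0) mask is empty")
    return np.array([100.0 * m.volume_ml / v0 for m in masks])
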