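"""3D and 2D shape morphometrics of segmented gel depots.

Sphericity and solidity quantify how compact and convex the deposited gel
is: a perfectly localized depot approaches a sphere (sphericity 1) with no
concavities or vessel-filling tendrils (solidity 1), while leakage drives
both down.

    sphericity = pi^(1/3) (6 V)^(2/3) / SA          (dimensionless, <= 1)
    solidity   = V / V(convex hull)                  (dimensionless, <= 1)

Volume comes from the voxel count, surface area from a triangulated
isosurface of the mask (voxel-face counting would overestimate SA by up to
~50% and wreck sphericity), and the convex hull from exact Qhull polytope
computation over mesh vertices (3D) or pixel-corner points (2D). Reported
units are mL for V and cm^2 for SA; sphericity/solidity are computed in a
single consistent unit system so they are scale-free.

Numerical choices: marching cubes runs on a Gaussian-smoothed copy of the
binary mask (sigma 0.8 voxels) because the raw binary isosurface
overestimates a digital sphere's area by ~9% while the anti-aliased one is
within ~1.5%; when the structure is too small to survive smoothing (max
smoothed value below the iso level) the raw mask is used instead. The 2D
perimeter is the marching-squares contour polygon length after a 5-point
moving-average smoothing of the contour, which removes pixel staircase
inflation (+6% on digital disks) at the cost of an O(1 px) corner-rounding
deficit on polygonal shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .errors import EmptyMeshError, ValidationError
from .io_formats import SurfaceMesh, VoxelVolume
from .segmentation import SegmentationMask

__all__ = [
    "Morphometrics3D",
    "Morphometrics2D",
    "SerialDeposition",
    "mesh_from_mask",
    "mesh_morphometrics",
    "morphometrics_3d",
    "morphometrics_2d",
    "serial_per_ml_analysis",
    "sphericity_from_vsa",
    "contour_perimeter",
]

MC_SMOOTHING_SIGMA = 0.8  # voxels
PERIMETER_SMOOTH_WINDOW = 5  # contour points


@dataclass
class Morphometrics3D:
    volume_ml: float
    surface_area_cm2: float
    sphericity: float
    solidity: float
    sa_to_v_cm: float  # cm^-1 (cm^2 per cm^3)
    mean_hu: float | None = None


@dataclass
class Morphometrics2D:
    area_cm2: float
    major_axis_cm: float
    minor_axis_cm: float
    circularity: float
    solidity: float
    perimeter_cm: float


def sphericity_from_vsa(volume: float, surface_area: float) -> float:
    """pi^(1/3) (6 V)^(2/3) / SA in any single consistent unit system."""
    if volume <= 0 or surface_area <= 0:
        raise ValidationError("sphericity needs positive V and SA")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def _mask_and_spacing(mask, spacing=None):
    if isinstance(mask, SegmentationMask):
        return mask.mask, mask.spacing
    arr = np.asarray(mask, dtype=bool)
    return arr, tuple(spacing) if spacing is not None else (1.0,) * arr.ndim


def mesh_from_mask(
    mask: SegmentationMask | np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    level: float = 0.5,
    smoothing_sigma: float = MC_SMOOTHING_SIGMA,
) -> SurfaceMesh:
    """Closed triangulated isosurface of a binary mask, in world mm.

    Marching cubes at the 0.5 level on a zero-padded (hence watertight),
    Gaussian-anti-aliased copy of the mask; smoothing is skipped for
    structures too small to survive it.
    """
    arr, spc = _mask_and_spacing(mask, spacing)
    if arr.ndim != 3:
        raise ValidationError("mesh_from_mask needs a 3D mask")
    if not arr.any():
        raise EmptyMeshError("cannot mesh an empty mask")
    pad = max(2, int(np.ceil(3 * smoothing_sigma)))
    vol = np.pad(arr.astype(float), pad)
    if smoothing_sigma > 0:
        smoothed = ndimage.gaussian_filter(vol, smoothing_sigma)
        if smoothed.max() > level:
            vol = smoothed
    verts, faces, _, _ = measure.marching_cubes(vol, level=level, spacing=spc)
    verts = verts - pad * np.asarray(spc)
    return SurfaceMesh(vertices=verts, faces=faces)


def _hull_volume(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise ValidationError(f"degenerate (coplanar/collinear) point set for hull: {exc}") from exc


# ---------------------------------------------------------------------------
# 3D morphometrics
# ---------------------------------------------------------------------------

def mesh_morphometrics(mesh: SurfaceMesh) -> Morphometrics3D:
    """Morphometrics of an exact closed mesh (vertices in mm).

    V is the enclosed mesh volume (divergence theorem), SA the facet-area
    sum, the hull is taken over the mesh vertices. Used for analytic
    reference shapes and STL inputs.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        warnings.warn("mesh is not watertight; enclosed volume may be unreliable", stacklevel=2)
    v_mm3 = float(abs(tm.volume))
    sa_mm2 = mesh.area_mm2
    return Morphometrics3D(
        volume_ml=v_mm3 / 1000.0,
        surface_area_cm2=sa_mm2 / 100.0,
        sphericity=sphericity_from_vsa(v_mm3, sa_mm2),
        solidity=v_mm3 / _hull_volume(mesh.vertices),
        sa_to_v_cm=(sa_mm2 / 100.0) / (v_mm3 / 1000.0),
    )


def morphometrics_3d(
    mask: SegmentationMask | np.ndarray,
    volume: VoxelVolume | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> Morphometrics3D:
    """Morphometrics of a segmented depot.

    V = voxel count x voxel volume; SA from the marching-cubes mesh;
    sphericity from (V, SA) in mm; solidity = V / hull volume over mesh
    vertices; mean HU over the mask when the source volume is supplied.
    """
    arr, spc = _mask_and_spacing(mask, spacing)
    if not arr.any():
        raise ValidationError("empty mask")
    v_mm3 = float(arr.sum()) * float(np.prod(spc))
    mesh = mesh_from_mask(arr, spc)
    sa_mm2 = mesh.area_mm2
    mean_hu = None
    if volume is not None:
        mean_hu = float(np.mean(np.asarray(volume.data)[arr]))
    return Morphometrics3D(
        volume_ml=v_mm3 / 1000.0,
        surface_area_cm2=sa_mm2 / 100.0,
        sphericity=sphericity_from_vsa(v_mm3, sa_mm2),
        solidity=v_mm3 / _hull_volume(mesh.vertices),
        sa_to_v_cm=(sa_mm2 / 100.0) / (v_mm3 / 1000.0),
        mean_hu=mean_hu,
    )


# ---------------------------------------------------------------------------
# 2D morphometrics
# ---------------------------------------------------------------------------

def contour_perimeter(
    mask2d: np.ndarray,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    smooth_window: int = PERIMETER_SMOOTH_WINDOW,
) -> float:
    """Polygonal boundary length in mm from smoothed marching-squares
    contours (see module docstring for the accuracy trade-off)."""
    arr = np.asarray(mask2d, dtype=bool)
    contours = measure.find_contours(np.pad(arr.astype(float), 1), 0.5)
    spc = np.asarray(pixel_spacing, dtype=float)
    total = 0.0
    for c in contours:
        pts = c[:-1] * spc  # drop duplicated closing point; scale to mm
        n = len(pts)
        if smooth_window > 1 and n > smooth_window:
            k = np.ones(smooth_window) / smooth_window
            half = smooth_window // 2
            wrapped = np.vstack([pts[-half:], pts, pts[:half]])
            pts = np.column_stack(
                [np.convolve(wrapped[:, j], k, "valid") for j in range(2)]
            )
        closed = np.vstack([pts, pts[:1]])
        total += float(np.hypot(*np.diff(closed, axis=0).T).sum())
    return total


def _pixel_corners(mask2d: np.ndarray, pixel_spacing) -> np.ndarray:
    """Corner points (mm) of every foreground pixel square."""
    rr, cc = np.nonzero(mask2d)
    sr, sc = pixel_spacing
    pts = []
    for dr in (-0.5, 0.5):
        for dc in (-0.5, 0.5):
            pts.append(np.column_stack([(rr + dr) * sr, (cc + dc) * sc]))
    return np.vstack(pts)


def morphometrics_2d(
    mask2d: np.ndarray,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> Morphometrics2D:
    """Plane morphometrics of a 2D mask.

    Area = pixel count x pixel area; axes are the equivalent-ellipse axis
    lengths from second-order moments (with the 1/12 pixel-square
    self-moment, so a single pixel still has finite axes);
    circularity = 4 pi A / P^2; solidity = area / convex-hull area of the
    pixel corner points.
    """
    arr = np.asarray(mask2d, dtype=bool)
    if arr.ndim != 2:
        raise ValidationError("morphometrics_2d needs a 2D mask")
    if not arr.any():
        raise ValidationError("empty 2D mask")
    sr, sc = (float(s) for s in pixel_spacing)
    n = int(arr.sum())
    area_mm2 = n * sr * sc

    rr, cc = np.nonzero(arr)
    y = rr * sr
    x = cc * sc
    pts = np.column_stack([y, x])
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / n + np.diag([sr * sr / 12.0, sc * sc / 12.0])
    evals = np.linalg.eigvalsh(cov)[::-1]
    major_mm = 4.0 * np.sqrt(max(evals[0], 0.0))
    minor_mm = 4.0 * np.sqrt(max(evals[1], 0.0))

    perim_mm = contour_perimeter(arr, (sr, sc))
    circularity = 4.0 * np.pi * area_mm2 / perim_mm ** 2
    hull_area_mm2 = _hull_volume(_pixel_corners(arr, (sr, sc)))
    return Morphometrics2D(
        area_cm2=area_mm2 / 100.0,
        major_axis_cm=major_mm / 10.0,
        minor_axis_cm=minor_mm / 10.0,
        circularity=circularity,
        solidity=area_mm2 / hull_area_mm2,
        perimeter_cm=perim_mm / 10.0,
    )


# ---------------------------------------------------------------------------
# serial per-mL deposition analysis
# ---------------------------------------------------------------------------

@dataclass
class SerialDeposition:
    """Per-injection-step masks aligned to a common needle frame."""

    masks: list[SegmentationMask]
    morphometrics: list[Morphometrics3D]
    incremental_volumes_ml: np.ndarray
    non_increasing_volume: bool = False  # warning flag, not an error


def _rotation_between(d_from: np.ndarray, d_to: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector d_from onto d_to (Rodrigues)."""
    a = d_from / np.linalg.norm(d_from)
    b = d_to / np.linalg.norm(d_to)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.isclose(c, 1.0):
        return np.eye(3)
    if np.isclose(c, -1.0):
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _align_mask(mask: np.ndarray, spacing, point, direction, ref_point, ref_direction) -> np.ndarray:
    """Rigidly transform a mask so its needle axis coincides with the
    reference axis (nearest-neighbour resampling on the same grid)."""
    spc = np.asarray(spacing, dtype=float)
    rot = _rotation_between(np.asarray(direction, float), np.asarray(ref_direction, float))
    # output world w' = R (w - p) + p_ref; affine_transform needs the inverse
    matrix = np.diag(1.0 / spc) @ rot.T @ np.diag(spc)
    offset = (np.asarray(point, float) - rot.T @ np.asarray(ref_point, float)) / spc
    out = ndimage.affine_transform(
        mask.astype(np.uint8), matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return out.astype(bool)


def serial_per_ml_analysis(
    masks: list[SegmentationMask],
    needle_axes: list[tuple[np.ndarray, np.ndarray]] | tuple[np.ndarray, np.ndarray],
) -> SerialDeposition:
    """Align per-mL injection-step masks on the needle axis and measure them.

    ``needle_axes`` is one (point, direction) world line shared by all
    steps, or one per step; steps after the first are rigidly transformed
    so their needle axes coincide with the first step's. Returns per-step
    3D morphometrics and incremental (step k minus step k-1) volumes; a
    non-increasing total volume sets a warning flag (leakage can shrink the
    visible depot) rather than raising.
    """
    if len(masks) < 2:
        raise ValidationError("serial analysis needs at least 2 steps")
    if isinstance(needle_axes, tuple) and not isinstance(needle_axes[0], tuple):
        needle_axes = [needle_axes] * len(masks)
    if len(needle_axes) != len(masks):
        raise ValidationError("one needle axis per step (or a single shared axis) required")

    ref_point, ref_dir = needle_axes[0]
    aligned = [masks[0]]
    for m, (p, d) in zip(masks[1:], needle_axes[1:]):
        arr = _align_mask(m.mask, m.spacing, p, d, ref_point, ref_dir)
        aligned.append(SegmentationMask(mask=arr, spacing=m.spacing))

    morph = [morphometrics_3d(m.mask, spacing=m.spacing) for m in aligned]
    totals = np.array([m.volume_ml for m in aligned])
    incremental = np.diff(np.concatenate([[0.0], totals]))
    flag = bool(np.any(np.diff(totals) <= 0))
    if flag:
        warnings.warn("total depot volume is non-increasing across steps", stacklevel=2)
    return SerialDeposition(
        masks=aligned,
        morphometrics=morph,
        incremental_volumes_ml=incremental,
        non_increasing_volume=flag,
    )
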