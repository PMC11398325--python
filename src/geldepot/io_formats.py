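"""Readers and writers for every external representation the pipeline touches.

Coordinate convention (used everywhere in the package):

* World coordinates are in millimetres.
* Voxel/pixel indices are 0-based and the stored value sits at the voxel
  *center*, so index ``i`` along an axis maps to ``origin + i * spacing``.
* :class:`VoxelVolume` arrays are indexed ``data[ix, iy, iz]`` — array axis
  0 is world x, axis 1 is world y, axis 2 is world z.
* :class:`PlanarImage` arrays are indexed ``data[row, col]`` with
  ``pixel_spacing = (row_mm, col_mm)``.

Physical quantities never leave this module in voxel/pixel units: spacing
is attached to every container and all downstream measurements are
reported in mm/cm/mL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import trimesh

from .errors import EmptyMeshError, FormatError, ValidationError

__all__ = [
    "VoxelVolume",
    "PlanarImage",
    "TrackedFrame",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "read_mesh_stl",
    "write_mesh_stl",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_poses_json",
    "write_poses_json",
    "read_frame_image",
    "write_frame_image",
    "read_tracked_frames",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_METAIMAGE_SUFFIXES = (".mha", ".mhd")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical spacing.

    ``data`` carries Hounsfield units for CT/CBCT or arbitrary echo units
    for reconstructed ultrasound volumes (``modality='US3D'``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"VoxelVolume needs a 3D array, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.modality not in ("CT", "CBCT", "US3D"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume data must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world mm (voxel-center convention)."""
        idx = np.atleast_2d(idx)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class PlanarImage:
    """A single 2D grayscale image (B-mode frame or CT plane)."""

    data: np.ndarray
    pixel_spacing: tuple[float, float]  # (row, col) mm
    intensity_units: str = "au"  # "HU" or "au"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError(f"PlanarImage needs a 2D array, got {self.data.ndim}D")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError(f"pixel_spacing must be 2 positive lengths, got {self.pixel_spacing}")
        if self.intensity_units not in ("HU", "au"):
            raise ValidationError(f"intensity_units must be 'HU' or 'au', got {self.intensity_units!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("image data must be finite")

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass
class TrackedFrame:
    """A B-mode frame plus the rigid pose placing it in world coordinates.

    Image-plane coordinates ``(u * col_spacing, v * row_spacing, 0)`` (u =
    column index, v = row index) are mapped to world mm by
    ``world = rotation @ plane + translation``.
    """

    image: PlanarImage
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-6):
            raise ValidationError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValidationError("rotation must be proper (det +1)")

    @classmethod
    def from_matrix(cls, image: PlanarImage, matrix: np.ndarray) -> "TrackedFrame":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValidationError("pose matrix must be 4x4")
        return cls(image=image, rotation=matrix[:3, :3], translation=matrix[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def pixel_world_coords(self) -> np.ndarray:
        """World mm coordinates of every pixel center, shape (rows, cols, 3)."""
        rows, cols = self.image.data.shape
        v, u = np.mgrid[0:rows, 0:cols]
        plane = np.stack(
            [
                u * self.image.pixel_spacing[1],
                v * self.image.pixel_spacing[0],
                np.zeros_like(u, dtype=float),
            ],
            axis=-1,
        )
        return plane @ self.rotation.T + self.translation


@dataclass
class SurfaceMesh:
    """A triangulated surface in world mm."""

    vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (M, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def area_mm2(self) -> float:
        """Summed facet area."""
        v = self.vertices
        t = v[self.faces]
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _suffix_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path: str | Path, modality: str = "CT") -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing and origin are taken from the header; intensities are passed
    through unscaled beyond the header slope/intercept.
    """
    path = Path(path)
    suffix = _suffix_of(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        if suffix in _NIFTI_SUFFIXES:
            img = nib.load(str(path))
            data = np.asarray(img.get_fdata())
            zooms = img.header.get_zooms()[:3]
            origin = tuple(float(x) for x in img.affine[:3, 3])
            spacing = tuple(float(z) for z in zooms)
        elif suffix in _METAIMAGE_SUFFIXES:
            img = sitk.ReadImage(str(path))
            # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
            spacing = tuple(float(s) for s in img.GetSpacing())
            origin = tuple(float(o) for o in img.GetOrigin())
        else:
            raise FormatError(f"unsupported volume format {suffix!r} for {path}")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap third-party parse errors
        raise FormatError(f"unreadable volume file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path} holds a {data.ndim}D payload, expected 3D")
    return VoxelVolume(data=data, spacing=spacing, origin=origin, modality=modality)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI or MetaImage depending on the suffix."""
    path = Path(path)
    suffix = _suffix_of(path)
    if suffix in _NIFTI_SUFFIXES:
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    elif suffix in _METAIMAGE_SUFFIXES:
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format {suffix!r} for {path}")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a binary STL. Re-reading yields the same triangle set up to
    vertex de-duplication."""
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write a mesh with no faces")
    mesh.to_trimesh().export(str(path), file_type="stl")


def read_mesh_stl(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mesh file: {path}")
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable STL {path}: {exc}") from exc
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# plasma tables
# ---------------------------------------------------------------------------

def write_plasma_csv(series, path: str | Path) -> None:
    """Write a PlasmaSeries as CSV with a JSON sidecar holding t_admin."""
    path = Path(path)
    pd.DataFrame({"time_min": series.t, "conc_ng_per_ml": series.C}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"t_admin_min": series.t_admin, "label": series.label}))


def read_plasma_csv(path: str | Path, t_admin: float | None = None, label: str | None = None):
    """Read a plasma concentration-time table.

    Columns ``time_min`` and ``conc_ng_per_ml`` are required and time must
    be strictly increasing. The administration window is taken from an
    explicit ``t_admin`` argument or, failing that, from a
    ``<name>.csv.meta.json`` companion file.
    """
    from .pharmacokinetics import PlasmaSeries  # local import: avoid cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such plasma file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable plasma CSV {path}: {exc}") from exc
    for col in ("time_min", "conc_ng_per_ml"):
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"{path} holds no samples (header-only file)")
    t = df["time_min"].to_numpy(dtype=float)
    c = df["conc_ng_per_ml"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: time_min must be strictly increasing")
    if np.any(c < 0):
        raise ValidationError(f"{path}: negative concentration values")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if t_admin is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        t_admin = meta.get("t_admin_min")
        if label is None:
            label = meta.get("label")
    kwargs = {}
    if t_admin is not None:
        kwargs["t_admin"] = float(t_admin)
    return PlasmaSeries(t=t, C=c, label=label or "", **kwargs)


# ---------------------------------------------------------------------------
# tracked frames: TIFF/PNG images + JSON pose lists
# ---------------------------------------------------------------------------

def write_frame_image(image: PlanarImage, path: str | Path) -> None:
    """Write a frame as 16-bit TIFF (.tif) or 8-bit PNG (.png)."""
    path = Path(path)
    data = np.asarray(image.data)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            str(path),
            np.clip(np.rint(data), 0, 65535).astype(np.uint16),
            resolution=(25.4 / image.pixel_spacing[1], 25.4 / image.pixel_spacing[0]),
        )
    elif path.suffix.lower() == ".png":
        iio.imwrite(str(path), np.clip(np.rint(data), 0, 255).astype(np.uint8))
    else:
        raise FormatError(f"unsupported frame format {path.suffix!r}")


def read_frame_image(path: str | Path, pixel_spacing: tuple[float, float]) -> PlanarImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            data = tifffile.imread(str(path))
        else:
            data = iio.imread(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    return PlanarImage(data=np.asarray(data, dtype=float), pixel_spacing=pixel_spacing)


def write_poses_json(frames: Sequence[TrackedFrame], path: str | Path) -> None:
    """Write poses as a JSON list of 4x4 row-major matrices, one per frame,
    same order as the frame image files."""
    mats = [f.as_matrix().tolist() for f in frames]
    Path(path).write_text(json.dumps(mats))


def read_poses_json(path: str | Path) -> list[np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such pose file: {path}")
    try:
        mats = json.loads(path.read_text())
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable pose JSON {path}: {exc}") from exc
    out = []
    for m in mats:
        arr = np.asarray(m, dtype=float)
        if arr.shape != (4, 4):
            raise FormatError(f"{path}: each pose must be a 4x4 matrix")
        out.append(arr)
    return out


def read_tracked_frames(
    image_paths: Sequence[str | Path],
    poses_path: str | Path,
    pixel_spacing: tuple[float, float],
) -> list[TrackedFrame]:
    """Pair frame images (sorted order) with the pose list."""
    poses = read_poses_json(poses_path)
    if len(poses) != len(image_paths):
        raise ValidationError(
            f"{len(image_paths)} frame images but {len(poses)} poses"
        )
    return [
        TrackedFrame.from_matrix(read_frame_image(p, pixel_spacing), m)
        for p, m in zip(image_paths, poses)
    ]
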