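"""Segmentation-volume ingestion and surface-mesh preprocessing.

The front end of the pipeline: read multi-label segmentation volumes
(NIfTI or NRRD), extract per-region closed surfaces by marching cubes,
then apply the preprocessing used before simulation — decimation to a
target face count (default 10,000) and isotropic scaling (default one
half, which speeds up calibration while preserving particle size).

Conventions: physical units are always millimetres; voxel indices are
0-based with voxel *centers* at ``origin + index * spacing``; the
anatomical frame is x = left, y = ventral (+y points to the belly,
so −y is dorsal / the operating table), z = cranial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from . import _nrrd, _ply
from ._decimate import quadric_decimate
from ._geometry import is_watertight, mesh_volume

REGIONS = ("wall", "viscera", "inflatable", "skin", "lungs")

#: default label integers, matching the four-region segmentation scheme
#: (gas/inflatable boundary, viscera, lungs, abdominal wall) plus background
DEFAULT_LABEL_MAP = {
    "background": 0,
    "wall": 1,
    "viscera": 2,
    "inflatable": 3,
    "lungs": 4,
}

MIN_REGION_VOXELS = 10


@dataclass
class SurfaceMesh:
    """Triangulated region surface in mm.

    ``region`` is one of :data:`REGIONS`.  Closed meshes are consistently
    oriented with positive signed volume; a thick region (the abdominal
    wall) may have a multi-shell boundary and is still closed in the
    every-edge-shared-by-two-faces sense.
    """

    vertices: np.ndarray
    faces: np.ndarray
    region: str = "wall"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def volume(self) -> float:
        """Signed enclosed volume (mm³), positive for outward orientation."""
        return mesh_volume(self.vertices, self.faces)

    def is_watertight(self) -> bool:
        return is_watertight(self.vertices, self.faces)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.region)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class LabelVolume:
    """Voxel grid of region labels with physical geometry.

    ``voxels`` is indexed ``[x, y, z]``; ``spacing``/``origin`` are mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("label volume must be a non-empty 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        present = set(np.unique(self.voxels).tolist())
        declared = set(self.label_map.values())
        unknown = sorted(present - declared)
        if unknown:
            raise ValueError(
                f"volume contains labels {unknown} absent from the label map "
                f"{sorted(declared)}")

    def region_mask(self, region: str) -> np.ndarray:
        if region not in self.label_map:
            raise KeyError(f"region {region!r} not in label map")
        return self.voxels == self.label_map[region]

    def region_voxel_count(self, region: str) -> int:
        return int(self.region_mask(region).sum())


def read_label_volume(path, label_map: dict[str, int] | None = None
                      ) -> LabelVolume:
    """Read a NIfTI (``.nii``/``.nii.gz``) or NRRD segmentation volume.

    Spacing and origin are reconstructed from the file header; labels found
    in the file must all appear in ``label_map`` (default
    :data:`DEFAULT_LABEL_MAP`).
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map = dict(label_map or DEFAULT_LABEL_MAP)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"{path}: header lacks valid voxel spacing")
        origin = tuple(float(t) for t in img.affine[:3, 3])
        voxels = np.asarray(img.dataobj).astype(np.int16)
    elif name.endswith(".nrrd"):
        voxels, header = _nrrd.read_nrrd(path)
        if "spacing" not in header:
            raise ValueError(f"{path}: NRRD header lacks voxel spacing")
        spacing = header["spacing"]
        origin = header.get("origin", (0.0, 0.0, 0.0))
        voxels = voxels.astype(np.int16)
    else:
        raise ValueError(
            f"{path}: unsupported volume format (expected .nii/.nii.gz/.nrrd)")
    return LabelVolume(voxels, spacing, origin, label_map)


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a LabelVolume to NIfTI or NRRD depending on extension."""
    import nibabel as nib

    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(vol.voxels.astype(np.int16), affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif name.endswith(".nrrd"):
        _nrrd.write_nrrd(path, vol.voxels.astype(np.int16), vol.spacing,
                         vol.origin)
    else:
        raise ValueError(f"{path}: unsupported volume format")


def extract_region_surface(vol: LabelVolume, region: str) -> SurfaceMesh:
    """Closed isosurface of one region at iso-level 0.5 (marching cubes).

    Vertices are mapped to physical mm with the volume's spacing/origin and
    the mesh is oriented so its signed volume is positive.
    """
    mask = vol.region_mask(region)
    count = int(mask.sum())
    if count < MIN_REGION_VOXELS:
        raise ValueError(
            f"region {region!r} has {count} voxels "
            f"(minimum {MIN_REGION_VOXELS}) — too small to mesh")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=vol.spacing)
    verts = verts + np.asarray(vol.origin) - np.asarray(vol.spacing)
    mesh_region = region if region in REGIONS else "wall"
    mesh = SurfaceMesh(verts, faces, mesh_region)
    if mesh.volume() < 0:
        mesh = SurfaceMesh(verts, faces[:, ::-1], mesh_region)
    if not mesh.is_watertight():
        raise ValueError(
            f"marching-cubes surface of region {region!r} is not closed "
            f"({len(faces)} faces); check the segmentation for stray voxels")
    return mesh


def simplify_mesh(mesh: SurfaceMesh, target_faces: int = 10000) -> SurfaceMesh:
    """Decimate a closed mesh to exactly ``target_faces`` faces.

    Quadric edge collapse with manifold and orientation guards; raises if the
    mesh is open, the target invalid, or decimation would damage closedness.
    """
    if target_faces > mesh.n_faces:
        raise ValueError(
            f"target {target_faces} exceeds current face count {mesh.n_faces}")
    if target_faces < 100:
        raise ValueError(f"target {target_faces} below minimum of 100 faces")
    if not mesh.is_watertight():
        raise ValueError("decimation requires a closed (watertight) mesh")
    if target_faces == mesh.n_faces:
        return mesh.copy()
    v, f = quadric_decimate(mesh.vertices, mesh.faces, target_faces)
    out = SurfaceMesh(v, f, mesh.region)
    if not out.is_watertight():
        raise ValueError(
            "decimation broke watertightness; choose a larger target")
    return out


def scale_mesh(mesh: SurfaceMesh, factor: float) -> SurfaceMesh:
    """Scale isotropically about the vertex centroid (volume scales by f³)."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    c = mesh.centroid()
    return replace(mesh.copy(), vertices=c + factor * (mesh.vertices - c))


def read_mesh(path, region: str = "wall") -> SurfaceMesh:
    """Read an STL or PLY triangle mesh (mm)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = _ply.read_ply(path)
        return SurfaceMesh(data["vertices"], data["faces"], region)
    if suffix == ".stl":
        tm = trimesh.load(str(path), file_type="stl", process=False)
        if not isinstance(tm, trimesh.Trimesh):
            raise ValueError(f"{path}: not a triangle mesh")
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                           region)
    raise ValueError(
        f"{path}: unsupported mesh format {suffix!r} (only STL and PLY "
        f"triangle meshes are accepted)")


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write STL (binary, float32 per the format) or PLY (binary, float64)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        _ply.write_ply(path, mesh.vertices, mesh.faces)
    elif suffix == ".stl":
        mesh.as_trimesh().export(str(path), file_type="stl")
    else:
        raise ValueError(f"{path}: unsupported mesh format {suffix!r}")
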