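"""Synthetic abdomen phantom: nested ellipsoidal shells with known truth.

Real insufflation studies image the same subject twice — deflated and
insufflated — and treat the insufflated reconstruction as ground truth.
No such scan pair ships with this package, so the phantom plays that
role: an ellipsoidal "torso" with the same region topology a segmented
abdominal CT has (skin/abdominal wall shell, viscera, a thin gas gap
bounded by the peritoneal "inflatable" surface, plus an inert lungs
blob), and an analytically inflated counterpart with identical vertex
topology, so every downstream stage — rasterization, surface
extraction, discretization, simulation, error metrics, calibration —
can be validated against known generating parameters.

The default phantom is a half-scale porcine-like torso section (skin
semi-axes 36×28×30 mm), matching the pipeline's half-scaling of the
input meshes.  Axes: x left, +y ventral, z cranial; the body is centred
at the origin.

Ground-truth inflation is analytic: the ventral wall (and the attached
peritoneal surface) is pushed outward by a smooth radial bump, and the
viscera yield dorsally by a compensating amount, which is what a gas
pocket forming between wall and viscera looks like at first order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from ._geometry import grid_points_in_mesh
from .imaging import (DEFAULT_LABEL_MAP, LabelVolume, SurfaceMesh,
                      write_label_volume, write_mesh)

#: landmark name → unit direction on the skin used to seat it
_LANDMARK_DIRECTIONS = {
    "umbilicus": (0.0, 1.0, 0.0),
    "asis_right": (-0.55, 0.65, -0.52),
    "asis_left": (0.55, 0.65, -0.52),
    "xiphisternum": (0.0, 0.62, 0.78),
    "pubic_symphysis": (0.0, 0.62, -0.78),
}


@dataclass
class PhantomSpec:
    """Generating parameters of the synthetic abdomen (all lengths mm)."""

    skin_semi_axes: tuple[float, float, float] = (36.0, 28.0, 30.0)
    wall_thickness: float = 4.0
    viscera_semi_axes: tuple[float, float, float] = (29.5, 21.5, 23.5)
    gap_thickness: float = 2.5
    bump_amplitude: float = 6.0
    mesh_subdivisions: int = 4
    voxel_spacing: float = 1.0
    seed: int = 0
    #: amplitude of the seeded smooth asymmetry, as a fraction of the
    #: smallest skin semi-axis (0 disables; keeps the phantom non-spherical)
    irregularity: float = 0.015

    def __post_init__(self):
        self.skin_semi_axes = tuple(float(a) for a in self.skin_semi_axes)
        self.viscera_semi_axes = tuple(float(a) for a in self.viscera_semi_axes)
        if min(self.skin_semi_axes) <= 0 or min(self.viscera_semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        for name in ("wall_thickness", "gap_thickness", "voxel_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be non-negative")
        if self.mesh_subdivisions < 2:
            raise ValueError("mesh_subdivisions must be at least 2")
        inner = self.wall_inner_semi_axes
        for v, i in zip(self.viscera_semi_axes, inner):
            if v + self.gap_thickness > i + 1e-9:
                raise ValueError(
                    "geometry infeasible: viscera semi-axes "
                    f"{self.viscera_semi_axes} do not fit inside the wall "
                    f"inner surface {inner} with {self.gap_thickness} mm "
                    "gap clearance")

    @property
    def wall_inner_semi_axes(self) -> tuple[float, float, float]:
        return tuple(a - self.wall_thickness for a in self.skin_semi_axes)


@dataclass
class PhantomPair:
    """Deflated phantom plus its analytically insufflated ground truth.

    Region meshes of ``deflated`` and ``inflated_truth`` share vertex
    topology index-for-index (the correspondence map is the identity), so
    indexed per-vertex errors are meaningful, as they are for registered
    scan pairs of one subject.
    """

    spec: PhantomSpec
    deflated: dict[str, SurfaceMesh]
    inflated_truth: dict[str, SurfaceMesh]
    true_params: dict[str, float]
    landmarks: dict[str, np.ndarray]
    landmark_indices: dict[str, int] = field(default_factory=dict)

    def landmark_positions(self, state: str = "deflated") -> dict[str, np.ndarray]:
        """Landmark coordinates on the deflated or inflated skin."""
        meshes = self.deflated if state == "deflated" else self.inflated_truth
        skin = meshes["skin"]
        return {name: skin.vertices[idx].copy()
                for name, idx in self.landmark_indices.items()}


def _unit_sphere(subdivisions: int) -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)


def _harmonic_field(rng: np.random.Generator):
    """Smooth zero-mean function on the unit sphere (degree-2 harmonics)."""
    c = rng.uniform(-1.0, 1.0, size=5)

    def f(u: np.ndarray) -> np.ndarray:
        x, y, z = u[:, 0], u[:, 1], u[:, 2]
        return (c[0] * x * y + c[1] * y * z + c[2] * x * z
                + c[3] * (x * x - y * y) + c[4] * (3 * z * z - 1) / 2)

    return f


def _bump_weight(u: np.ndarray) -> np.ndarray:
    """Smooth ventral weight in [0, 1]: 0 on the dorsal half, 1 at +y."""
    return np.maximum(0.0, u[:, 1]) ** 2


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Build the deflated phantom and its inflated ground-truth twin.

    Deterministic for a given spec (including seed).  All meshes are
    watertight; corresponding deflated/inflated meshes share vertices and
    faces index-for-index.
    """
    sphere = _unit_sphere(spec.mesh_subdivisions)
    unit = np.asarray(sphere.vertices)  # unit directions, |u| = 1
    faces = np.asarray(sphere.faces)
    rng = np.random.default_rng(spec.seed)
    wobble = _harmonic_field(rng)
    amp = spec.irregularity * min(spec.skin_semi_axes)
    radial_jitter = amp * wobble(unit)  # same for every shell: gaps preserved

    def shell(semi_axes, region) -> SurfaceMesh:
        v = unit * np.asarray(semi_axes) + radial_jitter[:, None] * unit
        return SurfaceMesh(v, faces.copy(), region)

    skin = shell(spec.skin_semi_axes, "skin")
    inner = shell(spec.wall_inner_semi_axes, "wall")
    inflatable = SurfaceMesh(inner.vertices.copy(), faces.copy(), "inflatable")
    viscera = shell(spec.viscera_semi_axes, "viscera")
    # wall = closed shell between skin and inner surface (two components,
    # inner one flipped inward)
    wall = SurfaceMesh(
        np.vstack([skin.vertices, inner.vertices]),
        np.vstack([faces, faces[:, ::-1] + len(skin.vertices)]),
        "wall")
    # lungs: small inert ellipsoid in the cranial viscera space
    lungs_axes = 0.32 * np.asarray(spec.viscera_semi_axes)
    lungs_center = np.array([0.0, 0.0, 0.55 * spec.viscera_semi_axes[2]])
    lungs = SurfaceMesh(unit * lungs_axes + lungs_center, faces.copy(), "lungs")

    deflated = {"skin": skin, "wall": wall, "inflatable": inflatable,
                "viscera": viscera, "lungs": lungs}

    # --- analytic inflation -------------------------------------------------
    A = spec.bump_amplitude
    # viscera give way dorsally by a compensating fraction of the bump,
    # bounded by the available gap so they stay inside the peritoneal surface
    s = min(0.5 * A, 0.8 * spec.gap_thickness)

    def inflate_outward(mesh: SurfaceMesh) -> SurfaceMesh:
        u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        disp = (A * _bump_weight(u))[:, None] * u
        return SurfaceMesh(mesh.vertices + disp, mesh.faces.copy(), mesh.region)

    def viscera_yield(mesh: SurfaceMesh) -> SurfaceMesh:
        centered = mesh.vertices - lungs_center if mesh.region == "lungs" \
            else mesh.vertices
        u = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        disp = np.zeros_like(mesh.vertices)
        disp[:, 1] = -s * np.maximum(0.0, u[:, 1])
        return SurfaceMesh(mesh.vertices + disp, mesh.faces.copy(), mesh.region)

    inflated = {
        "skin": inflate_outward(skin),
        "inflatable": inflate_outward(inflatable),
        "viscera": viscera_yield(viscera),
        "lungs": viscera_yield(lungs),
    }
    wall_in = inflate_outward(SurfaceMesh(inner.vertices, faces, "wall"))
    inflated["wall"] = SurfaceMesh(
        np.vstack([inflated["skin"].vertices, wall_in.vertices]),
        wall.faces.copy(), "wall")

    # gas volume must grow
    v_defl = inflatable.volume() - viscera.volume()
    v_infl = inflated["inflatable"].volume() - inflated["viscera"].volume()
    if A > 0 and not v_infl > v_defl:
        raise ValueError("inflation produced no gas-volume increase")

    # landmarks: canonical directions snapped to exact skin vertices
    landmark_indices = {}
    for name, d in _LANDMARK_DIRECTIONS.items():
        d = np.asarray(d) / np.linalg.norm(d)
        landmark_indices[name] = int(
            np.argmax(skin.vertices / np.linalg.norm(
                skin.vertices, axis=1, keepdims=True) @ d))
    landmarks = {name: skin.vertices[i].copy()
                 for name, i in landmark_indices.items()}

    true_params = {
        "pressure_factor": v_infl / v_defl,
        "cluster_stiffness": 0.6,
        "spring_stiffness": 0.5,
        "bump_amplitude": A,
    }
    return PhantomPair(spec, deflated, inflated, true_params, landmarks,
                       landmark_indices)


def rasterize_phantom(pair: PhantomPair, spacing: float | None = None,
                      state: str = "deflated") -> LabelVolume:
    """Voxelize a phantom into a label volume (innermost region wins).

    Labels follow :data:`DEFAULT_LABEL_MAP`.  Precedence, innermost first:
    lungs → viscera → gas (inflatable) → wall → background, evaluated with
    ray-parity point-in-mesh tests at voxel centers.
    """
    spacing = float(spacing if spacing is not None else pair.spec.voxel_spacing)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    meshes = pair.deflated if state == "deflated" else pair.inflated_truth
    skin = meshes["skin"]
    lo = skin.vertices.min(axis=0) - 2 * spacing
    hi = skin.vertices.max(axis=0) + 2 * spacing
    axes = [np.arange(lo[k], hi[k] + spacing / 2, spacing) for k in range(3)]

    inside = {
        name: grid_points_in_mesh(meshes[name].vertices, meshes[name].faces,
                                  *axes)
        for name in ("skin", "inflatable", "viscera", "lungs")
    }
    labels = np.zeros(tuple(len(a) for a in axes), dtype=np.int16)
    lm = DEFAULT_LABEL_MAP
    labels[inside["skin"]] = lm["wall"]
    labels[inside["inflatable"]] = lm["inflatable"]
    labels[inside["viscera"]] = lm["viscera"]
    labels[inside["lungs"]] = lm["lungs"]

    for region in ("wall", "inflatable", "viscera", "lungs"):
        count = int((labels == lm[region]).sum())
        if count < 10:
            raise ValueError(
                f"spacing {spacing} mm too coarse: region {region!r} has "
                f"{count} voxels (< 10)")
    return LabelVolume(labels, (spacing,) * 3,
                       tuple(float(a[0]) for a in axes))


def write_phantom(pair: PhantomPair, out_dir, spacing: float | None = None
                  ) -> dict[str, str]:
    """Write label volumes (NIfTI + NRRD), meshes (STL + PLY) and landmark
    JSON for both phantom states; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for state in ("deflated", "inflated_truth"):
        vol = rasterize_phantom(
            pair, spacing,
            state="deflated" if state == "deflated" else "inflated")
        for ext in ("nii.gz", "nrrd"):
            p = out / f"{state}.{ext}"
            write_label_volume(vol, p)
            written[f"{state}_{ext}"] = str(p)
        meshes = pair.deflated if state == "deflated" else pair.inflated_truth
        for region, mesh in meshes.items():
            for ext in ("stl", "ply"):
                p = out / f"{state}_{region}.{ext}"
                write_mesh(mesh, p)
                written[f"{state}_{region}_{ext}"] = str(p)
    lm_path = out / "landmarks.json"
    lm_path.write_text(json.dumps(
        {k: [float(x) for x in v] for k, v in pair.landmarks.items()},
        indent=2))
    written["landmarks"] = str(lm_path)
    return written
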