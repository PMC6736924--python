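"""From region meshes to the simulated entities: particles and constraints.

Soft bodies (abdominal wall, viscera) are filled with particles on a
regular interior grid; deformability comes from overlapping
shape-matching clusters.  The peritoneal boundary becomes an
"inflatable" — one particle per surface vertex carrying the closed
triangulation, stiffened by edge springs and driven by a volume target.
Extra connectivity springs tie the inflatable to nearby wall particles
so the gas pocket cannot escape the abdominal wall.  Dorsal wall
particles below the centre of mass are pinned to stand in for the
operating table, and the rendered skin mesh is bound to the wall
particles so deformed surfaces can be exported.

Lengths are mm, masses grams, densities g/cm³ (converted internally).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import grid_points_in_mesh, mesh_volume, unique_edges
from .imaging import SurfaceMesh

MIN_SPRING_REST_LENGTH = 1e-3  # mm; guards zero-length springs

#: particles per mm³ conversion: densities are quoted in g/cm³
_G_PER_CM3_TO_G_PER_MM3 = 1e-3


def particle_mass(radius: float, density: float = 1.05) -> float:
    """Mass (g) of one particle of the given radius (mm), density g/cm³."""
    return density * _G_PER_CM3_TO_G_PER_MM3 * (4.0 / 3.0) * np.pi * radius**3


@dataclass
class ParticleSystem:
    """Positions (mm), velocities (mm/s), inverse masses (1/g; 0 = fixed),
    a single global particle radius (mm) and a region tag per particle."""

    positions: np.ndarray
    velocities: np.ndarray
    inverse_masses: np.ndarray
    radius: float
    regions: np.ndarray  # array of region-name strings

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.inverse_masses = np.asarray(self.inverse_masses, dtype=np.float64)
        self.regions = np.asarray(self.regions)
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        if (self.inverse_masses < 0).any():
            raise ValueError("inverse masses must be non-negative")
        if not np.isfinite(self.positions).all():
            raise ValueError("particle positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_fixed(self) -> int:
        return int((self.inverse_masses == 0).sum())

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(self.positions.copy(), self.velocities.copy(),
                              self.inverse_masses.copy(), self.radius,
                              self.regions.copy())


@dataclass
class ClusterSet:
    """Overlapping shape-matching clusters in flat-array form.

    ``members[offsets[c]:offsets[c+1]]`` are the particle indices of cluster
    ``c``; ``rest_rel`` holds each member's rest position relative to the
    cluster's rest centre of mass.
    """

    members: np.ndarray
    offsets: np.ndarray
    rest_centers: np.ndarray
    rest_rel: np.ndarray
    stiffness: float
    center_particles: np.ndarray | None = None  # FPS seed particle per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.offsets) - 1

    @property
    def cluster_of_member(self) -> np.ndarray:
        counts = np.diff(self.offsets)
        return np.repeat(np.arange(self.n_clusters), counts)

    def memberships_per_particle(self, n_particles: int) -> np.ndarray:
        return np.bincount(self.members, minlength=n_particles)


@dataclass
class SpringSet:
    """Distance constraints: particle index pairs with rest lengths (mm)."""

    pairs: np.ndarray
    rest_lengths: np.ndarray
    stiffness: float

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=np.float64)
        if len(self.pairs):
            if (self.rest_lengths <= 0).any():
                raise ValueError("spring rest lengths must be positive")
            key = np.sort(self.pairs, axis=1)
            if len(np.unique(key, axis=0)) != len(key):
                raise ValueError("duplicate spring pairs")
        _check_stiffness(self.stiffness)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class InflatableSurface:
    """Closed particle surface of the peritoneal boundary.

    ``vertex_particles[k]`` is the particle carrying mesh vertex ``k``;
    the volume target during simulation is ``pressure_factor *
    rest_volume``.
    """

    vertex_particles: np.ndarray
    faces: np.ndarray
    rest_positions: np.ndarray
    rest_volume: float
    pressure_factor: float

    def __post_init__(self):
        if self.rest_volume <= 0:
            raise ValueError("inflatable rest volume must be positive")
        if self.pressure_factor < 0:
            raise ValueError("pressure factor must be non-negative")

    def current_volume(self, positions: np.ndarray) -> float:
        return mesh_volume(positions[self.vertex_particles], self.faces)

    def as_mesh(self, positions: np.ndarray,
                region: str = "inflatable") -> SurfaceMesh:
        return SurfaceMesh(positions[self.vertex_particles].copy(),
                           self.faces.copy(), region)


@dataclass
class SkinBinding:
    """Convex barycentric-style binding of mesh vertices to particles."""

    particle_indices: np.ndarray  # (V, k)
    weights: np.ndarray  # (V, k), rows sum to 1
    rest_particle_positions: np.ndarray  # (N, 3) at bind time


def _check_stiffness(k: float) -> None:
    if not 0.0 < k <= 1.0:
        raise ValueError(f"stiffness must be in (0, 1], got {k}")


def sample_particles(meshes: dict[str, SurfaceMesh], radius: float,
                     volume_sampling_factor: float = 4.0,
                     density: float = 1.05) -> ParticleSystem:
    """Fill closed region meshes with particles on a regular grid.

    The grid spacing is ``radius * (2 / volume_sampling_factor) * 2`` —
    the sampling factor (default 4, i.e. spacing equal to the radius)
    raises particle density as it grows.  Particle mass follows from the
    tissue density and the particle volume.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if volume_sampling_factor <= 0:
        raise ValueError("volume_sampling_factor must be positive")
    h = radius * (2.0 / volume_sampling_factor) * 2.0
    all_pos, all_region = [], []
    for region, mesh in meshes.items():
        if abs(mesh.volume()) < h**3:
            raise ValueError(
                f"region {region!r} is degenerate or thinner than one grid "
                f"cell ({h:.3g} mm): volume {mesh.volume():.3g} mm³")
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        axes = [np.arange(lo[k] + h / 2.0, hi[k], h) for k in range(3)]
        inside = grid_points_in_mesh(mesh.vertices, mesh.faces, *axes)
        idx = np.argwhere(inside)
        if len(idx) == 0:
            raise ValueError(
                f"region {region!r} thinner than one grid cell "
                f"({h:.3g} mm): no interior grid points")
        pts = np.column_stack([axes[k][idx[:, k]] for k in range(3)])
        all_pos.append(pts)
        all_region.append(np.full(len(pts), region))
    positions = np.vstack(all_pos)
    regions = np.concatenate(all_region)
    inv_mass = np.full(len(positions), 1.0 / particle_mass(radius, density))
    return ParticleSystem(positions, np.zeros_like(positions), inv_mass,
                          radius, regions)


def _farthest_point_centers(points: np.ndarray, spacing: float) -> np.ndarray:
    """Deterministic farthest-point sampling until every point lies within
    ``spacing`` of a centre.  Returns centre indices."""
    centers = [0]
    d = np.linalg.norm(points - points[0], axis=1)
    while d.max() > spacing:
        nxt = int(np.argmax(d))  # first max -> deterministic
        centers.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(centers, dtype=np.int64)


def build_clusters(ps: ParticleSystem, spacing_factor: float = 3.33,
                   stiffness: float = 0.6) -> ClusterSet:
    """Overlapping shape-matching clusters per region.

    Cluster centres are farthest-point samples at spacing
    ``spacing_factor * radius``; each cluster contains every same-region
    particle within that spacing, so neighbouring clusters overlap.
    Degenerate clusters (< 4 members) are merged into their nearest
    neighbour cluster.
    """
    _check_stiffness(stiffness)
    if len(ps) == 0:
        raise ValueError("empty particle system")
    if spacing_factor <= 1.0:
        raise ValueError("spacing_factor must exceed 1")
    spacing = spacing_factor * ps.radius
    member_lists: list[np.ndarray] = []
    center_particles: list[int] = []
    for region in np.unique(ps.regions):
        idx = np.flatnonzero(ps.regions == region)
        pts = ps.positions[idx]
        centers = _farthest_point_centers(pts, spacing)
        tree = cKDTree(pts)
        clusters = [np.sort(idx[np.asarray(m, dtype=int)])
                    for m in tree.query_ball_point(pts[centers], spacing)]
        # orphan guard (cannot occur with FPS termination, kept as a safety)
        covered = np.zeros(len(pts), dtype=bool)
        for m in tree.query_ball_point(pts[centers], spacing):
            covered[np.asarray(m, dtype=int)] = True
        if not covered.all():
            _, nearest = cKDTree(pts[centers]).query(pts[~covered])
            for local, c in zip(np.flatnonzero(~covered), nearest):
                clusters[c] = np.sort(np.append(clusters[c], idx[local]))
        # merge tiny clusters into the nearest sizeable one
        region_centers = idx[centers].tolist()
        if len(clusters) > 1:
            big = [k for k, m in enumerate(clusters) if len(m) >= 4]
            if not big:
                clusters = [np.sort(np.unique(np.concatenate(clusters)))]
                region_centers = region_centers[:1]
            else:
                ctr_pts = pts[centers]
                for k, m in enumerate(clusters):
                    if len(m) < 4:
                        d = np.linalg.norm(ctr_pts[big] - ctr_pts[k], axis=1)
                        tgt = big[int(np.argmin(d))]
                        clusters[tgt] = np.sort(
                            np.unique(np.concatenate([clusters[tgt], m])))
                clusters = [clusters[k] for k in big]
                region_centers = [region_centers[k] for k in big]
        member_lists.extend(clusters)
        center_particles.extend(region_centers)

    offsets = np.concatenate([[0], np.cumsum([len(m) for m in member_lists])])
    members = np.concatenate(member_lists) if member_lists else np.empty(0, int)
    rest_centers = np.empty((len(member_lists), 3))
    rest_rel = np.empty((len(members), 3))
    for c, m in enumerate(member_lists):
        com = ps.positions[m].mean(axis=0)
        rest_centers[c] = com
        rest_rel[offsets[c]:offsets[c + 1]] = ps.positions[m] - com
    return ClusterSet(members, offsets.astype(np.int64), rest_centers,
                      rest_rel, stiffness,
                      np.asarray(center_particles, dtype=np.int64))


def build_inflatable(boundary_mesh: SurfaceMesh, pressure_factor: float,
                     density: float = 1.05, radius: float = 2.7,
                     first_particle: int = 0
                     ) -> tuple[ParticleSystem, InflatableSurface]:
    """One particle per boundary-mesh vertex plus the surface record.

    The triangulation is copied; orientation is fixed so the stored rest
    volume is positive.  ``first_particle`` offsets the vertex→particle map
    when the inflatable is appended to an existing system.
    """
    v = boundary_mesh.vertices
    f = boundary_mesh.faces
    vol = mesh_volume(v, f)
    if vol == 0 or not SurfaceMesh(v, f, boundary_mesh.region).is_watertight():
        raise ValueError("inflatable boundary mesh must be closed")
    if vol < 0:  # inward orientation: flip, never store a negative volume
        f = f[:, ::-1].copy()
        vol = -vol
    n = len(v)
    inv_mass = np.full(n, 1.0 / particle_mass(radius, density))
    ps = ParticleSystem(v.copy(), np.zeros((n, 3)), inv_mass, radius,
                        np.full(n, "inflatable"))
    surface = InflatableSurface(
        vertex_particles=np.arange(first_particle, first_particle + n),
        faces=f.copy(), rest_positions=v.copy(), rest_volume=vol,
        pressure_factor=float(pressure_factor))
    return ps, surface


def concat_systems(*systems: ParticleSystem) -> ParticleSystem:
    """Concatenate particle systems (radii must match)."""
    radius = systems[0].radius
    if any(abs(s.radius - radius) > 1e-12 for s in systems):
        raise ValueError("particle radii differ between systems")
    return ParticleSystem(
        np.vstack([s.positions for s in systems]),
        np.vstack([s.velocities for s in systems]),
        np.concatenate([s.inverse_masses for s in systems]),
        radius,
        np.concatenate([s.regions for s in systems]))


def build_surface_springs(surface: InflatableSurface,
                          stiffness: float = 0.5) -> SpringSet:
    """One spring per unique triangulation edge, rest length = rest edge."""
    _check_stiffness(stiffness)
    edges = unique_edges(surface.faces)
    rest = np.linalg.norm(
        surface.rest_positions[edges[:, 0]]
        - surface.rest_positions[edges[:, 1]], axis=1)
    rest = np.maximum(rest, MIN_SPRING_REST_LENGTH)
    pairs = surface.vertex_particles[edges]
    return SpringSet(pairs, rest, stiffness)


def add_connectivity_springs(surface: InflatableSurface,
                             ps: ParticleSystem, max_dist: float,
                             stiffness: float = 0.5,
                             wall_region: str = "wall") -> SpringSet:
    """Tie each inflatable particle to its nearest wall particle.

    Springs are created only within ``max_dist`` (mm); rest length is the
    current separation (floored at the minimum rest length).  An empty
    result is valid and raises a warning, not an error.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    _check_stiffness(stiffness)
    wall_idx = np.flatnonzero(ps.regions == wall_region)
    pairs, rests = [], []
    if len(wall_idx):
        tree = cKDTree(ps.positions[wall_idx])
        d, nearest = tree.query(ps.positions[surface.vertex_particles])
        for k, (dist, nb) in enumerate(zip(d, nearest)):
            if dist <= max_dist:
                pairs.append((surface.vertex_particles[k], wall_idx[nb]))
                rests.append(max(dist, MIN_SPRING_REST_LENGTH))
    if not pairs:
        warnings.warn(
            f"no inflatable-wall pairs within {max_dist} mm; connectivity "
            "spring set is empty", stacklevel=2)
        return SpringSet(np.empty((0, 2), dtype=np.int64), np.empty(0),
                         stiffness)
    return SpringSet(np.asarray(pairs), np.asarray(rests), stiffness)


def fix_back_particles(ps: ParticleSystem, band: float = 3.0,
                       dorsal_axis: int = 1,
                       wall_region: str = "wall") -> int:
    """Pin dorsal wall particles to emulate the operating table.

    Wall particles whose dorso-ventral coordinate lies at least ``band`` mm
    dorsal of the system centre of mass (default: −y dorsal) get inverse
    mass 0 along the whole cranio-caudal extent.  Mutates ``ps`` in place
    and returns the number of particles fixed (idempotent).
    """
    # uniform radius ⇒ uniform mass, so the COM is the plain mean; using the
    # unweighted mean also keeps the operation idempotent after pinning
    com = ps.positions.mean(axis=0)
    threshold = com[dorsal_axis] - band
    select = (ps.regions == wall_region) & (
        ps.positions[:, dorsal_axis] <= threshold)
    ps.inverse_masses[select] = 0.0
    n = int(select.sum())
    if n == 0:
        warnings.warn(
            "no particles fixed: the simulation has no table contact and "
            "may drift", stacklevel=2)
    return n


def bind_skin(mesh: SurfaceMesh, ps: ParticleSystem, k: int = 4,
              region: str | None = "wall") -> SkinBinding:
    """Bind each mesh vertex to its k nearest (wall) particles with
    inverse-distance weights (convex, summing to 1 per vertex)."""
    if len(ps) == 0:
        raise ValueError("empty particle system")
    cand = (np.arange(len(ps)) if region is None
            else np.flatnonzero(ps.regions == region))
    if k > len(cand):
        raise ValueError(f"k={k} exceeds the {len(cand)} candidate particles")
    tree = cKDTree(ps.positions[cand])
    d, nb = tree.query(mesh.vertices, k=k)
    d = np.atleast_2d(d)
    nb = np.atleast_2d(nb)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    coincident = d <= 1e-12
    w[np.any(coincident, axis=1)] = 0.0
    w[coincident] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    return SkinBinding(cand[nb], w, ps.positions.copy())


# --- serialization ----------------------------------------------------------

def save_system(path, ps: ParticleSystem, clusters: ClusterSet | None = None,
                springs: list[SpringSet] | None = None,
                inflatable: InflatableSurface | None = None) -> None:
    """Serialize a particle system and its constraints to a JSON container."""
    doc: dict = {
        "radius": ps.radius,
        "positions": ps.positions.tolist(),
        "velocities": ps.velocities.tolist(),
        "inverse_masses": ps.inverse_masses.tolist(),
        "regions": ps.regions.tolist(),
    }
    if clusters is not None:
        doc["clusters"] = {
            "members": clusters.members.tolist(),
            "offsets": clusters.offsets.tolist(),
            "rest_centers": clusters.rest_centers.tolist(),
            "rest_rel": clusters.rest_rel.tolist(),
            "stiffness": clusters.stiffness,
        }
    if springs:
        doc["springs"] = [{
            "pairs": s.pairs.tolist(),
            "rest_lengths": s.rest_lengths.tolist(),
            "stiffness": s.stiffness,
        } for s in springs]
    if inflatable is not None:
        doc["inflatable"] = {
            "vertex_particles": inflatable.vertex_particles.tolist(),
            "faces": inflatable.faces.tolist(),
            "rest_positions": inflatable.rest_positions.tolist(),
            "rest_volume": inflatable.rest_volume,
            "pressure_factor": inflatable.pressure_factor,
        }
    Path(path).write_text(json.dumps(doc))


def load_system(path):
    """Inverse of :func:`save_system`; returns
    (ParticleSystem, ClusterSet | None, list[SpringSet], InflatableSurface | None)."""
    doc = json.loads(Path(path).read_text())
    ps = ParticleSystem(np.asarray(doc["positions"]),
                        np.asarray(doc["velocities"]),
                        np.asarray(doc["inverse_masses"]),
                        doc["radius"], np.asarray(doc["regions"]))
    clusters = None
    if "clusters" in doc:
        c = doc["clusters"]
        clusters = ClusterSet(np.asarray(c["members"], dtype=np.int64),
                              np.asarray(c["offsets"], dtype=np.int64),
                              np.asarray(c["rest_centers"]),
                              np.asarray(c["rest_rel"]), c["stiffness"])
    springs = [SpringSet(np.asarray(s["pairs"], dtype=np.int64),
                         np.asarray(s["rest_lengths"]), s["stiffness"])
               for s in doc.get("springs", [])]
    inflatable = None
    if "inflatable" in doc:
        i = doc["inflatable"]
        inflatable = InflatableSurface(
            np.asarray(i["vertex_particles"], dtype=np.int64),
            np.asarray(i["faces"], dtype=np.int64),
            np.asarray(i["rest_positions"]), i["rest_volume"],
            i["pressure_factor"])
    return ps, clusters, springs, inflatable
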