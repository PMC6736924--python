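"""Low-level mesh geometry kernels shared across the package.

All routines operate on raw ``(V, 3)`` float vertex arrays and ``(F, 3)``
integer face arrays in millimetres.  They are written against plain
numpy/scipy so behaviour is deterministic and has no optional-dependency
fallbacks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# Deterministic sub-voxel shift used to push ray/edge degeneracies off the
# measure-zero set; irrational so it never aligns with grid or mesh coords.
_EPS_SHIFT = 2.0 ** -21 * np.sqrt(2.0)


def cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis bookkeeping (hot path)."""
    out = np.empty_like(u)
    out[:, 0] = u[:, 1] * v[:, 2] - u[:, 2] * v[:, 1]
    out[:, 1] = u[:, 2] * v[:, 0] - u[:, 0] * v[:, 2]
    out[:, 2] = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    return out


def triple_sum(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    """Σ_rows u · (v × w)."""
    return float((
        u[:, 0] * (v[:, 1] * w[:, 2] - v[:, 2] * w[:, 1])
        + u[:, 1] * (v[:, 2] * w[:, 0] - v[:, 0] * w[:, 2])
        + u[:, 2] * (v[:, 0] * w[:, 1] - v[:, 1] * w[:, 0])).sum())


def mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume of a triangulated surface (divergence theorem).

    Positive for outward-oriented closed surfaces.  Each triangle contributes
    the signed volume of the tetrahedron it spans with the origin.
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces)
    return triple_sum(v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]) / 6.0


def accumulate_rows(n: int, index: np.ndarray, values: np.ndarray
                    ) -> np.ndarray:
    """Scatter-add (M, 3) rows into an (n, 3) array (bincount beats ufunc.at)."""
    out = np.empty((n, 3))
    for a in range(3):
        out[:, a] = np.bincount(index, weights=values[:, a], minlength=n)
    return out


def volume_gradient(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex gradient of the signed volume.

    For vertex i the gradient is the sum over incident triangles of the cross
    product of the opposite edge pair, divided by 6.  The gradients of a closed
    surface sum to zero (the volume is translation invariant).
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = len(v)
    grad = (accumulate_rows(n, f[:, 0], cross3(b, c))
            + accumulate_rows(n, f[:, 1], cross3(c, a))
            + accumulate_rows(n, f[:, 2], cross3(a, b)))
    return grad / 6.0


def unique_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (sorted pairs) of a triangulation."""
    f = np.asarray(faces)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def is_watertight(vertices: np.ndarray, faces: np.ndarray) -> bool:
    """True if every undirected edge is shared by exactly two faces with
    opposite directed orientation (closed, consistently oriented 2-manifold)."""
    f = np.asarray(faces)
    if len(f) == 0:
        return False
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)
    # each directed edge must appear exactly once ...
    _, counts = np.unique(directed, axis=0, return_counts=True)
    if counts.max() != 1:
        return False
    # ... and its reverse exactly once
    und = np.sort(directed, axis=1)
    _, ucounts = np.unique(und, axis=0, return_counts=True)
    return bool((ucounts == 2).all())


def _column_crossings(vertices, faces, xs, ys):
    """For every grid column (xi, yj) find z-values where a vertical ray
    crosses the surface.  Returns flat arrays (col_i, col_j, z_cross)."""
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces)
    xs = np.asarray(xs, dtype=np.float64) + _EPS_SHIFT
    ys = np.asarray(ys, dtype=np.float64) + _EPS_SHIFT * np.sqrt(3.0)

    tri = v[f]  # (F, 3, 3)
    # candidate column index ranges per triangle (half-open)
    txmin, txmax = tri[:, :, 0].min(axis=1), tri[:, :, 0].max(axis=1)
    tymin, tymax = tri[:, :, 1].min(axis=1), tri[:, :, 1].max(axis=1)
    i0 = np.searchsorted(xs, txmin, side="left")
    i1 = np.searchsorted(xs, txmax, side="right")
    j0 = np.searchsorted(ys, tymin, side="left")
    j1 = np.searchsorted(ys, tymax, side="right")
    nx_per = np.maximum(i1 - i0, 0)
    ny_per = np.maximum(j1 - j0, 0)
    counts = nx_per * ny_per
    keep = counts > 0
    if not keep.any():
        return (np.empty(0, int), np.empty(0, int), np.empty(0))

    tri = tri[keep]
    i0k, j0k = i0[keep], j0[keep]
    nxk, nyk = nx_per[keep], ny_per[keep]
    ck = nxk * nyk
    tidx = np.repeat(np.arange(len(tri)), ck)
    # local (col, row) offsets inside each triangle's bbox
    offs = np.arange(ck.sum()) - np.repeat(np.cumsum(ck) - ck, ck)
    ii = i0k[tidx] + offs // nyk[tidx]
    jj = j0k[tidx] + offs % nyk[tidx]

    px, py = xs[ii], ys[jj]
    a, b, c = tri[tidx, 0], tri[tidx, 1], tri[tidx, 2]
    # 2-D barycentric point-in-triangle in the xy plane
    d1x, d1y = b[:, 0] - a[:, 0], b[:, 1] - a[:, 1]
    d2x, d2y = c[:, 0] - a[:, 0], c[:, 1] - a[:, 1]
    qx, qy = px - a[:, 0], py - a[:, 1]
    det = d1x * d2y - d1y * d2x
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (qx * d2y - qy * d2x) / det
        w = (d1x * qy - d1y * qx) / det
        hit = (np.abs(det) > 0) & (u >= 0) & (w >= 0) & (u + w <= 1)
    if not hit.any():
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    u, w = u[hit], w[hit]
    zc = (
        a[hit][:, 2]
        + u * (b[hit][:, 2] - a[hit][:, 2])
        + w * (c[hit][:, 2] - a[hit][:, 2])
    )
    return ii[hit], jj[hit], zc


def grid_points_in_mesh(vertices, faces, xs, ys, zs) -> np.ndarray:
    """Boolean occupancy of the grid ``xs × ys × zs`` inside a closed surface.

    Uses vertical-ray crossing parity per grid column; robust to multi-shell
    surfaces (e.g. a thick wall whose boundary has two components).
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    zs = np.asarray(zs, dtype=np.float64)
    ii, jj, zc = _column_crossings(vertices, faces, xs, ys)
    nz = len(zs)
    # crossings strictly above z_k toggle parity for that sample
    counts = np.zeros((len(xs), len(ys), nz + 1), dtype=np.int32)
    kbin = np.searchsorted(zs + _EPS_SHIFT * np.sqrt(5.0), zc, side="left")
    np.add.at(counts, (ii, jj, kbin), 1)
    # number of crossings above sample k = total in bins > k
    above = np.cumsum(counts[:, :, ::-1], axis=2)[:, :, ::-1]
    return (above[:, :, 1:] % 2) == 1


def points_in_mesh(vertices, faces, points) -> np.ndarray:
    """Ray-parity inside test for an arbitrary point set (closed surface)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        return np.zeros(0, dtype=bool)
    # Reuse the column machinery: treat each unique (x, y) as a column.
    xy, inv = np.unique(pts[:, :2], axis=0, return_inverse=True)
    inside = np.zeros(len(pts), dtype=bool)
    # group points per column via sorted crossings
    ii, jj, zc = _column_crossings(
        vertices, faces, np.sort(np.unique(xy[:, 0])), np.sort(np.unique(xy[:, 1]))
    )
    ux = np.sort(np.unique(xy[:, 0]))
    uy = np.sort(np.unique(xy[:, 1]))
    col_of_point = np.searchsorted(ux, pts[:, 0]) * len(uy) + np.searchsorted(
        uy, pts[:, 1]
    )
    col_of_cross = ii * len(uy) + jj
    order = np.argsort(col_of_cross, kind="stable")
    col_of_cross, zc = col_of_cross[order], zc[order]
    starts = np.searchsorted(col_of_cross, col_of_point, side="left")
    ends = np.searchsorted(col_of_cross, col_of_point, side="right")
    for k in range(len(pts)):
        zvals = zc[starts[k] : ends[k]]
        inside[k] = (np.count_nonzero(zvals > pts[k, 2] + _EPS_SHIFT) % 2) == 1
    return inside


def _point_triangle_distance(points, tri_a, tri_b, tri_c):
    """Exact distance from each point to its paired triangle (vectorized).

    Classic barycentric-region closest-point-on-triangle (Ericson),
    branch-free via np.where.
    """
    p = points
    a, b, c = tri_a, tri_b, tri_c
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where((d1 - d3) != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where(((d4 - d3) + (d5 - d6)) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v_in = vb / denom
        w_in = vc / denom

    closest = a + v_in[:, None] * ab + w_in[:, None] * ac  # interior default
    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, closest)
    # edge AB
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + np.clip(v_ab, 0, 1)[:, None] * ab, closest)
    # edge AC
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + np.clip(w_ac, 0, 1)[:, None] * ac, closest)
    # edge BC
    on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    closest = np.where(
        on_bc[:, None], b + np.clip(w_bc, 0, 1)[:, None] * (c - b), closest
    )
    return np.linalg.norm(p - closest, axis=1), closest


def closest_point_distances(vertices, faces, points) -> np.ndarray:
    """Distance from each query point to the nearest point on the surface.

    KD-tree on triangle centroids prunes candidates; the nearest-vertex
    distance gives a certified upper bound, so every triangle that could beat
    it is examined exactly.
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = v[f]
    cent = tri.mean(axis=1)
    # farthest vertex from centroid per triangle: any triangle whose centroid
    # is farther than bound + its own spread cannot contain a closer point
    spread = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    max_spread = float(spread.max())
    vert_tree = cKDTree(v)
    cent_tree = cKDTree(cent)
    ub, _ = vert_tree.query(pts)
    out = np.empty(len(pts))
    for k, p in enumerate(pts):
        cand = cent_tree.query_ball_point(p, ub[k] + max_spread + 1e-12)
        cand = np.asarray(cand, dtype=int)
        if len(cand) == 0:  # nearest vertex is the answer
            out[k] = ub[k]
            continue
        d, _ = _point_triangle_distance(
            np.repeat(p[None, :], len(cand), axis=0),
            tri[cand, 0],
            tri[cand, 1],
            tri[cand, 2],
        )
        out[k] = d.min()
    return out
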