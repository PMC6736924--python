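"""Quadric error-metric edge-collapse decimation for closed triangle meshes.

Garland–Heckbert style: every vertex carries the sum of squared-distance
quadrics of its incident face planes (area weighted); edges are collapsed
cheapest-first into the position minimizing the combined quadric, until the
requested face count is reached exactly (each interior collapse on a closed
manifold removes exactly two faces, and closed manifolds always have an even
face count, so any even target is reachable).

Collapses that would break the mesh are rejected:

* link condition — the endpoints may share exactly the two opposite vertices
  of the collapsed edge, otherwise the result is non-manifold;
* normal flip / degeneracy — no surviving incident face may invert its
  orientation or lose its area.

Pure Python with flat-float quadrics; no third-party decimation backend.
"""

from __future__ import annotations

import heapq

import numpy as np

_DEGENERATE_AREA = 1e-14


def _face_quadric(pa, pb, pc):
    """Area-weighted plane quadric of one face as a flat 10-tuple
    (a11,a12,a13,a22,a23,a33,b1,b2,b3,c) for cost = xᵀAx + 2bᵀx + c."""
    e1x, e1y, e1z = pb[0] - pa[0], pb[1] - pa[1], pb[2] - pa[2]
    e2x, e2y, e2z = pc[0] - pa[0], pc[1] - pa[1], pc[2] - pa[2]
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    norm2 = nx * nx + ny * ny + nz * nz
    if norm2 < _DEGENERATE_AREA:
        return (0.0,) * 10
    norm = norm2 ** 0.5
    area = 0.5 * norm
    nx, ny, nz = nx / norm, ny / norm, nz / norm
    d = -(nx * pa[0] + ny * pa[1] + nz * pa[2])
    return (
        area * nx * nx, area * nx * ny, area * nx * nz,
        area * ny * ny, area * ny * nz, area * nz * nz,
        area * nx * d, area * ny * d, area * nz * d, area * d * d,
    )


def _qadd(q, r):
    return tuple(a + b for a, b in zip(q, r))


def _qcost(q, x, y, z):
    a11, a12, a13, a22, a23, a33, b1, b2, b3, c = q
    return (
        x * (a11 * x + 2 * a12 * y + 2 * a13 * z + 2 * b1)
        + y * (a22 * y + 2 * a23 * z + 2 * b2)
        + z * (a33 * z + 2 * b3)
        + c
    )


def _optimal_point(q, pu, pv):
    """Minimizer of the quadric, regularized toward the edge midpoint.

    Solving (A + εI) x = −b + ε·m keeps the optimal position along the
    quadric's strong (normal) directions while pinning weakly constrained
    (tangential, for near-planar neighbourhoods) directions to the
    midpoint — a bare solve is near-singular there and a midpoint
    fallback systematically shrinks curved surfaces."""
    a11, a12, a13, a22, a23, a33, b1, b2, b3, _ = q
    mx = (pu[0] + pv[0]) / 2
    my = (pu[1] + pv[1]) / 2
    mz = (pu[2] + pv[2]) / 2
    eps = 1e-6 * (a11 + a22 + a33) + 1e-300
    a11 += eps
    a22 += eps
    a33 += eps
    rx, ry, rz = -b1 + eps * mx, -b2 + eps * my, -b3 + eps * mz
    det = (a11 * (a22 * a33 - a23 * a23)
           - a12 * (a12 * a33 - a23 * a13)
           + a13 * (a12 * a23 - a22 * a13))
    if det == 0.0:
        return min((pu, pv, (mx, my, mz)), key=lambda p: _qcost(q, *p))
    x = (rx * (a22 * a33 - a23 * a23)
         - a12 * (ry * a33 - a23 * rz)
         + a13 * (ry * a23 - a22 * rz)) / det
    y = (a11 * (ry * a33 - rz * a23)
         - rx * (a12 * a33 - a23 * a13)
         + a13 * (a12 * rz - ry * a13)) / det
    z = (a11 * (a22 * rz - ry * a23)
         - a12 * (a12 * rz - ry * a13)
         + rx * (a12 * a23 - a22 * a13)) / det
    return (x, y, z)


def _face_normal(pa, pb, pc):
    e1x, e1y, e1z = pb[0] - pa[0], pb[1] - pa[1], pb[2] - pa[2]
    e2x, e2y, e2z = pc[0] - pa[0], pc[1] - pa[1], pc[2] - pa[2]
    return (e1y * e2z - e1z * e2y, e1z * e2x - e1x * e2z, e1x * e2y - e1y * e2x)


def quadric_decimate(vertices: np.ndarray, faces: np.ndarray,
                     target_faces: int) -> tuple[np.ndarray, np.ndarray]:
    """Collapse edges of a closed triangle mesh until ``target_faces`` remain.

    Returns new (vertices, faces).  Raises ``ValueError`` if the target cannot
    be reached (all remaining collapses would damage the mesh).
    """
    pos = [tuple(map(float, p)) for p in np.asarray(vertices, dtype=np.float64)]
    fcs = [tuple(map(int, f)) for f in np.asarray(faces)]
    nf_alive = len(fcs)
    if target_faces == nf_alive:
        return (np.asarray(vertices, dtype=np.float64).copy(),
                np.asarray(faces).copy())
    if target_faces % 2 != 0:
        raise ValueError("closed meshes have even face counts; "
                         f"target {target_faces} unreachable")

    face_alive = [True] * len(fcs)
    vfaces: list[set[int]] = [set() for _ in pos]
    for fi, (a, b, c) in enumerate(fcs):
        vfaces[a].add(fi)
        vfaces[b].add(fi)
        vfaces[c].add(fi)

    quadric = [(0.0,) * 10] * len(pos)
    for fi, (a, b, c) in enumerate(fcs):
        fq = _face_quadric(pos[a], pos[b], pos[c])
        quadric[a] = _qadd(quadric[a], fq)
        quadric[b] = _qadd(quadric[b], fq)
        quadric[c] = _qadd(quadric[c], fq)

    stamp = [0] * len(pos)

    def neighbors(u):
        out = set()
        for fi in vfaces[u]:
            out.update(fcs[fi])
        out.discard(u)
        return out

    def push(heap, u, v):
        if u > v:
            u, v = v, u
        q = _qadd(quadric[u], quadric[v])
        p = _optimal_point(q, pos[u], pos[v])
        heapq.heappush(heap, (_qcost(q, *p), u, v, stamp[u], stamp[v], p))

    heap: list = []
    seen = set()
    for a, b, c in fcs:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            if key not in seen:
                seen.add(key)
                push(heap, *key)
    del seen

    # edges rejected by the manifold/flip guards are parked rather than
    # dropped: later collapses can make them valid again, so they are
    # re-queued whenever progress has been made since the heap drained
    blocked: list = []
    progressed = False
    while nf_alive > target_faces:
        if not heap:
            if blocked and progressed:
                for u, v in blocked:
                    if stamp[u] >= 0 and vfaces[u] and vfaces[v]:
                        push(heap, u, v)
                blocked.clear()
                progressed = False
                continue
            raise ValueError(
                f"decimation stalled at {nf_alive} faces before reaching "
                f"{target_faces}: remaining collapses would break the mesh")
        cost, u, v, su, sv, p = heapq.heappop(heap)
        if su != stamp[u] or sv != stamp[v]:
            continue  # stale entry
        shared = vfaces[u] & vfaces[v]
        if len(shared) != 2:
            continue  # edge gone or non-manifold here
        # link condition: common vertex neighbors must be exactly the two
        # vertices opposite the edge
        opposite = set()
        for fi in shared:
            for w in fcs[fi]:
                if w != u and w != v:
                    opposite.add(w)
        if neighbors(u) & neighbors(v) != opposite or len(opposite) != 2:
            blocked.append((u, v))
            continue
        # normal-flip / degeneracy guard on all surviving faces
        ok = True
        for fi in (vfaces[u] | vfaces[v]) - shared:
            a, b, c = fcs[fi]
            pa, pb, pc = pos[a], pos[b], pos[c]
            n0 = _face_normal(pa, pb, pc)
            qa = p if a in (u, v) else pa
            qb = p if b in (u, v) else pb
            qc = p if c in (u, v) else pc
            n1 = _face_normal(qa, qb, qc)
            dot = n0[0] * n1[0] + n0[1] * n1[1] + n0[2] * n1[2]
            a1 = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
            if dot <= 0.0 or a1 < _DEGENERATE_AREA:
                ok = False
                break
        if not ok:
            blocked.append((u, v))
            continue

        # commit: merge v into u at position p
        progressed = True
        pos[u] = p
        quadric[u] = _qadd(quadric[u], quadric[v])
        for fi in shared:
            face_alive[fi] = False
            nf_alive -= 1
            for w in fcs[fi]:
                vfaces[w].discard(fi)
        for fi in list(vfaces[v]):
            a, b, c = fcs[fi]
            fcs[fi] = (u if a == v else a, u if b == v else b, u if c == v else c)
            vfaces[v].discard(fi)
            vfaces[u].add(fi)
        vfaces[v] = set()
        # only u's quadric and position changed: invalidate and re-push its
        # incident edges (topology validity is re-checked at pop time)
        stamp[u] += 1
        stamp[v] += 1
        for x in neighbors(u):
            push(heap, u, x)

    new_index = {}
    out_faces = []
    for fi, alive in enumerate(face_alive):
        if not alive:
            continue
        tri = []
        for w in fcs[fi]:
            if w not in new_index:
                new_index[w] = len(new_index)
            tri.append(new_index[w])
        out_faces.append(tri)
    out_vertices = np.empty((len(new_index), 3), dtype=np.float64)
    for old, new in new_index.items():
        out_vertices[new] = pos[old]
    return out_vertices, np.asarray(out_faces, dtype=np.int64)
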