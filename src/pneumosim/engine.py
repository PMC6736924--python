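"""Position-based dynamics solver for the insufflation simulation.

Each frame is split into substeps (collision detection happens once per
substep); each substep predicts positions from damped velocities, then
runs a fixed number of constraint-projection iterations in a fixed
order — shape-matching clusters, springs, the inflatable volume target,
inter-region particle collisions — and finally rebuilds velocities from
the positional change.  Constraints move positions directly, which is
what gives the scheme its unconditional stability: a projection can
only move particles toward constraint satisfaction, never integrate an
unbounded force.

Within one constraint group, corrections are accumulated Jacobi-style
and relaxed "locally": overlapping corrections on a particle are
averaged by participation count.  The averaging divisor is shared
across each constraint's members (the mean of their counts), so every
single constraint's corrections still cancel exactly and the projection
conserves linear momentum to floating-point precision — with gravity
off and nothing pinned, the centre of mass stays put.

Stiffness values k ∈ (0, 1] are iteration-corrected to
k′ = 1 − (1 − k)^(1/n) for n solver iterations, so a configured
stiffness means the same effective stiffness regardless of iteration
count.

The static post-insufflation state is the quantity of interest;
dynamics en route are damped heavily and not claimed to be physical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import (accumulate_rows, mesh_volume, triple_sum,
                        volume_gradient)
from .discretize import (ClusterSet, InflatableSurface, ParticleSystem,
                         SkinBinding, SpringSet)
from .imaging import SurfaceMesh

__all__ = [
    "SimulationSettings", "EquilibriumCriteria", "SimulationState",
    "EquilibriumReport", "mesh_volume", "predict", "project_clusters",
    "project_springs", "project_volume", "project_collisions", "step",
    "simulate_to_equilibrium", "deform_skin",
]


@dataclass
class SimulationSettings:
    """Solver settings; the defaults are the calibration settings.

    time_step s; gravity mm/s²; damping_factor 1/s (per-second velocity
    attenuation, clamped so velocities can only shrink); friction
    coefficients dimensionless.  ``shape_friction`` applies to contacts
    against pinned (table) particles, ``particle_friction`` between free
    particles.
    """

    time_step: float = 1.0 / 60.0
    substeps: int = 3
    iterations_per_substep: int = 9
    gravity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    damping_factor: float = 12.0
    shape_friction: float = 0.35
    particle_friction: float = 0.25
    relaxation_factor: float = 1.0
    tissue_density: float = 1.05  # g/cm³

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.substeps < 1 or self.iterations_per_substep < 1:
            raise ValueError("substeps and iterations must be >= 1")
        for name in ("shape_friction", "particle_friction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.gravity = tuple(float(g) for g in np.broadcast_to(
            np.asarray(self.gravity, dtype=float), (3,)))

    def corrected_stiffness(self, k: float) -> float:
        """k′ = 1 − (1 − k)^(1/n): per-iteration stiffness whose n-fold
        application equals the configured stiffness."""
        n = self.iterations_per_substep
        return 1.0 - (1.0 - k) ** (1.0 / n)


@dataclass
class EquilibriumCriteria:
    """Static-equilibrium detection: the largest per-frame particle
    displacement must stay below ``tolerance`` (mm) for ``window``
    consecutive frames.  ``tolerance=None`` resolves to 10⁻³ × radius."""

    tolerance: float | None = None
    window: int = 30
    max_frames: int = 3000

    def resolve_tolerance(self, radius: float) -> float:
        tol = 1e-3 * radius if self.tolerance is None else self.tolerance
        if tol <= 0 or self.window <= 0 or self.max_frames <= 0:
            raise ValueError("equilibrium criteria must be positive")
        return tol


@dataclass
class SimulationState:
    """Everything the solver advances.

    ``contact_rest`` is a sorted (pair-key, rest-distance) table of
    inter-region pairs that already sit closer than the collision
    diameter in the rest configuration — a discretization artifact of
    adjacent region layers, not a real contact.  Those pairs are exempt
    from collision response (the analogue of collision filters/phases in
    particle engines): without the exemption the rest state itself is
    massively infeasible and the solver cannot settle.  Genuinely new
    contacts still repel at two radii.
    """

    ps: ParticleSystem
    clusters: ClusterSet | None = None
    springs: list[SpringSet] = field(default_factory=list)
    inflatable: InflatableSurface | None = None
    contact_rest: tuple[np.ndarray, np.ndarray] | None = None
    frame: int = 0
    last_max_displacement: float = np.inf
    _substep_prev: np.ndarray | None = None  # positions at substep start
    _collision_pairs: np.ndarray | None = None

    def inflatable_volume_ratio(self) -> float | None:
        if self.inflatable is None:
            return None
        return (self.inflatable.current_volume(self.ps.positions)
                / self.inflatable.rest_volume)


@dataclass
class EquilibriumReport:
    converged: bool
    frames: int
    final_max_displacement: float
    volume_ratio: float | None = None


def predict(state: SimulationState, settings: SimulationSettings,
            dt: float | None = None) -> np.ndarray:
    """Damped explicit prediction; updates velocities in place and returns
    the predicted positions (fixed particles do not move).

    v ← (1 − min(1, damping·dt)) · (v + g·dt);  x* ← x + v·dt
    """
    ps = state.ps
    dt = settings.time_step if dt is None else dt
    keep = 1.0 - min(1.0, settings.damping_factor * dt)
    free = (ps.inverse_masses > 0)[:, None]
    ps.velocities = np.where(
        free, keep * (ps.velocities + np.asarray(settings.gravity) * dt), 0.0)
    return np.where(free, ps.positions + ps.velocities * dt, ps.positions)


def _shared_divisors(counts: np.ndarray, index_groups: np.ndarray,
                     group_ids: np.ndarray, n_groups: int) -> np.ndarray:
    """Largest participation count per constraint, shared across its members.

    Sharing one divisor per constraint keeps that constraint's corrections
    summing to zero (momentum conservation); taking the max of the member
    counts makes the accumulated correction on any particle at most one
    full constraint correction, so the averaged projection never
    over-corrects (gain ≤ 1 — a mean divisor can exceed 1 on particles
    with asymmetric participation and sustain a period-2 limit cycle)."""
    out = np.ones(n_groups)
    np.maximum.at(out, group_ids, counts[index_groups])
    return out


def project_clusters(state: SimulationState,
                     settings: SimulationSettings | None = None
                     ) -> np.ndarray:
    """Shape-matching correction toward each cluster's best rigid fit.

    Per cluster, the optimal rotation of the rest shape onto the current
    member positions comes from the polar decomposition (via SVD, with the
    reflection removed) of the moment matrix; members are pulled a
    stiffness fraction of the way to their goal positions.  Overlapping
    corrections are averaged with a per-cluster shared divisor.
    """
    cs = state.clusters
    if cs is None or cs.n_clusters == 0:
        return np.zeros_like(state.ps.positions)
    settings = settings or SimulationSettings()
    x = state.ps.positions
    members = cs.members
    nc = cs.n_clusters
    # static per-cluster arrays, cached on first use
    cache = getattr(cs, "_solver_cache", None)
    if cache is None:
        cid = cs.cluster_of_member
        sizes = np.diff(cs.offsets).astype(np.float64)
        counts = np.bincount(members, minlength=len(x)).astype(np.float64)
        div = _shared_divisors(counts, members, cid, nc)
        cache = (cid, sizes, div[cid][:, None])
        cs._solver_cache = cache
    cid, sizes, inv_div = cache

    xm = x[members]
    com = np.empty((nc, 3))
    for a in range(3):
        com[:, a] = np.bincount(cid, weights=xm[:, a], minlength=nc) / sizes
    xc = xm - com[cid]
    q = cs.rest_rel
    # moment matrix A_c = Σ (x_i − com) q_iᵀ, batched over clusters
    A = np.empty((nc, 3, 3))
    for a in range(3):
        for b in range(3):
            A[:, a, b] = np.bincount(cid, weights=xc[:, a] * q[:, b],
                                     minlength=nc)
    U, S, Vt = np.linalg.svd(A)
    # remove reflections so R is a proper rotation
    det = np.linalg.det(U @ Vt)
    U[:, :, 2] *= np.sign(det)[:, None]
    R = U @ Vt
    # near-collinear clusters (rank < 2): no well-defined rotation
    degenerate = S[:, 1] <= 1e-12 * (S[:, 0] + 1e-300)
    R[degenerate] = np.eye(3)

    goal = com[cid] + np.einsum("cij,cj->ci", R[cid], q)
    kp = settings.corrected_stiffness(cs.stiffness)
    delta = kp * (goal - xm) / inv_div
    return accumulate_rows(len(x), members, delta)


def project_springs(state: SimulationState,
                    settings: SimulationSettings | None = None
                    ) -> np.ndarray:
    """Distance-constraint projection for every spring set.

    Corrections act along the pair axis, are split by inverse mass, scaled
    by the iteration-corrected stiffness, and averaged with per-spring
    shared divisors.  Coincident endpoints are skipped this iteration.
    """
    settings = settings or SimulationSettings()
    x = state.ps.positions
    w = state.ps.inverse_masses
    corr = np.zeros_like(x)
    for ss in state.springs:
        if len(ss) == 0:
            continue
        i, j = ss.pairs[:, 0], ss.pairs[:, 1]
        d = x[j] - x[i]
        L = np.linalg.norm(d, axis=1)
        ok = L > 1e-12
        wsum = w[i] + w[j]
        ok &= wsum > 0
        if not ok.any():
            continue
        kp = settings.corrected_stiffness(ss.stiffness)
        n = np.zeros_like(d)
        n[ok] = d[ok] / L[ok][:, None]
        C = np.where(ok, L - ss.rest_lengths, 0.0)
        scale = np.where(ok, C / np.maximum(wsum, 1e-300), 0.0) * kp

        div = getattr(ss, "_div_cache", None)
        if div is None:
            counts = np.bincount(ss.pairs.ravel(), minlength=len(x)
                                 ).astype(np.float64)
            div = np.maximum(counts[i], counts[j])
            ss._div_cache = div
        di = (w[i] * scale / div)[:, None] * n
        dj = -(w[j] * scale / div)[:, None] * n
        corr += accumulate_rows(len(x), i, di)
        corr += accumulate_rows(len(x), j, dj)
    return corr


def project_volume(state: SimulationState,
                   settings: SimulationSettings | None = None) -> np.ndarray:
    """Project the inflatable's volume constraint C(x) = V(x) − p·V₀.

    Δx_i = −w_i λ ∇_iC with λ = C / Σ_j w_j |∇_jC|²; the per-vertex volume
    gradient is the summed cross product of opposite edge pairs over
    incident triangles.  The gradients of a closed surface sum to zero, so
    the projection never shifts the centre of mass.
    """
    surf = state.inflatable
    corr = np.zeros_like(state.ps.positions)
    if surf is None:
        return corr
    x = state.ps.positions
    w = state.ps.inverse_masses
    idx = surf.vertex_particles
    V = mesh_volume(x[idx], surf.faces)
    C = V - surf.pressure_factor * surf.rest_volume
    grad = volume_gradient(x[idx], surf.faces)
    denom = float((w[idx] * (grad * grad).sum(axis=1)).sum())
    if denom <= 0.0:
        warnings.warn("all inflatable particles are fixed; volume "
                      "constraint skipped", stacklevel=2)
        return corr
    lam = C / denom
    delta = -(w[idx] * lam)[:, None] * grad
    # The constraint is cubic along the step direction, so the raw Newton
    # step over- or undershoots; a line search lands each step exactly on
    # the target volume, which keeps the inflation a single smooth
    # displacement instead of an oscillation that churns the surface.
    # V(x + s·delta) is an exact cubic in s whose coefficients are scalar
    # triple products over the faces, so the search is closed-form cheap.
    # Scaling the whole step uniformly keeps the zero-sum property of the
    # corrections, so momentum conservation is untouched.
    f = surf.faces
    xs = x[idx]
    a, b, c = xs[f[:, 0]], xs[f[:, 1]], xs[f[:, 2]]
    da, db, dc = delta[f[:, 0]], delta[f[:, 1]], delta[f[:, 2]]
    c1 = (triple_sum(da, b, c) + triple_sum(a, db, c)
          + triple_sum(a, b, dc)) / 6.0
    c2 = (triple_sum(da, db, c) + triple_sum(da, b, dc)
          + triple_sum(a, db, dc)) / 6.0
    c3 = triple_sum(da, db, dc) / 6.0

    def residual(s: float) -> float:  # V(x + s·delta) − target, exact
        return C + s * (c1 + s * (c2 + s * c3))

    if residual(1.0) * C < 0:
        # full step would cross the target: bisect the cubic to land on it
        lo_s, hi_s = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo_s + hi_s)
            if residual(mid) * C > 0:
                lo_s = mid
            else:
                hi_s = mid
        delta *= 0.5 * (lo_s + hi_s)
    corr[idx] = delta
    return corr


def _pair_keys(pairs: np.ndarray, n: int) -> np.ndarray:
    lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
    hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
    return lo * n + hi


def collision_pairs(ps: ParticleSystem,
                    exempt_keys: np.ndarray | None = None) -> np.ndarray:
    """Inter-region particle candidate pairs (deterministic lexicographic
    order), via a KD-tree at cell size 2·radius.

    A 10% detection margin keeps pairs sitting exactly at the contact
    distance in the candidate set between substeps (response only acts on
    actual penetration), which prevents contact-set flicker cycles.
    Pairs whose key appears in ``exempt_keys`` (sorted) are dropped."""
    tree = cKDTree(ps.positions)
    pairs = tree.query_pairs(2.2 * ps.radius, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    differ = ps.regions[pairs[:, 0]] != ps.regions[pairs[:, 1]]
    pairs = pairs[differ]
    if exempt_keys is not None and len(exempt_keys) and len(pairs):
        keys = _pair_keys(pairs, len(ps))
        pos = np.minimum(np.searchsorted(exempt_keys, keys),
                         len(exempt_keys) - 1)
        pairs = pairs[exempt_keys[pos] != keys]
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def rest_contact_table(ps: ParticleSystem
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(sorted pair keys, rest distances) of inter-region pairs closer than
    the collision diameter at rest.

    Adjacent region layers are closer than two radii purely by
    discretization; colliding those pairs at their rest distance keeps the
    rest state feasible while forbidding any further interpenetration."""
    pairs = collision_pairs(ps)
    if len(pairs) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0))
    d = np.linalg.norm(ps.positions[pairs[:, 0]] - ps.positions[pairs[:, 1]],
                       axis=1)
    close = d < 2.0 * ps.radius
    keys = _pair_keys(pairs[close], len(ps))
    order = np.argsort(keys)
    return keys[order], np.maximum(d[close][order], 1e-6)


def project_collisions(state: SimulationState,
                       settings: SimulationSettings | None = None,
                       pairs: np.ndarray | None = None) -> np.ndarray:
    """Separate overlapping inter-region particles to two radii apart.

    Normal corrections are inverse-mass weighted; tangential relative
    displacement accumulated since the substep start is removed up to a
    Coulomb-style bound (μ × penetration depth), with the shape-friction
    coefficient for contacts against pinned particles and the particle
    friction coefficient otherwise.
    """
    settings = settings or SimulationSettings()
    ps = state.ps
    corr = np.zeros_like(ps.positions)
    if pairs is None:
        pairs = (state._collision_pairs if state._collision_pairs is not None
                 else collision_pairs(ps))
    if len(pairs) == 0:
        return corr
    x = ps.positions
    w = ps.inverse_masses
    i, j = pairs[:, 0], pairs[:, 1]
    d = x[j] - x[i]
    L = np.linalg.norm(d, axis=1)
    pen = 2.0 * ps.radius - L
    active = (pen > 0) & (L > 1e-12) & ((w[i] + w[j]) > 0)
    if not active.any():
        return corr
    i, j, d, L, pen = i[active], j[active], d[active], L[active], pen[active]
    n = d / L[:, None]
    wsum = w[i] + w[j]
    push = pen / wsum

    counts = np.bincount(np.concatenate([i, j]), minlength=len(x)
                         ).astype(np.float64)
    div = np.maximum(counts[i], counts[j])

    di = -(w[i] * push / div)[:, None] * n
    dj = (w[j] * push / div)[:, None] * n

    if state._substep_prev is not None:
        mu = np.where((w[i] == 0) | (w[j] == 0),
                      settings.shape_friction, settings.particle_friction)
        rel = ((x[i] - state._substep_prev[i])
               - (x[j] - state._substep_prev[j]))
        tang = rel - (np.einsum("ij,ij->i", rel, n))[:, None] * n
        tnorm = np.linalg.norm(tang, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(tnorm < mu * pen, 1.0,
                             np.minimum(mu * pen / np.where(tnorm > 0, tnorm,
                                                            1.0), 1.0))
        f = tang * scale[:, None]
        di -= (w[i] / wsum / div)[:, None] * f
        dj += (w[j] / wsum / div)[:, None] * f

    corr += accumulate_rows(len(x), i, di)
    corr += accumulate_rows(len(x), j, dj)
    return corr


_GROUPS = (project_clusters, project_springs, project_volume,
           project_collisions)


def step(state: SimulationState, settings: SimulationSettings | None = None
         ) -> SimulationState:
    """Advance one frame: per substep, predict then iterate the constraint
    groups in fixed order (clusters → springs → volume → collisions), then
    rebuild velocities.  Fixed particles never move.  Raises on non-finite
    positions with frame diagnostics."""
    settings = settings or SimulationSettings()
    ps = state.ps
    dt_sub = settings.time_step / settings.substeps
    free = (ps.inverse_masses > 0)[:, None]
    x_frame = ps.positions.copy()
    for _ in range(settings.substeps):
        xprev = ps.positions.copy()
        state._substep_prev = xprev
        ps.positions = predict(state, settings, dt=dt_sub)
        if not np.isfinite(ps.positions).all():
            bad = int(np.flatnonzero(
                ~np.isfinite(ps.positions).all(axis=1))[0])
            raise FloatingPointError(
                f"non-finite particle positions at frame {state.frame + 1} "
                f"(first bad particle {bad}, region {ps.regions[bad]!r})")
        state._collision_pairs = collision_pairs(
            ps, state.contact_rest[0] if state.contact_rest else None)
        for _ in range(settings.iterations_per_substep):
            for group in _GROUPS:
                corr = group(state, settings)
                ps.positions = ps.positions + np.where(
                    free, settings.relaxation_factor * corr, 0.0)
        ps.velocities = np.where(free, (ps.positions - xprev) / dt_sub, 0.0)
        # CFL-style limiter for the quasi-static solve: velocities rebuilt
        # from constraint travel may not advect particles farther than half
        # a radius per substep (uniform scaling preserves total momentum)
        vmax = 0.5 * ps.radius / dt_sub
        vpeak = float(np.linalg.norm(ps.velocities, axis=1).max(initial=0.0))
        if vpeak > vmax:
            ps.velocities *= vmax / vpeak
    state._substep_prev = None
    state._collision_pairs = None
    if not np.isfinite(ps.positions).all():
        bad = int(np.flatnonzero(~np.isfinite(ps.positions).all(axis=1))[0])
        raise FloatingPointError(
            f"non-finite particle positions at frame {state.frame + 1} "
            f"(first bad particle {bad}, region {ps.regions[bad]!r})")
    state.frame += 1
    state.last_max_displacement = float(
        np.linalg.norm(ps.positions - x_frame, axis=1).max())
    return state


def simulate_to_equilibrium(state: SimulationState,
                            settings: SimulationSettings | None = None,
                            criteria: EquilibriumCriteria | None = None,
                            frame_log=None, on_frame=None
                            ) -> tuple[SimulationState, EquilibriumReport]:
    """Step until the per-frame max displacement stays below tolerance for
    a full window of frames, or until the frame cap.

    Non-convergence is reported in the flag, never raised.  ``frame_log``
    (a path) receives per-frame CSV diagnostics (frame, max displacement,
    inflatable volume); ``on_frame(state)`` is called after every frame
    (e.g. to write mesh snapshots)."""
    settings = settings or SimulationSettings()
    criteria = criteria or EquilibriumCriteria()
    tol = criteria.resolve_tolerance(state.ps.radius)
    quiet = 0
    frames = 0
    log_fh = open(frame_log, "w") if frame_log is not None else None
    if log_fh:
        log_fh.write("frame,max_displacement_mm,inflatable_volume_mm3\n")
    try:
        while frames < criteria.max_frames:
            step(state, settings)
            frames += 1
            if log_fh:
                vol = (state.inflatable.current_volume(state.ps.positions)
                       if state.inflatable is not None else float("nan"))
                log_fh.write(f"{state.frame},"
                             f"{state.last_max_displacement:.9g},{vol:.9g}\n")
            if on_frame is not None:
                on_frame(state)
            quiet = quiet + 1 if state.last_max_displacement < tol else 0
            if quiet >= criteria.window:
                break
    finally:
        if log_fh:
            log_fh.close()
    converged = quiet >= criteria.window
    return state, EquilibriumReport(
        converged=converged, frames=frames,
        final_max_displacement=state.last_max_displacement,
        volume_ratio=state.inflatable_volume_ratio())


def deform_skin(binding: SkinBinding, state: SimulationState,
                mesh: SurfaceMesh) -> SurfaceMesh:
    """Carry a surface mesh along with its bound particles.

    Each vertex moves by the convex-weighted average of its bound
    particles' displacements since bind time."""
    if len(binding.rest_particle_positions) != len(state.ps):
        raise ValueError("binding was built against a different particle "
                         "system (particle count mismatch)")
    disp = state.ps.positions - binding.rest_particle_positions
    vdisp = np.einsum("vk,vkj->vj", binding.weights,
                      disp[binding.particle_indices])
    return SurfaceMesh(mesh.vertices + vdisp, mesh.faces.copy(), mesh.region)
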