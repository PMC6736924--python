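"""PBD solver: projections against oracles, conservation, determinism."""

import numpy as np
import pytest
import trimesh

from pneumosim.discretize import (ClusterSet, ParticleSystem, SpringSet,
                                  build_inflatable, build_surface_springs)
from pneumosim.engine import (EquilibriumCriteria, SimulationSettings,
                              SimulationState, collision_pairs, deform_skin,
                              predict, project_clusters, project_collisions,
                              project_springs, project_volume,
                              simulate_to_equilibrium, step)
from pneumosim.imaging import SurfaceMesh


def make_ps(points, radius=1.0, region="wall", inverse_masses=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    im = np.ones(n) if inverse_masses is None else np.asarray(
        inverse_masses, float)
    return ParticleSystem(points, np.zeros((n, 3)), im, radius,
                          np.full(n, region))


def single_cluster(ps):
    n = len(ps)
    com = ps.positions.mean(axis=0)
    return ClusterSet(np.arange(n), np.array([0, n]), com[None, :],
                      ps.positions - com, stiffness=1.0)


def sphere_state(pressure, radius=30.0, subdivisions=3):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                       "inflatable")
    ps, surf = build_inflatable(mesh, pressure_factor=pressure)
    return SimulationState(ps=ps, inflatable=surf)


class TestPredict:
    def test_rest_is_identity(self):
        st = SimulationState(ps=make_ps([[1, 2, 3]]))
        xp = predict(st, SimulationSettings())
        assert np.array_equal(xp, [[1, 2, 3]])

    def test_overdamped_zeroes_velocity(self):
        ps = make_ps([[0, 0, 0]])
        ps.velocities[:] = [5.0, -3.0, 1.0]
        st = SimulationState(ps=ps)
        predict(st, SimulationSettings(damping_factor=120.0))  # d·dt = 2 > 1
        assert np.array_equal(ps.velocities, np.zeros((1, 3)))

    def test_gravity_update_hand_computed(self):
        """One free particle under g = −9810 mm/s², dt = 1/60, damping 12:
        v_y = −163.5 · (1 − 12/60)."""
        ps = make_ps([[0, 0, 0]])
        st = SimulationState(ps=ps)
        settings = SimulationSettings(gravity=(0.0, -9810.0, 0.0))
        xp = predict(st, settings)
        expected_v = -9810.0 / 60.0 * (1.0 - 12.0 / 60.0)
        assert ps.velocities[0, 1] == pytest.approx(expected_v, rel=1e-12)
        assert xp[0, 1] == pytest.approx(expected_v / 60.0, rel=1e-12)

    def test_fixed_particles_do_not_move(self):
        ps = make_ps([[0, 0, 0]], inverse_masses=[0.0])
        ps.velocities[:] = 9.0
        st = SimulationState(ps=ps)
        xp = predict(st, SimulationSettings(gravity=(0, -9810, 0)))
        assert np.array_equal(xp, [[0, 0, 0]])


class TestClusters:
    settings1 = SimulationSettings(iterations_per_substep=1)  # k′ = k

    def square_ps(self):
        return make_ps([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])

    def test_rest_configuration_fixed_point(self):
        ps = self.square_ps()
        st = SimulationState(ps=ps, clusters=single_cluster(ps))
        corr = project_clusters(st, self.settings1)
        assert np.abs(corr).max() < 1e-12

    def test_rigid_rotation_invariance(self):
        ps = self.square_ps()
        cs = single_cluster(ps)
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        com = ps.positions.mean(axis=0)
        ps.positions = (ps.positions - com) @ R.T + com + [5.0, -2.0, 1.0]
        st = SimulationState(ps=ps, clusters=cs)
        corr = project_clusters(st, self.settings1)
        assert np.abs(corr).max() < 1e-9

    def test_goals_match_exhaustive_rigid_fit(self):
        """Stiffness 1: corrected positions equal the best rigid fit of the
        rest square, found by exhaustive in-plane rotation search."""
        ps = self.square_ps()
        cs = single_cluster(ps)
        rest = ps.positions.copy()
        ps.positions = rest.copy()
        ps.positions[2] += [0.3, -0.2, 0.0]  # displace one corner in-plane
        st = SimulationState(ps=ps, clusters=cs)
        corr = project_clusters(st, self.settings1)
        goals = ps.positions + corr

        q = rest - rest.mean(axis=0)
        com = ps.positions.mean(axis=0)
        best, best_err = None, np.inf
        for th in np.linspace(-np.pi, np.pi, 200001):
            R = np.array([[np.cos(th), -np.sin(th), 0],
                          [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
            cand = com + q @ R.T
            err = ((cand - ps.positions) ** 2).sum()
            if err < best_err:
                best, best_err = cand, err
        assert np.abs(goals - best).max() < 1e-4

    def test_degenerate_collinear_cluster_identity_rotation(self):
        ps = make_ps([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        cs = single_cluster(ps)
        ps.positions[1] += [0.0, 1e-3, 0.0]
        st = SimulationState(ps=ps, clusters=cs)
        corr = project_clusters(st, self.settings1)  # must not blow up
        assert np.isfinite(corr).all()


class TestSprings:
    settings1 = SimulationSettings(iterations_per_substep=1)

    def pair_state(self, d, L0=1.0, stiffness=1.0):
        ps = make_ps([[0, 0, 0], [d, 0, 0]])
        springs = SpringSet(np.array([[0, 1]]), np.array([L0]), stiffness)
        return SimulationState(ps=ps, springs=[springs])

    def test_rest_length_zero_correction(self):
        st = self.pair_state(1.0)
        assert np.abs(project_springs(st, self.settings1)).max() < 1e-12

    def test_symmetric_split(self):
        st = self.pair_state(2.0, L0=1.0, stiffness=1.0)
        corr = project_springs(st, self.settings1)
        assert corr[0, 0] == pytest.approx(0.5)
        assert corr[1, 0] == pytest.approx(-0.5)

    def test_scalar_recurrence_convergence(self):
        """k=0.5 projected 9 times matches d ← d − k(d − L0) and lands
        within 1% of the rest length."""
        st = self.pair_state(2.0, L0=1.0, stiffness=0.5)
        d_oracle = 2.0
        for _ in range(9):
            corr = project_springs(st, self.settings1)
            st.ps.positions += corr
            d_oracle = d_oracle - 0.5 * (d_oracle - 1.0)
            d_now = st.ps.positions[1, 0] - st.ps.positions[0, 0]
            assert d_now == pytest.approx(d_oracle, rel=1e-12)
        assert abs(d_now - 1.0) < 0.01 * 1.0

    def test_iteration_corrected_stiffness_semantics(self):
        """Projecting k=0.5 n times with the n-iteration correction removes
        half the violation overall, independent of n."""
        for n in (3, 9):
            st = self.pair_state(2.0, L0=1.0, stiffness=0.5)
            settings = SimulationSettings(iterations_per_substep=n)
            for _ in range(n):
                st.ps.positions += project_springs(st, settings)
            d = st.ps.positions[1, 0] - st.ps.positions[0, 0]
            assert d == pytest.approx(1.5, rel=1e-9), n

    def test_unequal_masses_split_by_inverse_mass(self):
        ps = make_ps([[0, 0, 0], [2.0, 0, 0]], inverse_masses=[2.0, 1.0])
        springs = SpringSet(np.array([[0, 1]]), np.array([1.0]), 1.0)
        st = SimulationState(ps=ps, springs=[springs])
        corr = project_springs(st, self.settings1)
        assert corr[0, 0] == pytest.approx(2.0 / 3.0)
        assert corr[1, 0] == pytest.approx(-1.0 / 3.0)


class TestVolume:
    def test_rest_pressure_one_zero_correction(self):
        st = sphere_state(1.0)
        corr = project_volume(st, SimulationSettings())
        assert np.abs(corr).max() < 1e-9

    def test_projection_preserves_center_of_mass(self):
        st = sphere_state(5.0)
        corr = project_volume(st, SimulationSettings())
        assert np.abs(corr.sum(axis=0)).max() < 1e-9
        assert np.abs(corr).max() > 0

    def test_sphere_doubles_radius_at_factor_eight(self):
        """Volume ∝ r³: pressure factor 8 doubles the radius within 1%."""
        st = sphere_state(8.0)
        st, report = simulate_to_equilibrium(st)
        assert report.converged
        r = np.linalg.norm(st.ps.positions, axis=1).mean()
        assert r == pytest.approx(60.0, rel=0.01)

    def test_all_fixed_warns_and_skips(self):
        st = sphere_state(5.0)
        st.ps.inverse_masses[:] = 0.0
        with pytest.warns(UserWarning, match="fixed"):
            corr = project_volume(st, SimulationSettings())
        assert np.abs(corr).max() == 0.0


class TestCollisions:
    settings = SimulationSettings()

    def two_particle_state(self, d):
        ps = ParticleSystem(np.array([[0.0, 0, 0], [d, 0, 0]]),
                            np.zeros((2, 3)), np.ones(2), 1.0,
                            np.array(["wall", "viscera"]))
        return SimulationState(ps=ps)

    def test_contact_threshold(self):
        st = self.two_particle_state(2.0)  # exactly 2r: no penetration
        corr = project_collisions(st, self.settings)
        assert np.abs(corr).max() == 0.0

    def test_symmetric_push_at_half_overlap(self):
        st = self.two_particle_state(1.0)  # distance r ⇒ push r/2 each
        corr = project_collisions(st, self.settings)
        assert corr[0, 0] == pytest.approx(-0.5)
        assert corr[1, 0] == pytest.approx(0.5)

    def test_same_region_ignored(self):
        ps = make_ps([[0, 0, 0], [1.0, 0, 0]], region="wall")
        st = SimulationState(ps=ps)
        assert np.abs(project_collisions(st, self.settings)).max() == 0.0

    def test_cloud_separates_to_brute_force_distances(self, rng):
        """Random 100-particle cloud: repeated projection reaches min
        pairwise inter-region distance ≥ 2r − 1e-6, and the engine's
        candidate pairs match an all-pairs O(n²) scan."""
        pts = rng.uniform(0, 14.0, size=(100, 3))
        regions = np.where(np.arange(100) % 2 == 0, "wall", "viscera")
        ps = ParticleSystem(pts, np.zeros((100, 3)), np.ones(100), 1.0,
                            regions)
        st = SimulationState(ps=ps)
        pairs = collision_pairs(ps)
        brute = {(i, j) for i in range(100) for j in range(i + 1, 100)
                 if regions[i] != regions[j]
                 and np.linalg.norm(pts[i] - pts[j]) < 2.2}
        assert {(int(a), int(b)) for a, b in pairs} == brute
        for _ in range(60):
            st._collision_pairs = collision_pairs(st.ps)
            st.ps.positions += project_collisions(st, self.settings)
        x = st.ps.positions
        dmin = np.inf
        for i in range(100):
            for j in range(i + 1, 100):
                if regions[i] != regions[j]:
                    dmin = min(dmin, np.linalg.norm(x[i] - x[j]))
        assert dmin >= 2.0 - 1e-6


class TestStep:
    def test_equilibrium_is_fixed_point(self):
        st = sphere_state(1.0)
        st.springs = [build_surface_springs(st.inflatable, 0.5)]
        for _ in range(10):
            step(st)
        assert st.last_max_displacement < 1e-6

    def test_center_of_mass_conserved(self):
        """Gravity 0, no fixed particles: COM drift < 1e-6 mm over 100
        frames even while constraints are actively correcting."""
        st = sphere_state(2.0)
        st.springs = [build_surface_springs(st.inflatable, 0.5)]
        com0 = st.ps.positions.mean(axis=0)
        for _ in range(100):
            step(st)
        drift = np.linalg.norm(st.ps.positions.mean(axis=0) - com0)
        assert drift < 1e-6

    def test_bitwise_deterministic(self):
        runs = []
        for _ in range(2):
            st = sphere_state(3.0, subdivisions=2)
            st.springs = [build_surface_springs(st.inflatable, 0.3)]
            for _ in range(25):
                step(st)
            runs.append(st.ps.positions.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_fixed_particles_bit_stationary(self):
        st = sphere_state(4.0, subdivisions=2)
        st.ps.inverse_masses[:20] = 0.0
        frozen = st.ps.positions[:20].copy()
        for _ in range(50):
            step(st)
        assert np.array_equal(st.ps.positions[:20], frozen)

    def test_non_finite_positions_abort_with_diagnostics(self):
        st = sphere_state(2.0, subdivisions=2)
        st.ps.velocities[3] = np.inf
        with pytest.raises(FloatingPointError, match="frame"):
            step(st)


class TestEquilibrium:
    def test_already_converged_returns_within_window(self):
        st = sphere_state(1.0)
        st, report = simulate_to_equilibrium(
            st, criteria=EquilibriumCriteria(window=10, max_frames=500))
        assert report.converged
        assert report.frames == 10

    @pytest.mark.parametrize("factor", [1.0, 2.0, 5.0, 10.0, 15.0])
    def test_isolated_inflatable_reaches_target_volume(self, factor):
        """Equilibrium volume = pressure factor × V₀ within 2%."""
        st = sphere_state(factor)
        st, report = simulate_to_equilibrium(st)
        assert report.converged
        assert report.volume_ratio == pytest.approx(factor, rel=0.02)

    def test_frame_cap_returns_unconverged(self):
        st = sphere_state(10.0)
        st, report = simulate_to_equilibrium(
            st, criteria=EquilibriumCriteria(max_frames=1))
        assert not report.converged
        assert report.frames == 1

    def test_frame_log_written(self, tmp_path):
        st = sphere_state(2.0, subdivisions=2)
        log = tmp_path / "frames.csv"
        st, report = simulate_to_equilibrium(
            st, criteria=EquilibriumCriteria(window=5, max_frames=50),
            frame_log=log)
        lines = log.read_text().strip().splitlines()
        assert lines[0].startswith("frame,")
        assert len(lines) == report.frames + 1


class TestDeformSkin:
    def make_binding_state(self):
        from pneumosim.discretize import bind_skin
        ps = make_ps([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]],
                     region="wall")
        mesh = SurfaceMesh(np.array([[1.0, 1, 1], [2.0, 0, 0]]),
                           np.zeros((0, 3), int), "skin")
        binding = bind_skin(mesh, ps, k=2)
        return binding, SimulationState(ps=ps), mesh

    def test_zero_displacement_identity(self):
        binding, st, mesh = self.make_binding_state()
        out = deform_skin(binding, st, mesh)
        assert np.allclose(out.vertices, mesh.vertices)

    def test_rigid_translation_partition_of_unity(self):
        binding, st, mesh = self.make_binding_state()
        st.ps.positions = st.ps.positions + [3.0, -1.0, 2.0]
        out = deform_skin(binding, st, mesh)
        assert np.allclose(out.vertices, mesh.vertices + [3.0, -1.0, 2.0])

    def test_particle_count_mismatch_rejected(self):
        binding, st, mesh = self.make_binding_state()
        st.ps = make_ps(np.zeros((7, 3)), region="wall")
        with pytest.raises(ValueError, match="mismatch"):
            deform_skin(binding, st, mesh)


class TestEmbeddedMonotonicity:
    def test_equilibrium_volume_monotone_in_pressure(self, tiny_pair):
        """On the phantom, more simulation pressure never yields less
        equilibrium gas volume (factors 1, 2, 4, 8)."""
        from pneumosim.calibrate import SimParams, build_state
        ratios = []
        for pf in (1.0, 2.0, 4.0, 8.0):
            st, _ = build_state(tiny_pair.deflated,
                                SimParams(0.6, 0.5, 2.2, pf))
            st, report = simulate_to_equilibrium(
                st, criteria=EquilibriumCriteria(max_frames=800))
            ratios.append(st.inflatable_volume_ratio())
        assert all(b >= a - 1e-6 for a, b in zip(ratios, ratios[1:])), ratios
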