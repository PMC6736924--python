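"""Particle sampling, clusters, springs, fixation, skin binding."""

import warnings

import numpy as np
import pytest
import trimesh

from pneumosim.discretize import (MIN_SPRING_REST_LENGTH, ParticleSystem,
                                  SpringSet, add_connectivity_springs,
                                  bind_skin, build_clusters, build_inflatable,
                                  build_surface_springs, concat_systems,
                                  fix_back_particles, load_system,
                                  particle_mass, sample_particles,
                                  save_system)
from pneumosim.imaging import SurfaceMesh


def cube_mesh(side=20.0, center=(0.0, 0.0, 0.0), region="wall"):
    box = trimesh.creation.box(extents=(side,) * 3)
    return SurfaceMesh(np.asarray(box.vertices) + np.asarray(center),
                       np.asarray(box.faces), region)


def make_ps(points, radius=1.0, region="wall"):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    return ParticleSystem(points, np.zeros((n, 3)), np.ones(n), radius,
                          np.full(n, region))


class TestSampleParticles:
    def test_cube_count_matches_brute_force(self):
        """Independent triple-loop grid enumeration of interior points."""
        radius, factor, side = 2.7, 4.0, 20.0
        ps = sample_particles({"wall": cube_mesh(side)}, radius, factor)
        h = radius * (2.0 / factor) * 2.0
        lo = -side / 2
        count = 0
        for ix in range(int(np.ceil(side / h)) + 2):
            for iy in range(int(np.ceil(side / h)) + 2):
                for iz in range(int(np.ceil(side / h)) + 2):
                    p = np.array([lo + h / 2 + ix * h, lo + h / 2 + iy * h,
                                  lo + h / 2 + iz * h])
                    if np.all(np.abs(p) < side / 2):
                        count += 1
        assert len(ps) == count

    def test_density_scales_with_sampling_factor(self):
        # fine grid relative to the cube keeps boundary effects small
        base = sample_particles({"wall": cube_mesh()}, 1.0, 4.0)
        dense = sample_particles({"wall": cube_mesh()}, 1.0, 8.0)
        assert len(dense) / len(base) == pytest.approx(8.0, rel=0.15)

    def test_mass_unit_conversion(self):
        # 1.05 g/cm³ in a (4/3)π·2.7³ mm³ ball ⇒ about 86.6 mg
        assert particle_mass(2.7, 1.05) == pytest.approx(0.0866, rel=0.01)
        ps = sample_particles({"wall": cube_mesh()}, 2.7, 4.0)
        masses = 1.0 / ps.inverse_masses
        assert np.allclose(masses, particle_mass(2.7))

    def test_particles_strictly_inside(self):
        ps = sample_particles({"wall": cube_mesh(side=10.0)}, 1.0)
        assert np.all(np.abs(ps.positions) < 5.0)

    def test_degenerate_flat_mesh_rejected(self):
        flat = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.001]]),
            np.array([[0, 1, 2], [0, 2, 3], [2, 1, 0], [3, 2, 0]]), "wall")
        with pytest.raises(ValueError, match="degenerate|thinner"):
            sample_particles({"wall": flat}, 2.0)

    def test_thin_region_named_in_error(self):
        thin = cube_mesh(side=1.0)
        with pytest.raises(ValueError, match="wall"):
            sample_particles({"wall": thin}, 2.7)


class TestBuildClusters:
    def test_single_cluster_limit(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        ps = make_ps(pts, radius=1.0)
        cs = build_clusters(ps, spacing_factor=10.0, stiffness=0.6)
        assert cs.n_clusters == 1
        assert sorted(cs.members.tolist()) == [0, 1, 2, 3]

    def test_grid_coverage_and_overlap(self):
        """Every particle in ≥1 cluster; mean memberships ≥ 2 on a regular
        grid, matching the brute-force membership count."""
        g = np.arange(10) * 2.7
        pts = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        ps = make_ps(pts, radius=2.7)
        cs = build_clusters(ps, spacing_factor=3.33, stiffness=0.6)
        memberships = cs.memberships_per_particle(len(ps))
        assert memberships.min() >= 1
        assert memberships.mean() >= 2.0
        # brute-force: membership of p = clusters whose center is within
        # spacing of p
        spacing = 3.33 * 2.7
        brute = np.zeros(len(ps), dtype=int)
        for c in range(cs.n_clusters):
            members = cs.members[cs.offsets[c]:cs.offsets[c + 1]]
            seed = pts[cs.center_particles[c]]
            within = np.linalg.norm(pts - seed, axis=1) <= spacing + 1e-9
            assert np.array_equal(np.sort(members), np.flatnonzero(within))
            brute += within
        assert np.array_equal(brute, memberships)

    def test_no_cluster_spans_regions(self):
        a = make_ps(np.random.default_rng(0).uniform(0, 5, (30, 3)),
                    region="wall")
        b = make_ps(np.random.default_rng(1).uniform(20, 25, (30, 3)),
                    region="viscera")
        ps = concat_systems(a, b)
        cs = build_clusters(ps, spacing_factor=50.0, stiffness=0.5)
        for c in range(cs.n_clusters):
            members = cs.members[cs.offsets[c]:cs.offsets[c + 1]]
            assert len(set(ps.regions[members].tolist())) == 1

    def test_min_members_after_merge(self, small_pair):
        ps = sample_particles({"wall": small_pair.deflated["wall"],
                               "viscera": small_pair.deflated["viscera"]},
                              2.7)
        cs = build_clusters(ps, 3.33, 0.6)
        sizes = np.diff(cs.offsets)
        assert sizes.min() >= 4

    def test_stiffness_validation(self):
        ps = make_ps([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="stiffness"):
            build_clusters(ps, 3.33, stiffness=1.5)


class TestBuildInflatable:
    def test_unit_cube_volume(self):
        ps, surf = build_inflatable(cube_mesh(side=1.0, region="inflatable"),
                                    pressure_factor=1.0)
        assert surf.rest_volume == pytest.approx(1.0)
        assert len(ps) == 8

    def test_icosphere_volume(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                           "inflatable")
        _, surf = build_inflatable(mesh, 1.0)
        assert surf.rest_volume == pytest.approx(4188.79, rel=0.02)

    def test_inverted_orientation_fixed(self):
        mesh = cube_mesh(side=2.0, region="inflatable")
        flipped = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1],
                              "inflatable")
        _, surf = build_inflatable(flipped, 1.0)
        assert surf.rest_volume == pytest.approx(8.0)

    def test_open_mesh_rejected(self):
        mesh = cube_mesh(region="inflatable")
        open_mesh = SurfaceMesh(mesh.vertices, mesh.faces[:-1], "inflatable")
        with pytest.raises(ValueError, match="closed"):
            build_inflatable(open_mesh, 1.0)


class TestSprings:
    def test_tetrahedron_has_six_springs(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        _, surf = build_inflatable(SurfaceMesh(v, f, "inflatable"), 1.0)
        springs = build_surface_springs(surf, 0.5)
        assert len(springs) == 6

    def test_icosphere_springs_match_edge_enumeration(self):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                           "inflatable")
        _, surf = build_inflatable(mesh, 1.0)
        springs = build_surface_springs(surf, 0.5)
        brute = set()
        for tri in mesh.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                brute.add((min(a, b), max(a, b)))
        got = {(min(i, j), max(i, j)) for i, j in springs.pairs}
        assert got == brute

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SpringSet(np.array([[0, 1], [1, 0]]), np.array([1.0, 1.0]), 0.5)

    def test_connectivity_parallel_planes(self):
        """Two parallel particle planes 1 mm apart, reach 2 mm: one spring
        per inflatable particle, rest length 1, matching brute force."""
        g = np.arange(5) * 3.0
        xy = np.array(np.meshgrid(g, g, indexing="ij")).reshape(2, -1).T
        wall_pts = np.column_stack([xy, np.zeros(len(xy))])
        infl_pts = np.column_stack([xy, np.ones(len(xy))])
        ps = concat_systems(make_ps(wall_pts, region="wall"),
                            make_ps(infl_pts, region="inflatable"))
        surf_idx = np.arange(len(xy)) + len(xy)

        class FakeSurf:
            vertex_particles = surf_idx
        springs = add_connectivity_springs(FakeSurf(), ps, max_dist=2.0,
                                           stiffness=0.5)
        assert len(springs) == len(xy)
        assert np.allclose(springs.rest_lengths, 1.0)
        for (i, j) in springs.pairs:  # brute-force nearest neighbor
            d = np.linalg.norm(ps.positions[i] - wall_pts, axis=1)
            assert j == np.argmin(d)

    def test_connectivity_out_of_reach_warns_empty(self):
        wall = make_ps([[0, 0, 0]], region="wall")
        infl = make_ps([[0, 0, 1.0]], region="inflatable")
        ps = concat_systems(wall, infl)

        class FakeSurf:
            vertex_particles = np.array([1])
        with pytest.warns(UserWarning, match="no inflatable-wall pairs"):
            springs = add_connectivity_springs(FakeSurf(), ps, max_dist=0.5)
        assert len(springs) == 0

    def test_coincident_pair_gets_minimum_rest_length(self):
        wall = make_ps([[0, 0, 0]], region="wall")
        infl = make_ps([[0, 0, 0]], region="inflatable")
        ps = concat_systems(wall, infl)

        class FakeSurf:
            vertex_particles = np.array([1])
        springs = add_connectivity_springs(FakeSurf(), ps, max_dist=1.0)
        assert springs.rest_lengths[0] == MIN_SPRING_REST_LENGTH


class TestFixBack:
    def test_matches_brute_force_filter(self, rng):
        pts = rng.uniform(-10, 10, size=(200, 3))
        ps = make_ps(pts, region="wall")
        band = 3.0
        n = fix_back_particles(ps, band=band)
        com_y = pts[:, 1].mean()
        expected = pts[:, 1] <= com_y - band
        assert n == expected.sum()
        assert np.array_equal(ps.inverse_masses == 0, expected)

    def test_band_zero_selects_dorsal_half(self, rng):
        pts = rng.normal(size=(100, 3))
        ps = make_ps(pts, region="wall")
        fix_back_particles(ps, band=0.0)
        assert np.array_equal(ps.inverse_masses == 0,
                              pts[:, 1] <= pts[:, 1].mean())

    def test_all_ventral_warns(self, rng):
        pts = rng.uniform(0, 1, size=(50, 3)) + [0, 100, 0]
        pts[:, 1] = 100 + pts[:, 1]  # tight ventral cloud
        ps = make_ps(pts, region="wall")
        with pytest.warns(UserWarning, match="no particles fixed"):
            n = fix_back_particles(ps, band=5.0)
        assert n == 0

    def test_idempotent(self, rng):
        pts = rng.uniform(-10, 10, size=(300, 3))
        ps = make_ps(pts, region="wall")
        fix_back_particles(ps, band=3.0)
        first = ps.inverse_masses.copy()
        fix_back_particles(ps, band=3.0)
        assert np.array_equal(ps.inverse_masses, first)

    def test_only_wall_region_affected(self, rng):
        pts = rng.uniform(-10, 10, size=(100, 3))
        ps = concat_systems(make_ps(pts, region="wall"),
                            make_ps(pts.copy(), region="viscera"))
        fix_back_particles(ps, band=0.0)
        assert (ps.inverse_masses[ps.regions == "viscera"] > 0).all()


class TestBindSkin:
    def test_coincident_vertex_single_weight(self):
        ps = make_ps([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]],
                     region="wall")
        mesh = SurfaceMesh(np.array([[0.0, 0, 0]]), np.zeros((0, 3), int),
                           "skin")
        binding = bind_skin(mesh, ps, k=3)
        row = binding.weights[0]
        assert row[binding.particle_indices[0] == 0][0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, rng):
        ps = make_ps(rng.uniform(-5, 5, (50, 3)), region="wall")
        mesh = SurfaceMesh(rng.uniform(-5, 5, (30, 3)),
                           np.zeros((0, 3), int), "skin")
        binding = bind_skin(mesh, ps, k=4)
        assert np.abs(binding.weights.sum(axis=1) - 1.0).max() < 1e-9

    def test_k_larger_than_particles_rejected(self):
        ps = make_ps([[0, 0, 0], [1, 1, 1]], region="wall")
        mesh = SurfaceMesh(np.array([[0.0, 0, 0]]), np.zeros((0, 3), int),
                           "skin")
        with pytest.raises(ValueError, match="exceeds"):
            bind_skin(mesh, ps, k=5)


class TestSerialization:
    def test_full_round_trip(self, tmp_path, small_pair):
        ps = sample_particles({"wall": small_pair.deflated["wall"]}, 2.7)
        cs = build_clusters(ps, 3.33, 0.6)
        _, surf = build_inflatable(small_pair.deflated["inflatable"], 2.0,
                                   first_particle=len(ps))
        springs = [build_surface_springs(surf, 0.5)]
        p = tmp_path / "system.json"
        save_system(p, ps, cs, springs, surf)
        ps2, cs2, springs2, surf2 = load_system(p)
        assert np.array_equal(ps2.positions, ps.positions)
        assert np.array_equal(ps2.regions, ps.regions)
        assert np.array_equal(cs2.members, cs.members)
        assert np.array_equal(springs2[0].pairs, springs[0].pairs)
        assert surf2.rest_volume == surf.rest_volume
        assert surf2.pressure_factor == surf.pressure_factor
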