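import numpy as np
import pytest

from shell_lattice.synthetic import (
    CorruptionSpec,
    SurfaceSpec,
    corrupt_particles,
    decorate_lattice,
    make_channel,
    make_line_profile,
    make_sheet_beads,
    make_surface,
)

from conftest import random_table


class TestMakeSurface:
    def test_sphere_area_matches_closed_form(self):
        R = 500.0
        mesh = make_surface(SurfaceSpec(kind="sphere", size=(R,), resolution=25.0))
        assert mesh.area == pytest.approx(4 * np.pi * R ** 2, rel=0.01)
        assert mesh.is_watertight and mesh.is_winding_consistent

    def test_plane_area_exact(self):
        mesh = make_surface(SurfaceSpec(kind="plane", size=(1000.0, 1000.0), resolution=35.0))
        assert mesh.area == pytest.approx(1e6, rel=1e-12)

    def test_same_seed_same_mesh(self):
        spec = SurfaceSpec(kind="perturbed_sphere", size=(500.0, 30.0), resolution=40.0, seed=11)
        m1, m2 = make_surface(spec), make_surface(spec)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)

    def test_resolution_coarser_than_object_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            SurfaceSpec(kind="sphere", size=(50.0,), resolution=100.0)

    @pytest.mark.parametrize("kind,size", [
        ("ellipsoid", (600.0, 500.0, 400.0)),
        ("box", (400.0, 400.0, 400.0)),
        ("perturbed_sphere", (500.0, 25.0)),
    ])
    def test_closed_kinds_are_watertight(self, kind, size):
        mesh = make_surface(SurfaceSpec(kind=kind, size=size, resolution=50.0))
        assert mesh.is_watertight


class TestDecorateLattice:
    def test_plane_p4_exact_lattice(self, plane_p4):
        table = plane_p4.table
        assert len(table) == 121
        xs = np.unique(np.round(table.positions[:, 0], 6))
        assert np.allclose(xs, np.arange(11) * 115.0)
        # all interior nearest-neighbour distances are exactly the constant
        from scipy.spatial import cKDTree

        d, _ = cKDTree(table.positions).query(table.positions, k=2)
        assert np.allclose(d[:, 1], 115.0, atol=1e-6)

    def test_particles_point_along_outward_normal(self, sphere_p4):
        table = sphere_p4.table
        z = table.z_axes()
        radial = table.positions / np.linalg.norm(table.positions, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip((z * radial).sum(1), -1, 1)))
        assert ang.max() < 1e-6 + 3.0  # face-normal orientation on a faceted mesh

    def test_plane_orientation_exactly_normal(self, plane_p4):
        z = plane_p4.table.z_axes()
        assert np.abs(z - np.array([0.0, 0.0, 1.0])).max() < 1e-6

    def test_p2_neighbor_angle_histogram_peaks(self, plane_mesh):
        dec = decorate_lattice(plane_mesh, group="p2", a=115.0, b=135.0, gamma=75.0)
        pos = dec.table.positions
        angles = []
        adj: dict[int, list[int]] = {}
        for i, j in dec.neighbor_edges:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        for i, nbrs in adj.items():
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    u = pos[nbrs[a]] - pos[i]
                    v = pos[nbrs[b]] - pos[i]
                    c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
                    if 5 < ang < 175:
                        angles.append(ang)
        hist, edges = np.histogram(angles, bins=np.arange(0, 181, 5))
        top2 = np.sort(np.argsort(hist)[-2:])
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert abs(centers[top2[0]] - 75.0) <= 5.0
        assert abs(centers[top2[1]] - 105.0) <= 5.0

    def test_interior_p4_nodes_have_four_neighbors(self, plane_p4):
        from collections import Counter

        deg = Counter()
        for i, j in plane_p4.neighbor_edges:
            deg[i] += 1
            deg[j] += 1
        pos = plane_p4.table.positions
        interior = (pos[:, 0] > 1) & (pos[:, 0] < 1149) & (pos[:, 1] > 1) & (pos[:, 1] < 1149)
        for idx in np.flatnonzero(interior):
            assert deg[idx] == 4
        for idx in np.flatnonzero(~interior):
            assert deg[idx] < 4

    def test_lattice_constant_larger_than_surface_rejected(self):
        tiny = make_surface(SurfaceSpec(kind="plane", size=(50.0, 50.0), resolution=10.0))
        with pytest.raises(ValueError, match="larger than the surface"):
            decorate_lattice(tiny, a=500.0)


class TestCorruptParticles:
    def test_zero_spec_is_identity(self):
        table = random_table(50, seed=4)
        out = corrupt_particles(table, CorruptionSpec(seed=1))
        assert np.array_equal(out.positions, table.positions)
        assert np.array_equal(out.eulers, table.eulers)

    def test_same_seed_same_output(self):
        table = random_table(80, seed=4)
        spec = CorruptionSpec(jitter_sigma_pos=5, jitter_sigma_ang=4, false_positive_rate=0.2,
                              false_negative_rate=0.1, flip_rate=0.05, seed=7)
        o1 = corrupt_particles(table, spec)
        o2 = corrupt_particles(table, spec)
        assert np.array_equal(o1.positions, o2.positions)
        assert np.array_equal(o1.eulers, o2.eulers)

    def test_false_negative_rate_matches_binomial(self):
        """Mean retained count over 300 seeds within 4 s.e. of n(1-p)."""
        table = random_table(200, seed=0)
        counts = [len(corrupt_particles(table, CorruptionSpec(false_negative_rate=0.5, seed=s)))
                  for s in range(300)]
        se = np.sqrt(200 * 0.25) / np.sqrt(300)
        assert abs(np.mean(counts) - 100.0) < 4 * se

    def test_flip_rate_inverts_z_axes(self):
        table = random_table(400, seed=2)
        out = corrupt_particles(table, CorruptionSpec(flip_rate=0.25, seed=3))
        flipped = ((out.z_axes() * table.z_axes()).sum(1) < -0.999).sum()
        assert 60 <= flipped <= 140  # ~Binomial(400, .25)

    def test_false_positives_added_with_lower_scores(self):
        table = random_table(100, seed=2)
        table.scores = np.ones(100)
        out = corrupt_particles(table, CorruptionSpec(false_positive_rate=0.3, seed=3))
        n_fp = len(out) - 100
        assert n_fp > 10
        assert (out.scores[100:] < 1.0).all()


class TestChannelsSheetsProfiles:
    def test_cylinder_analytic_radius(self):
        ch = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=100.0)
        assert np.allclose(ch.analytic_radius(ch.ring_z), 7.0)

    def test_hourglass_min_radius_at_waist(self):
        ch = make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=100.0, waist=4.0)
        prof = ch.analytic_radius(ch.ring_z)
        assert prof.min() == pytest.approx(3.0)
        assert prof.max() == pytest.approx(7.0)

    def test_beads_lie_on_stated_ring_radius(self):
        ch = make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=60.0, waist=5.0)
        coords = ch.model.coords
        rho = np.sqrt(coords[:, 0] ** 2 + coords[:, 1] ** 2)
        expected = ch.analytic_radius(coords[:, 2]) + 1.0
        assert np.abs(rho - expected).max() < 1e-6

    def test_hourglass_requires_waist(self):
        with pytest.raises(ValueError, match="waist"):
            make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=50.0)

    def test_sheet_bead_count_and_centroids(self):
        model = make_sheet_beads(3, 3, a=115.0, beads_per_unit=100, seed=1)
        assert len(model) == 900
        centroids = model.coords.reshape(9, 100, 3).mean(axis=1)
        expected = np.array([[i * 115.0, j * 115.0, 0.0] for i in range(3) for j in range(3)])
        assert np.abs(centroids - expected).max() < 1e-6
        again = make_sheet_beads(3, 3, a=115.0, beads_per_unit=100, seed=1)
        assert np.array_equal(model.coords, again.coords)

    def test_line_profile_ideal_tophat(self):
        prof = make_line_profile(200.0, edge_width=0.0, noise_sigma=0.0, pixel_size=2.0)
        dark = prof < 0.5
        assert dark.sum() * 2.0 == pytest.approx(200.0, abs=2.0)
        assert prof.max() == 1.0 and prof.min() == 0.0

    def test_profile_shorter_than_diameter_rejected(self):
        with pytest.raises(ValueError, match="length"):
            make_line_profile(200.0, length=150.0)

    def test_profile_same_seed_identical(self):
        p1 = make_line_profile(100.0, edge_width=5.0, noise_sigma=0.05, seed=3)
        p2 = make_line_profile(100.0, edge_width=5.0, noise_sigma=0.05, seed=3)
        assert np.array_equal(p1, p2)
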