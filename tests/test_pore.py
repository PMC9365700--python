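import numpy as np
import pytest

from shell_lattice.io_formats import BeadModel
from shell_lattice.pore import pore_profile, pore_volume, profile_series, restrictive_diameter
from shell_lattice.synthetic import make_channel


def brute_force_radius(model, radii, point):
    """Oracle: explicit scan of every bead's clearance at a probe centre."""
    best = np.inf
    for x, r in zip(model.coords, radii):
        best = min(best, np.linalg.norm(x - point) - r)
    return max(0.0, best)


class TestPoreProfile:
    def test_cylinder_matches_analytic_everywhere(self):
        ch = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=100.0)
        prof = pore_profile(ch.model, zrange=(-50.0, 50.0), dz=2.0)
        assert np.abs(prof.radius - 7.0).max() < 1e-6
        assert restrictive_diameter(prof) == pytest.approx(1.4, abs=1e-9)

    def test_hourglass_matches_analytic_and_waist(self):
        ch = make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=100.0, waist=4.0)
        prof = pore_profile(ch.model, zrange=(-50.0, 50.0), dz=2.0)
        assert np.abs(prof.radius - ch.analytic_radius(prof.z)).max() < 1e-6
        assert restrictive_diameter(prof) == pytest.approx(0.6, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-20, 20, (60, 3))
        radii = rng.uniform(1.0, 3.0, 60)
        model = BeadModel(coords=coords, masses=np.ones(60), radii=radii)
        prof = pore_profile(model, zrange=(-10.0, 10.0), dz=5.0, slab_halfwidth=50.0)
        for z, r in zip(prof.z, prof.radius):
            assert abs(r - brute_force_radius(model, radii, np.array([0.0, 0.0, z]))) < 1e-10

    def test_off_axis_channel_relaxation_recovers_true_centre(self):
        ch = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=60.0)
        shifted = BeadModel(coords=ch.model.coords + np.array([3.0, 0.0, 0.0]),
                            masses=ch.model.masses, radii=ch.model.radii)
        fixed = pore_profile(shifted, zrange=(-30.0, 30.0), dz=2.0)
        relaxed = pore_profile(shifted, zrange=(-30.0, 30.0), dz=2.0, relax=True)
        assert np.abs(relaxed.radius - 7.0).max() < 0.1
        assert np.all(fixed.radius <= relaxed.radius + 1e-12)
        assert fixed.radius.max() < 7.0

    def test_adding_a_bead_never_increases_radius(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-15, 15, (40, 3))
        model = BeadModel(coords=coords, masses=np.ones(40), radii=np.full(40, 1.5))
        prof1 = pore_profile(model, zrange=(-10, 10), dz=2.0, slab_halfwidth=40.0)
        bigger = BeadModel(coords=np.vstack([coords, [[2.0, 2.0, 0.0]]]),
                           masses=np.ones(41), radii=np.full(41, 1.5))
        prof2 = pore_profile(bigger, zrange=(-10, 10), dz=2.0, slab_halfwidth=40.0)
        assert np.all(prof2.radius <= prof1.radius + 1e-12)

    def test_scale_equivariance(self):
        ch = make_channel("hourglass", ring_radius=8.0, atom_radius=1.0, length=80.0, waist=4.0)
        c = 2.5
        scaled = BeadModel(coords=ch.model.coords * c, masses=ch.model.masses,
                           radii=ch.model.radii * c)
        p1 = pore_profile(ch.model, zrange=(-40, 40), dz=4.0)
        p2 = pore_profile(scaled, zrange=(-40 * c, 40 * c), dz=4.0 * c, slab_halfwidth=15.0 * c)
        assert np.abs(p2.radius - c * p1.radius).max() < 1e-9
        assert pore_volume(p2) == pytest.approx(c ** 3 * pore_volume(p1), rel=1e-9)

    def test_empty_slab_marked_unbounded(self):
        ch = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=40.0)
        prof = pore_profile(ch.model, zrange=(-100.0, 100.0), dz=10.0, slab_halfwidth=15.0)
        assert not prof.bounded.all()
        assert np.isnan(prof.radius[~prof.bounded]).all()
        # unbounded stations are excluded from the restrictive diameter
        assert restrictive_diameter(prof) == pytest.approx(1.4, abs=1e-9)


class TestRestrictiveDiameterAndVolume:
    def test_closed_channel_reports_zero(self):
        ch = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=40.0)
        blocked = BeadModel(coords=np.vstack([ch.model.coords, [[0.0, 0.0, 0.0]]]),
                            masses=np.ones(len(ch.model) + 1),
                            radii=np.append(ch.model.radii, 2.0))
        prof = pore_profile(blocked, zrange=(-20, 20), dz=2.0)
        assert restrictive_diameter(prof) == 0.0

    def test_cylinder_volume_closed_form(self):
        # R = 5 Å over 100 Å: π·(0.5 nm)²·10 nm = 7.854 nm³
        ch = make_channel("cylinder", ring_radius=6.7, atom_radius=1.7, length=100.0)
        prof = pore_profile(ch.model, zrange=(-50, 50), dz=2.0)
        assert pore_volume(prof) == pytest.approx(np.pi * 0.25 * 10.0, abs=1e-6)

    def test_quadrature_exact_for_constant_radius(self):
        # rings at 1 Å so every station of both grids sits on a ring plane
        ch = make_channel("cylinder", ring_radius=6.7, atom_radius=1.7, length=100.0,
                          ring_spacing=1.0)
        v1 = pore_volume(pore_profile(ch.model, zrange=(-50, 50), dz=2.0))
        v2 = pore_volume(pore_profile(ch.model, zrange=(-50, 50), dz=1.0))
        assert abs(v1 - v2) < 1e-6

    def test_all_unbounded_rejected(self):
        ch = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=20.0)
        prof = pore_profile(ch.model, zrange=(100.0, 120.0), dz=10.0)
        with pytest.raises(ValueError, match="unbounded"):
            restrictive_diameter(prof)


class TestProfileSeries:
    def _frames(self):
        base = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=60.0).model
        narrow = make_channel("cylinder", ring_radius=6.0, atom_radius=1.0, length=60.0).model
        return base, narrow

    def test_identical_frames_zero_sd(self):
        base, _ = self._frames()
        _, summary = profile_series([base, base, base], zrange=(-30, 30), dz=2.0)
        assert summary["restrictive_diameter_nm_sd"] == pytest.approx(0.0, abs=1e-12)
        assert summary["n_frames"] == 3

    def test_two_frame_mean_and_population_sd(self):
        base, narrow = self._frames()
        _, summary = profile_series([base, narrow], zrange=(-30, 30), dz=2.0)
        assert summary["restrictive_diameter_nm_mean"] == pytest.approx((1.4 + 1.0) / 2)
        assert summary["restrictive_diameter_nm_sd"] == pytest.approx(0.2)

    def test_excluded_frames_shrink_n(self):
        base, narrow = self._frames()
        _, summary = profile_series([base, narrow, base], zrange=(-30, 30), dz=2.0,
                                    exclude_frames=[1])
        assert summary["n_frames"] == 2
        assert summary["restrictive_diameter_nm_sd"] == 0.0

    def test_inconsistent_bead_counts_rejected(self):
        base, _ = self._frames()
        other = make_channel("cylinder", ring_radius=8.0, atom_radius=1.0, length=40.0).model
        with pytest.raises(ValueError, match="beads"):
            profile_series([base, other], zrange=(-20, 20), dz=2.0)
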