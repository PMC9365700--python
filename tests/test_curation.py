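import numpy as np
import pytest

from shell_lattice.curation import (
    CurationParams,
    estimate_lattice,
    neighbor_count_filter,
    neighbor_plot,
    remove_duplicates,
)
from shell_lattice.io_formats import ParticleTable
from shell_lattice.synthetic import CorruptionSpec, SurfaceSpec, corrupt_particles, decorate_lattice, make_surface

from conftest import random_table


def brute_force_greedy_dedup(table, min_dist):
    """Independent oracle: explicit greedy pass in descending score order."""
    order = sorted(range(len(table)), key=lambda i: (-table.scores[i], table.ids[i]))
    accepted = []
    for i in order:
        if all(np.linalg.norm(table.positions[i] - table.positions[j]) >= min_dist
               for j in accepted):
            accepted.append(i)
    return sorted(accepted)


class TestRemoveDuplicates:
    def test_closer_pair_keeps_higher_score(self):
        t = ParticleTable(ids=[0, 1], tomo_id=np.array(["a", "a"], dtype=object),
                          positions=[[0, 0, 0], [80, 0, 0]], eulers=np.zeros((2, 3)),
                          scores=[0.7, 0.5])
        out = remove_duplicates(t, CurationParams(dup_min_dist=90))
        assert list(out.ids) == [0]

    def test_separated_pair_both_kept(self):
        t = ParticleTable(ids=[0, 1], tomo_id=np.array(["a", "a"], dtype=object),
                          positions=[[0, 0, 0], [120, 0, 0]], eulers=np.zeros((2, 3)),
                          scores=[0.7, 0.5])
        assert len(remove_duplicates(t, CurationParams(dup_min_dist=90))) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_crowded_box(self, seed):
        t = random_table(50, seed=seed, box=200.0)
        params = CurationParams(dup_min_dist=90.0)
        out = remove_duplicates(t, params)
        assert sorted(out.ids) == brute_force_greedy_dedup(t, 90.0)

    def test_output_pairwise_distance_invariant(self):
        t = random_table(120, seed=7, box=400.0)
        out = remove_duplicates(t, CurationParams(dup_min_dist=90.0))
        from scipy.spatial import cKDTree

        if len(out) > 1:
            d, _ = cKDTree(out.positions).query(out.positions, k=2)
            assert d[:, 1].min() >= 90.0

    def test_missing_scores_warns(self):
        t = random_table(10, seed=1, scores=False)
        with pytest.warns(UserWarning, match="score"):
            remove_duplicates(t, CurationParams())


class TestNeighborCountFilter:
    def test_isolated_particle_removed(self):
        t = random_table(1, seed=0)
        assert len(neighbor_count_filter(t, CurationParams())) == 0

    def test_interior_lattice_nodes_kept_corners_removed(self, plane_p4):
        out = neighbor_count_filter(plane_p4.table, CurationParams())
        pos = plane_p4.table.positions
        interior = ((pos[:, 0] > 1) & (pos[:, 0] < 1149) &
                    (pos[:, 1] > 1) & (pos[:, 1] < 1149))
        kept = set(out.ids)
        # every interior node (4 neighbours at 115 Å) survives
        assert set(plane_p4.table.ids[interior]) <= kept
        # corner nodes have 2 neighbours and are removed
        corners = [i for i, p in enumerate(pos)
                   if (p[0] in (0.0, 1150.0)) and (p[1] in (0.0, 1150.0))]
        assert kept.isdisjoint(plane_p4.table.ids[corners])

    def test_counts_computed_on_input_set_single_pass(self):
        # a chain where removing an endpoint would cascade if iterated:
        # single-pass semantics keep the middle nodes
        xs = np.arange(6) * 115.0
        t = ParticleTable(ids=np.arange(6), tomo_id=np.array(["a"] * 6, dtype=object),
                          positions=np.column_stack([xs, np.zeros(6), np.zeros(6)]),
                          eulers=np.zeros((6, 3)))
        params = CurationParams(neighbor_min_count=2)
        out = neighbor_count_filter(t, params)
        # ends have 1 neighbour -> removed; middles have 2 on the INPUT set
        assert list(out.ids) == [1, 2, 3, 4]


class TestNeighborPlot:
    def test_ideal_p4_peaks_at_lattice_vectors(self, plane_p4):
        counts, edges = neighbor_plot(plane_p4.table, rmax=130.0, bin_size=10.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        flat = counts.ravel()
        top4 = np.argsort(flat)[-4:]
        peaks = set()
        for i in top4:
            a, b, c = np.unravel_index(i, counts.shape)
            peaks.add((round(centers[a] / 115) * 115, round(centers[b] / 115) * 115,
                       round(centers[c] / 115) * 115))
        assert peaks == {(115, 0, 0), (-115, 0, 0), (0, 115, 0), (0, -115, 0)}

    def test_random_scatter_has_no_dominant_bin(self):
        t = random_table(500, seed=1, box=1200.0)
        counts, _ = neighbor_plot(t, rmax=200.0, bin_size=40.0)
        occupied = counts[counts > 0]
        assert counts.max() <= 3.0 * occupied.mean()

    def test_empty_table_gives_empty_histogram(self):
        t = random_table(5, seed=0).select(np.zeros(5, dtype=bool))
        counts, edges = neighbor_plot(t, rmax=100.0)
        assert counts.sum() == 0


class TestEstimateLattice:
    def test_ideal_p4_recovered(self, plane_p4):
        est = estimate_lattice(plane_p4.table)
        assert est.group_call == "p4"
        assert est.a == pytest.approx(115.0, abs=1.0)
        assert est.b == pytest.approx(115.0, abs=1.0)
        assert est.gamma == pytest.approx(90.0, abs=1.0)

    def test_ideal_p2_recovered(self, plane_mesh):
        dec = decorate_lattice(plane_mesh, group="p2", a=115.0, b=135.0, gamma=75.0)
        est = estimate_lattice(dec.table)
        assert est.group_call == "p2"
        assert est.a == pytest.approx(115.0, abs=2.0)
        assert est.b == pytest.approx(135.0, abs=2.0)
        assert est.gamma == pytest.approx(75.0, abs=3.0)

    def test_jittered_p4_spacing_recovered(self, plane_p4):
        noisy = corrupt_particles(plane_p4.table, CorruptionSpec(jitter_sigma_pos=8.0, seed=3))
        est = estimate_lattice(noisy)
        assert est.group_call == "p4"
        assert est.a == pytest.approx(115.0, abs=5.0)

    def test_random_cloud_called_disordered(self):
        t = random_table(300, seed=2, box=1500.0)
        assert estimate_lattice(t).group_call == "disordered"

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError, match="20"):
            estimate_lattice(random_table(10, seed=0))


class TestCurationRecovery:
    def test_corrupted_lattice_recovery(self):
        """fp_rate 0.3 + jitter 5 Å: ≥95% of truth kept, ≤5% contamination."""
        mesh = make_surface(SurfaceSpec(kind="plane", size=(3335.0, 3335.0), resolution=60.0))
        dec = decorate_lattice(mesh, a=115.0)
        spec = CorruptionSpec(jitter_sigma_pos=5.0, false_positive_rate=0.3, seed=3)
        corrupted = corrupt_particles(dec.table, spec, mesh=mesh)
        cleaned = neighbor_count_filter(remove_duplicates(corrupted))
        from scipy.spatial import cKDTree

        d, _ = cKDTree(dec.table.positions).query(cleaned.positions)
        n_true = int((d < 25.0).sum())
        assert n_true / len(dec.table) >= 0.95
        assert (len(cleaned) - n_true) / len(cleaned) <= 0.05
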