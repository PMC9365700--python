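import numpy as np
import pytest

from shell_lattice.builder import (
    AssemblyModel,
    SegmentMap,
    TetramerUnit,
    assembly_to_particle_table,
    build_cube,
    build_prism,
    build_sheet,
    linker_spans,
    point_group_check,
    refold_sheet_to_cube,
    symmetry_expand,
    unfold_cube_to_sheet,
    wallpaper_p442_check,
)

from conftest import random_table


class TestBuilders:
    def test_sheet_count_and_mass(self):
        sheet = build_sheet(n=3, m=3)
        assert len(sheet) == 9
        assert sheet.n_protomers == 36
        assert sheet.mass_kda == pytest.approx(36 * 69.5)
        assert np.allclose(sheet.rotations, np.eye(3))

    def test_sheet_wallpaper_symmetry(self):
        assert wallpaper_p442_check(build_sheet(n=3, m=3))
        assert wallpaper_p442_check(build_sheet(n=2, m=2))

    def test_cube_protomers_and_mass(self):
        cube = build_cube()
        assert len(cube) == 6
        assert cube.n_protomers == 24
        assert round(cube.mass_mda, 2) == 1.67

    def test_cube_octahedral_invariance(self):
        assert point_group_check(build_cube(), "O")

    def test_cube_is_not_d4_only(self):
        # sanity: the prism is D4 but NOT O
        assert not point_group_check(build_prism(), "O")

    def test_prism_protomers_mass_envelope(self):
        prism = build_prism()
        assert len(prism) == 10
        assert prism.n_protomers == 40
        assert round(prism.mass_mda, 2) == 2.78
        env = prism.envelope()
        assert env == pytest.approx([220.0, 220.0, 335.0])
        assert env[2] / env[0] == pytest.approx(33.5 / 22.0, rel=1e-9)

    def test_prism_d4_invariance(self):
        assert point_group_check(build_prism(), "D4")

    def test_mass_scales_with_protomer_mass(self):
        cube = build_cube(TetramerUnit(protomer_mass_kda=70.0))
        assert round(cube.mass_mda, 2) == 1.68

    def test_opposite_cube_faces_are_antipodal(self):
        from shell_lattice.curvature import neighbor_bend_angles

        table = assembly_to_particle_table(build_cube())
        _, angles = neighbor_bend_angles(table, 110.0, 120.0)  # opposite faces at 115
        assert np.allclose(np.abs(angles), 180.0)


class TestUnfold:
    def test_net_is_planar_cross_of_six_tiles(self):
        net, report = unfold_cube_to_sheet(build_cube())
        assert report["n_tiles"] == 6
        assert report["n_hinges"] == 5
        assert np.allclose(net.translations[:, 2], 57.5)
        assert np.allclose(net.rotations[:, :, 2], [0.0, 0.0, 1.0])
        assert report["net_bend_angles_deg"] == [0.0] * 5

    def test_each_hinge_rotates_ninety_degrees(self):
        _, report = unfold_cube_to_sheet(build_cube())
        assert all(v == 90.0 for v in report["hinge_rotation_deg"].values())

    def test_refold_reproduces_cube(self):
        cube = build_cube()
        net, _ = unfold_cube_to_sheet(cube)
        back = refold_sheet_to_cube(net)
        lut = {lab: i for i, lab in enumerate(back.labels)}
        for i, lab in enumerate(cube.labels):
            j = lut[lab]
            assert np.abs(back.translations[j] - cube.translations[i]).max() < 1e-6
            assert np.abs(back.rotations[j] - cube.rotations[i]).max() < 1e-6

    def test_cts1_rotation_is_cube_diagonal_angle(self):
        _, report = unfold_cube_to_sheet(build_cube())
        assert report["cts1_rotation_deg"] == pytest.approx(np.degrees(np.arccos(1 / np.sqrt(3))))
        assert report["cts1_rotation_deg"] == pytest.approx(55.0, abs=0.5)

    def test_non_cube_input_rejected(self):
        with pytest.raises(ValueError, match="cube"):
            unfold_cube_to_sheet(build_sheet(n=2, m=2))


class TestSegmentsAndLinkers:
    def test_segment_ranges_validated(self):
        with pytest.raises(ValueError):
            SegmentMap(cts1=(611, 590))
        with pytest.raises(ValueError):
            SegmentMap(linker1=(582, 595))  # overlaps CTS1

    def test_linker_lengths_and_extension_bound(self):
        seg = SegmentMap()
        assert seg.linker_residues(1) == 8
        assert seg.linker_residues(2) == 10
        assert seg.max_extension(1) == pytest.approx(28.0)

    def test_identical_anchors_span_zero_and_345_triangle(self):
        unit = TetramerUnit()
        anchors = {k: {"CTD_end": np.zeros(3), "CTS1_start": np.zeros(3),
                       "CTS1_end": np.array([0.0, 0.0, 0.0]),
                       "CTS2_start": np.array([30.0, 40.0, 0.0])} for k in range(4)}
        df = linker_spans(build_sheet(unit, 1, 1), anchors=anchors)
        assert np.allclose(df["linker1_span_A"], 0.0)
        assert np.allclose(df["linker2_span_A"], 50.0)

    def test_default_anchor_spans_within_extension_bound(self):
        seg = SegmentMap()
        for model in (build_sheet(n=2, m=2), build_cube()):
            df = linker_spans(model, seg)
            assert (df["linker1_span_A"] <= seg.max_extension(1)).all()
            assert (df["linker2_span_A"] <= seg.max_extension(2)).all()

    def test_missing_anchor_gives_nan(self):
        anchors = {0: {"CTD_end": np.zeros(3)}}  # CTS1_start absent
        df = linker_spans(build_sheet(n=1, m=1), anchors=anchors)
        assert np.isnan(df.loc[df.protomer == 0, "linker1_span_A"]).all()


class TestSymmetryExpand:
    def test_single_record_o_to_c4_gives_six(self):
        t = random_table(1, seed=3)
        assert len(symmetry_expand(t, "O", "C4")) == 6

    def test_expansion_factors_exact_for_generic_orientations(self):
        t = random_table(250, seed=4)
        assert len(symmetry_expand(t, "O", "C4")) == 250 * 6
        assert len(symmetry_expand(t, "C4", "C1")) == 250 * 4

    def test_replicates_have_distinct_tilt_psi(self):
        t = random_table(20, seed=5)
        out = symmetry_expand(t, "O", "C4")
        src = out.extras["_slSourceId"].to_numpy()
        for sid in np.unique(src):
            sub = out.eulers[src == sid][:, 1:]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    assert np.abs(sub[i] - sub[j]).max() > 1e-4

    def test_expand_then_collapse_returns_original(self):
        t = random_table(40, seed=6)
        out = symmetry_expand(t, "C4", "C1")
        src = out.extras["_slSourceId"].to_numpy()
        # first replicate of each source is the identity coset representative
        firsts = [np.flatnonzero(src == sid)[0] for sid in t.ids]
        assert np.allclose(out.eulers[firsts], t.eulers, atol=1e-9)
        assert np.allclose(out.positions[firsts], t.positions)

    def test_subgroup_validation(self):
        t = random_table(2, seed=0)
        with pytest.raises(ValueError):
            symmetry_expand(t, "C4", "O")
        with pytest.raises(ValueError):
            symmetry_expand(t, "C4", "C4")

    def test_mass_conservation_invariant(self):
        for model in (build_sheet(n=4, m=2), build_cube(), build_prism()):
            assert model.mass_kda == pytest.approx(len(model) * 4 * model.unit.protomer_mass_kda)

    def test_duplicate_placements_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AssemblyModel(unit=TetramerUnit(), rotations=np.stack([np.eye(3)] * 2),
                          translations=np.zeros((2, 3)), topology="custom", symmetry="none")
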