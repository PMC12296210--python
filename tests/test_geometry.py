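import math

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

import nmrcell as nc
from nmrcell.geometry import (
    CellDesign,
    MeshExportError,
    UnsupportedGeometryError,
    _shell_mesh_parametric,
)


class TestVoxelGrid:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            nc.VoxelGrid((3, 8, 8), (0.1,) * 3, (0, 0, 0))
        with pytest.raises(ValueError):
            nc.VoxelGrid((8, 8, 8), (0.1, -0.1, 0.1), (0, 0, 0))

    def test_coordinates_reproducible(self):
        g = nc.VoxelGrid((8, 8, 16), (0.1, 0.1, 0.2), (-0.35, -0.35, -1.0))
        z = g.axis_coords(2)
        assert z[0] == -1.0 and np.allclose(np.diff(z), 0.2)
        assert g.index_of((-0.35, -0.35, -1.0)) == (0, 0, 0)
        assert g.voxel_volume_ul == pytest.approx(0.002)

    def test_interface_alignment(self):
        g = nc.VoxelGrid.for_interface((16, 16, 32), 0.1, fraction_below=0.5)
        z = g.axis_coords(2)
        # voxel edge exactly at z = 0: nearest centers at +-spacing/2
        assert np.min(np.abs(z)) == pytest.approx(0.05)


class TestAnalyticVolume:
    @pytest.mark.parametrize("shape,expected", [
        # access channel from measured print dimensions: ~11 uL
        (nc.Cylinder(0.65, 0.0, 8.5), 11.28),
        # 3.3 x 23 mm ellipsoid
        (nc.Ellipsoid((0, 0, 0), (1.65, 1.65, 11.5)), 131.1),
        # unit sphere
        (nc.Ellipsoid((0, 0, 0), (1.0, 1.0, 1.0)), 4.18879),
    ])
    def test_closed_forms(self, shape, expected):
        assert nc.analytic_volume(shape) == pytest.approx(expected, abs=0.05)

    def test_disjoint_union_adds(self):
        u = nc.Union((nc.Cylinder(0.5, 0.0, 2.0),
                      nc.Ellipsoid((0, 0, 5.0), (1, 1, 1))))
        expected = math.pi * 0.25 * 2 + 4 / 3 * math.pi
        assert nc.analytic_volume(u) == pytest.approx(expected)

    def test_overlapping_union_unsupported(self):
        u = nc.Union((nc.Cylinder(0.5, 0.0, 2.0),
                      nc.Ellipsoid((0, 0, 1.0), (1, 1, 1))))
        with pytest.raises(UnsupportedGeometryError):
            nc.analytic_volume(u)

    def test_half_space_unsupported(self):
        with pytest.raises(UnsupportedGeometryError):
            nc.analytic_volume(nc.HalfSpace(0.0))


class TestVoxelize:
    def test_uniform_scene_constant(self):
        g = nc.VoxelGrid((6, 6, 6), (0.2,) * 3, (0, 0, 0))
        scene = nc.Scene(background_chi=-9.01)
        m = nc.voxelize(scene, g)
        assert np.all(m.chi == -9.01)

    def test_half_space_boundary_voxel_half_filled(self):
        g = nc.VoxelGrid((4, 4, 5), (0.1,) * 3, (-0.15, -0.15, -0.2))
        scene = nc.Scene(background_chi=0.0).add(nc.HalfSpace(0.0), 1.0)
        m = nc.voxelize(scene, g, supersampling=2)
        k = g.index_of((0, 0, 0))
        assert m.chi[k] == pytest.approx(0.5)
        assert m.chi[:, :, 0].mean() == pytest.approx(1.0)
        assert m.chi[:, :, -1].mean() == pytest.approx(0.0)

    def test_sphere_volume_within_one_percent(self):
        g = nc.VoxelGrid.centered((2.6, 2.6, 2.6), 0.1)
        scene = nc.Scene(background_chi=0.0).add(
            nc.Ellipsoid((0, 0, 0), (1, 1, 1)), 1.0)
        m = nc.voxelize(scene, g, supersampling=3)
        vol = m.chi.sum() * g.voxel_volume_ul
        assert vol == pytest.approx(4 / 3 * math.pi, rel=0.01)

    def test_under_resolved_feature_warns(self):
        g = nc.VoxelGrid((8, 8, 8), (0.5,) * 3, (0, 0, 0))
        scene = nc.Scene().add(nc.Ellipsoid((1, 1, 1), (0.3, 0.3, 0.3)), 1.0)
        with pytest.warns(UserWarning, match="under-resolved"):
            nc.voxelize(scene, g, supersampling=1)

    @given(st.permutations(range(3)))
    def test_painting_nonoverlapping_shapes_is_order_free(self, order):
        shapes = [(nc.Ellipsoid((0, 0, -1.2), (0.4, 0.4, 0.4)), 1.0),
                  (nc.Ellipsoid((0, 0, 0.0), (0.4, 0.4, 0.4)), 2.0),
                  (nc.Cylinder(0.4, 0.8, 1.6), 3.0)]
        g = nc.VoxelGrid.centered((1.6, 1.6, 4.0), 0.2)
        base = nc.voxelize(nc.Scene(list(shapes), 0.0), g, supersampling=2)
        perm = nc.voxelize(nc.Scene([shapes[i] for i in order], 0.0), g,
                           supersampling=2)
        np.testing.assert_array_equal(base.chi, perm.chi)


class TestPresets:
    def test_shigemi_two_regions_over_background(self):
        scene = nc.build_preset_scene("shigemi", chi_glass=-9.075,
                                      chi_solvent=-9.011)
        assert len(scene.regions) == 2
        chis = {chi for _, chi in scene.regions}
        assert chis == {-9.075, -9.011}
        # interface at z = 0: glass below, solvent above
        pts = np.array([[0, 0, -1.0], [0, 0, 1.0], [3.0, 0, 1.0]])
        assert list(scene.paint(pts)) == [-9.075, -9.011, scene.background_chi]

    def test_microcell_channel_toggle(self):
        no_chan = nc.build_preset_scene("microcell", chi_solvent=-9.011,
                                        chi_resin=-9.40, channel=False)
        assert len(no_chan.regions) == 2
        # center and tip: solvent; inside the 0.3 mm wall: resin
        pts = np.array([[0, 0, 0.0], [0, 0, 11.4], [0, 0, 11.65]])
        assert list(no_chan.paint(pts)) == [-9.011, -9.011, -9.40]
        # above the shell: background
        assert no_chan.paint(np.array([[0, 0, 15.0]]))[0] == no_chan.background_chi
        with_chan = nc.build_preset_scene("microcell", chi_solvent=-9.011,
                                          chi_resin=-9.40, channel=True)
        # the bore keeps solvent above the ellipsoid tip
        assert with_chan.paint(np.array([[0, 0, 13.0]]))[0] == -9.011

    def test_plug_matched_media_is_uniform_inside(self):
        preset = nc.build_preset("plug_in_tube", chi_resin=-9.011,
                                 chi_solvent=-9.011)
        g = nc.VoxelGrid.for_interface((16, 16, 48), 0.3, fraction_below=0.5)
        m = nc.voxelize(preset.scene, g, supersampling=2)
        mref = nc.voxelize(preset.shim_reference, g, supersampling=2)
        f = nc.differential_field(m, mref)
        assert np.max(np.abs(f.offset_ppm)) < 1e-12

    def test_unknown_preset_and_missing_chi(self):
        with pytest.raises(ValueError, match="unknown preset"):
            nc.build_preset("sphere_flask", chi_solvent=-9.0)
        with pytest.raises(ValueError, match="parameters"):
            nc.build_preset("shigemi", chi_solvent=-9.0)


class TestCellDesign:
    def test_printed_channel_volume_is_11_ul(self):
        d = CellDesign()
        assert d.channel_volume_ul == pytest.approx(11.28, abs=0.005)
        assert round(d.channel_volume_ul) == 11

    def test_total_volume_composition(self):
        d = CellDesign()
        assert d.total_volume_ul == pytest.approx(
            d.ellipsoid_volume_ul + d.channel_volume_ul - d.overlap_volume_ul)
        assert 0 < d.overlap_volume_ul < d.channel_volume_ul
        no_chan = CellDesign(with_channel=False)
        assert no_chan.total_volume_ul == pytest.approx(no_chan.ellipsoid_volume_ul)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            CellDesign(wall_thickness=0.0)
        with pytest.raises(ValueError):
            CellDesign(semi_axes=(1.65, -1.65, 11.5))
        with pytest.raises(ValueError):
            CellDesign(channel_diameter=4.0)  # bore wider than cavity


class TestExportStl:
    ANALYTIC_SHELL = 4 / 3 * math.pi * (2.5 ** 3 - 2.0 ** 3)

    def test_sphere_shell_volume_within_2pct_at_10k_facets(self):
        d = CellDesign(semi_axes=(2.0, 2.0, 2.0), wall_thickness=0.5,
                       with_channel=False)
        mesh = nc.export_stl(d, facet_count=10_000)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(self.ANALYTIC_SHELL, rel=0.02)

    def test_volume_error_decreases_monotonically(self):
        d = CellDesign(semi_axes=(2.0, 2.0, 2.0), wall_thickness=0.5,
                       with_channel=False)
        errs = [abs(nc.export_stl(d, facet_count=fc).volume
                    - self.ANALYTIC_SHELL) / self.ANALYTIC_SHELL
                for fc in (64, 640, 2560, 10_240)]
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_default_microcell_roundtrips_and_is_watertight(self, tmp_path):
        path = tmp_path / "cell.stl"
        mesh = nc.export_stl(CellDesign(), facet_count=4000, path=path)
        assert mesh.is_watertight
        loaded = trimesh.load(path)
        assert len(loaded.faces) == len(mesh.faces)
        # binary STL: 80-byte header + 4-byte count + 50 bytes/facet
        assert path.stat().st_size == 84 + 50 * len(mesh.faces)
        # solid volume: shell + neck wall, bracketed by shell alone and
        # shell + full neck tube
        d = CellDesign()
        shell = 4 / 3 * math.pi * (np.prod(d.outer_semi_axes)
                                   - np.prod(d.semi_axes))
        assert shell < mesh.volume < shell + 25.0

    def test_facet_count_floor(self):
        with pytest.raises(ValueError):
            nc.export_stl(CellDesign(with_channel=False), facet_count=32)

    def test_parametric_mesh_face_budget(self):
        d = CellDesign(semi_axes=(1, 1, 1), wall_thickness=0.2,
                       with_channel=False)
        mesh = _shell_mesh_parametric(d, 640)
        assert len(mesh.faces) <= 640
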