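import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nmrcell as nc
from conftest import HALF_CONTRAST, bulk_slice_value, interface_slice_edge


def uniform_map(grid, chi=0.0, background=0.0):
    return nc.SusceptibilityMap(grid, np.full(grid.shape, chi), background)


class TestForwardFieldFFT:
    def test_zero_contrast_gives_zero_field(self):
        g = nc.VoxelGrid((8, 8, 8), (0.1,) * 3, (0, 0, 0))
        f = nc.forward_field_fft(uniform_map(g, chi=-9.01, background=-9.01))
        assert np.max(np.abs(f.offset_ppm)) == 0.0

    def test_long_cylinder_interior_is_third_of_contrast(self):
        # length 24 mm = 20x diameter, contrast 0.3 ppm
        g = nc.VoxelGrid.centered((4.8, 4.8, 28.8), 0.15)
        scene = nc.Scene(background_chi=0.0).add(
            nc.Cylinder(0.6, -12.0, 12.0), 0.3)
        f = nc.forward_field_fft(nc.voxelize(scene, g, 3))
        mid = f.at((0.075, 0.075, 0.075))
        far = f.at((-2.25, 0.075, 0.075))
        assert mid - far == pytest.approx(0.1, abs=0.005)

    def test_sphere_interior_offset_vanishes(self):
        g = nc.VoxelGrid.centered((3.8, 3.8, 3.8), 0.1)
        scene = nc.Scene(background_chi=0.0).add(
            nc.Ellipsoid((0, 0, 0), (1, 1, 1)), 1.0)
        f = nc.forward_field_fft(nc.voxelize(scene, g, 3))
        assert abs(f.at((0.05, 0.05, 0.05))
                   - f.at((-1.85, -1.85, -1.85))) < 1e-4

    def test_non_cubic_voxels_rejected_unless_enabled(self):
        g = nc.VoxelGrid((8, 8, 8), (0.1, 0.1, 0.2), (0, 0, 0))
        m = uniform_map(g)
        with pytest.raises(ValueError, match="non-cubic"):
            nc.forward_field_fft(m)
        nc.forward_field_fft(m, anisotropic_ok=True)  # does not raise

    def test_continuous_kernel_agrees_on_smooth_geometry(self):
        g = nc.VoxelGrid.centered((4.8, 4.8, 28.8), 0.15)
        scene = nc.Scene(background_chi=0.0).add(
            nc.Cylinder(0.6, -12.0, 12.0), 0.3)
        m = nc.voxelize(scene, g, 3)
        fd = nc.forward_field_fft(m, kernel="discrete")
        fc = nc.forward_field_fft(m, kernel="continuous")
        d_disc = fd.at((0.075,) * 3) - fd.at((-2.25, 0.075, 0.075))
        d_cont = fc.at((0.075,) * 3) - fc.at((-2.25, 0.075, 0.075))
        assert d_disc == pytest.approx(d_cont, abs=0.005)


class TestDirectOracle:
    def test_single_voxel_matches_point_dipole_on_axis(self):
        g = nc.VoxelGrid((8, 8, 24), (0.1,) * 3, (0, 0, 0))
        chi = np.zeros(g.shape)
        chi[4, 4, 4] = 1.0
        m = nc.SusceptibilityMap(g, chi, 0.0)
        r = 1.0  # 10 voxel sizes above the source
        val = nc.forward_field_direct(m, [(0.4, 0.4, 0.4 + r)])[0]
        expected = 2.0 * g.voxel_volume_ul / (4 * math.pi * r ** 3)
        assert val == pytest.approx(expected, rel=0.01)

    def test_empty_map_gives_zeros(self):
        g = nc.VoxelGrid((8, 8, 8), (0.1,) * 3, (0, 0, 0))
        out = nc.forward_field_direct(uniform_map(g), [(0, 0, 0), (1, 1, 1)])
        assert np.all(out == 0.0)

    def test_fft_equals_direct_summation_on_random_map(self):
        rng = np.random.default_rng(2024)
        g = nc.VoxelGrid((32, 32, 32), (0.1,) * 3, (0, 0, 0))
        m = nc.SusceptibilityMap(g, rng.normal(0.0, 1.0, g.shape), 0.0)
        fft = nc.forward_field_fft(m)
        idx = np.stack(np.meshgrid(*[np.arange(0, 32, 4)] * 3,
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        pts = idx * 0.1
        direct = nc.forward_field_direct(m, pts)
        assert np.max(np.abs(direct - fft.offset_ppm[idx[:, 0], idx[:, 1],
                                                     idx[:, 2]])) <= 1e-3


class TestInterfaceClosedForm:
    def test_limits(self):
        assert nc.interface_offset_on_axis(-9.075, -9.011, 0.0, 2.1) == \
            pytest.approx(HALF_CONTRAST)
        assert nc.interface_offset_on_axis(-9.075, -9.011, 1e6, 2.1) == \
            pytest.approx(0.0, abs=1e-9)
        # h = R: (dchi/2)(1 - 1/sqrt(2))
        dchi = 0.4
        assert nc.interface_offset_on_axis(0.4, 0.0, 2.1, 2.1) == \
            pytest.approx(dchi / 2 * (1 - 1 / math.sqrt(2)))

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            nc.interface_offset_on_axis(0, 1, -0.1, 1.0)
        with pytest.raises(ValueError):
            nc.interface_offset_on_axis(0, 1, 0.1, 0.0)

    def test_matches_fft_solver_along_axis(self):
        # semi-infinite-ish cylinder: R = 0.5 mm, 10 mm deep, contrast 1
        g = nc.VoxelGrid.for_interface((48, 48, 384), 0.05,
                                       fraction_below=0.55)
        scene = nc.Scene(background_chi=0.0).add(
            nc.Cylinder(0.5, -10.0, 0.0), 1.0)
        f = nc.forward_field_fft(nc.voxelize(scene, g, 3))

        def closed(h):  # finite length: difference of two open ends
            return (nc.interface_offset_on_axis(1.0, 0.0, h, 0.5)
                    - nc.interface_offset_on_axis(1.0, 0.0, h + 10.0, 0.5))

        for h in (0.075, 0.125, 0.275, 0.525, 1.025, 2.025, 2.475):
            assert f.at((0.025, 0.025, h)) == pytest.approx(closed(h), rel=0.05)


class TestDemagnetizingFactors:
    def test_sphere_is_isotropic(self):
        assert nc.demagnetizing_factors(1, 1, 1) == pytest.approx((1 / 3,) * 3)

    def test_microcell_spheroid(self):
        na, nb, nc_ = nc.demagnetizing_factors(1.65, 1.65, 11.5)
        assert nc_ == pytest.approx(0.0348, abs=5e-4)
        assert nc_ == pytest.approx(
            nc.prolate_demagnetizing_factor(1.65, 11.5), abs=1e-12)
        assert na == pytest.approx(nb)

    def test_needle_limit(self):
        _, _, nc_ = nc.demagnetizing_factors(1.0, 1.0, 1e5)
        assert nc_ < 1e-8

    @given(st.tuples(*[st.floats(0.05, 50.0) for _ in range(3)]))
    def test_factors_sum_to_one(self, axes):
        assert sum(nc.demagnetizing_factors(*axes)) == pytest.approx(
            1.0, abs=1e-10)


class TestEllipsoidInteriorOffset:
    def test_sphere_insensitive_to_mismatch(self):
        assert nc.ellipsoid_interior_offset(-9.0, -12.0, (1, 1, 1)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matched_media_zero(self):
        assert nc.ellipsoid_interior_offset(-9.4, -9.4, (1.65, 1.65, 11.5)) == 0.0

    def test_microcell_uniform_shift(self):
        val = nc.ellipsoid_interior_offset(-9.011, -9.40, (1.65, 1.65, 11.5))
        assert val == pytest.approx((1 / 3 - 0.0348) * 0.389, abs=2e-4)


class TestShigemiForwardModel:
    def test_interface_minus_bulk_reproduces_flux_average(self, shigemi_sim):
        delta = (interface_slice_edge(shigemi_sim)
                 - bulk_slice_value(shigemi_sim, h=13.0))
        assert delta == pytest.approx(HALF_CONTRAST, rel=0.10)
        assert delta < 0  # upfield: glass more diamagnetic than solvent

    def test_far_field_converges_to_bulk(self, shigemi_sim):
        # beyond ~5 tube diameters the offset is gone at the 1e-3 level
        assert abs(bulk_slice_value(shigemi_sim, h=16.0)) < 1e-3


class TestMicrocellField:
    def test_interior_uniformity_and_channel_perturbation(self, microcell_sims):
        from conftest import microcell_interior_mask

        grid = microcell_sims["grid"]
        interior = microcell_interior_mask(grid)
        analytic = nc.ellipsoid_interior_offset(
            microcell_sims["chi_solvent"], microcell_sims["chi_resin"],
            (1.65, 1.65, 11.5))
        vals = microcell_sims[False]["field"].offset_ppm[interior]
        assert vals.mean() == pytest.approx(analytic, rel=0.02)
        assert vals.std() <= 0.02 * abs(analytic)
        vals_chan = microcell_sims[True]["field"].offset_ppm[interior]
        assert vals_chan.std() > vals.std()
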