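import numpy as np
import pytest

from boldsim import fieldmap as fm
from boldsim.config import SimulationConfig
from boldsim.geometry import (Cylinder, VesselNetwork, Voxel, Z_AXIS,
                              generate_network_2d, grid_centers_1d,
                              single_vessel_network, voxelize_mask)

DCHI, B0 = 4.15e-7, 3.0
MAGIC = np.arccos(1 / np.sqrt(3))        # 54.7356 deg, 3cos^2-1 = 0


def make_cylinder(theta_b, phi_b=0.0, radius=2.0):
    return Cylinder(anchor=np.zeros(3), axis=Z_AXIS.copy(), radius=radius,
                    theta_b=theta_b, phi_b=phi_b)


class TestCylinderOffset:
    def test_interior_parallel(self):
        c = make_cylinder(theta_b=0.0)
        off = fm.cylinder_offset([0.5, 0.0], c, DCHI, B0)
        assert off == pytest.approx(DCHI * B0 / 3)
        assert off / B0 * 1e9 == pytest.approx(138.3, abs=0.05)

    def test_interior_magic_angle_zero(self):
        c = make_cylinder(theta_b=MAGIC)
        assert fm.cylinder_offset([0.0, 0.0], c, DCHI, B0) == \
            pytest.approx(0.0, abs=1e-20)

    def test_exterior_perpendicular(self):
        c = make_cylinder(theta_b=np.pi / 2, phi_b=0.0)
        off = fm.cylinder_offset([2 * c.radius, 0.0], c, DCHI, B0)
        assert off == pytest.approx(DCHI * B0 / 8)
        assert off / B0 * 1e9 == pytest.approx(51.9, abs=0.05)

    def test_exterior_45deg_zero(self):
        c = make_cylinder(theta_b=np.pi / 2, phi_b=0.0)
        r = 3.0 / np.sqrt(2)
        assert fm.cylinder_offset([r, r], c, DCHI, B0) == \
            pytest.approx(0.0, abs=1e-22)

    def test_on_axis_uses_interior_branch(self):
        c = make_cylinder(theta_b=0.0)
        assert fm.cylinder_offset([0.0, 0.0], c, DCHI, B0) == \
            pytest.approx(DCHI * B0 / 3)

    def test_3d_global_axis(self):
        """A cylinder along x with B0 along z is a perpendicular vessel."""
        c = Cylinder(anchor=np.zeros(3), axis=np.array([1.0, 0, 0]),
                     radius=1.0)
        off = fm.cylinder_offset([0.0, 0.0, 2.0], c, DCHI, B0)
        assert off == pytest.approx(0.5 * DCHI * B0 / 4)

    def test_exterior_annulus_integrates_to_zero(self):
        c = make_cylinder(theta_b=np.pi / 2)
        phis = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        vals = [fm.cylinder_offset([4 * np.cos(p), 4 * np.sin(p)], c,
                                   DCHI, B0) for p in phis]
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-18)


class TestFieldAtPoint:
    def test_empty_network_zero(self):
        net = VesselNetwork(voxel=Voxel(2, 50.0), vessels=[],
                            blood_volume_fraction=0.0)
        assert fm.field_at_point(net, [1.0, 1.0], SimulationConfig()) == 0.0

    def test_single_vessel_matches_cylinder_offset(self):
        net = single_vessel_network(100.0, 2.0, np.pi / 3)
        cfg = SimulationConfig()
        p = [5.0, 3.0]
        assert fm.field_at_point(net, p, cfg, wrap=False) == pytest.approx(
            fm.cylinder_offset(p, net.vessels[0], cfg.delta_chi, cfg.b0),
            rel=1e-12)

    def test_linear_superposition(self):
        cfg = SimulationConfig()
        v1 = make_cylinder(np.pi / 2, 0.0)
        v2 = Cylinder(anchor=np.array([10.0, 0, 0]), axis=Z_AXIS.copy(),
                      radius=2.0, theta_b=np.pi / 2, phi_b=0.0)
        net = VesselNetwork(voxel=Voxel(2, 80.0), vessels=[v1, v2],
                            blood_volume_fraction=0.01)
        p = [5.0, 0.0]   # symmetric between the two parallel vessels
        single = fm.cylinder_offset(p, v1, cfg.delta_chi, cfg.b0)
        assert fm.field_at_point(net, p, cfg, wrap=False) == pytest.approx(
            2 * single, rel=1e-12)

    def test_wrapped_images_contribute(self):
        """With the minimum-image convention a vessel near one edge is felt
        from the opposite edge."""
        cfg = SimulationConfig()
        L = 60.0
        v = Cylinder(anchor=np.array([L / 2 - 1.0, 0, 0]),
                     axis=Z_AXIS.copy(), radius=1.0, theta_b=np.pi / 2,
                     phi_b=0.0)
        net = VesselNetwork(voxel=Voxel(2, L), vessels=[v],
                            blood_volume_fraction=0.001)
        p = [-L / 2 + 1.0, 0.0]     # 2 um from the wrapped image
        wrapped = fm.field_at_point(net, p, cfg, wrap=True)
        v0 = Cylinder(anchor=np.zeros(3), axis=Z_AXIS.copy(), radius=1.0,
                      theta_b=np.pi / 2, phi_b=0.0)
        image_off = fm.cylinder_offset([2.0, 0.0], v0, cfg.delta_chi, cfg.b0)
        assert wrapped == pytest.approx(image_off, rel=1e-12)


class TestGriddedAnalytic:
    def test_grid_equals_continuous_at_cell_centres(self, net2d, config):
        grid = fm.field_on_grid_analytic(net2d, 32, config)
        c = grid_centers_1d(net2d.voxel.edge_length, 32)
        ev = fm.analytic_field(net2d, config)
        pts = np.array([[c[3], c[17], 0.0], [c[0], c[0], 0.0]])
        assert grid.offsets[3, 17] == pytest.approx(ev.at(pts)[0])
        assert grid.offsets[0, 0] == pytest.approx(ev.at(pts)[1])

    def test_nearest_neighbour_lookup(self, net2d, config):
        grid = fm.field_on_grid_analytic(net2d, 32, config)
        c = grid_centers_1d(net2d.voxel.edge_length, 32)
        # a point slightly off a cell centre maps onto that cell
        val = grid.at(np.array([[c[5] + 0.1 * grid.spacing, c[9]]]))[0]
        assert val == grid.offsets[5, 9]


class TestDipoleKernel:
    def test_axis_values(self):
        k = fm.dipole_kernel_k((8, 8, 8), 1.0, b0=3.0)
        assert k[0, 0, 1] == pytest.approx(-2.0 / 3.0 * 3.0)   # k along z
        assert k[1, 0, 0] == pytest.approx(3.0 / 3.0)          # transverse
        assert k[0, 0, 0] == 0.0

    def test_requires_3d(self):
        with pytest.raises(ValueError):
            fm.dipole_kernel_k((8, 8), 1.0)


class TestFieldFFT:
    def test_uniform_mask_zero_field(self):
        f = fm.field_fft(np.ones((16, 16, 16), dtype=bool), 16.0, DCHI, B0)
        assert np.max(np.abs(f.offsets)) < 1e-25

    def test_sphere_interior_mean_zero(self):
        n, L = 80, 80.0
        c = grid_centers_1d(L, n)
        xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
        mask = xx ** 2 + yy ** 2 + zz ** 2 <= (L / 4) ** 2
        f = fm.field_fft(mask, L, DCHI, B0)
        interior = xx ** 2 + yy ** 2 + zz ** 2 <= (0.8 * L / 4) ** 2
        assert abs(f.offsets[interior].mean()) < 0.02 * DCHI * B0

    def test_parallel_cylinder_matches_closed_form(self):
        """A z-spanning cylinder (B0 parallel): interior mean is the
        analytic dchi*B0/3 and the exterior vanishes (up to the zero-mean
        convention, which shifts both by the small mask fraction)."""
        L, R, n = 64.0, 4.0, 64
        c = grid_centers_1d(L, n)
        xx, yy = np.meshgrid(c, c, indexing="ij")
        circ = xx ** 2 + yy ** 2 <= R ** 2
        mask = np.repeat(circ[:, :, None], n, axis=2)
        f = fm.field_fft(mask, L, DCHI, B0)
        interior = f.offsets[circ].mean()
        exterior = f.offsets[~circ].mean()
        assert interior == pytest.approx(DCHI * B0 / 3, rel=0.05)
        assert abs(exterior) < 0.02 * DCHI * B0 / 3
        # the interior-exterior contrast is exact for z-invariant masks
        assert interior - exterior == pytest.approx(DCHI * B0 / 3, rel=1e-9)

    def test_transverse_cylinder_error_halves_with_resolution(self):
        """For a cylinder perpendicular to B0 the discrete dipole field
        converges on the analytic one as the grid is refined."""
        L, R = 64.0, 4.0
        cyl = Cylinder(anchor=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]),
                       radius=R)
        errs = {}
        for n in (32, 64, 128):
            c = grid_centers_1d(L, n)
            yy, zz = np.meshgrid(c, c, indexing="ij")
            circ = yy ** 2 + zz ** 2 <= R ** 2
            mask = np.broadcast_to(circ[None, :, :], (n, n, n))
            f = fm.field_fft(mask, L, DCHI, B0)
            # probe a ring of exterior points in the near field
            phis = np.linspace(0, 2 * np.pi, 16, endpoint=False)
            pts = np.column_stack([np.zeros(16), 2 * R * np.cos(phis),
                                   2 * R * np.sin(phis)])
            got = f.at(pts)
            want = np.array([fm.cylinder_offset(p, cyl, DCHI, B0)
                             for p in pts])
            errs[n] = np.sqrt(np.mean((got - want) ** 2))
        assert errs[64] < errs[32]
        assert errs[128] < 0.7 * errs[32]


class TestThreeB0:
    def test_iv_self_offset_exactly_zero(self):
        cfg = SimulationConfig()
        edge, radius = 40.0, 2.0
        net = generate_network_2d(edge, radius, np.pi * 4 / 1600,
                                  np.random.default_rng(0),
                                  field_mode="three_B0")
        centre = net.vessels[0].anchor[:2]
        assert fm.three_b0_field(net, centre, cfg) == pytest.approx(
            0.0, abs=1e-25)

    def test_ev_offset_is_two_thirds_perpendicular(self):
        cfg = SimulationConfig()
        net = single_vessel_network(100.0, 2.0, np.pi / 2)
        p = [6.0, 1.0]
        got = fm.field_at_point(net, p, cfg, mode="three_b0", wrap=False)
        perp = fm.cylinder_offset(p, net.vessels[0], cfg.delta_chi, cfg.b0,
                                  b0_direction=[1.0, 0.0, 0.0])
        assert got == pytest.approx(2.0 / 3.0 * perp, rel=1e-12)

    def test_ev_45deg_to_reference_zero(self):
        cfg = SimulationConfig()
        net = single_vessel_network(100.0, 2.0, np.pi / 2)
        r = 5.0 / np.sqrt(2)
        assert fm.field_at_point(net, [r, r], cfg, mode="three_b0",
                                 wrap=False) == pytest.approx(0.0, abs=1e-22)


class TestHistograms:
    def test_zero_susceptibility_delta_at_zero(self):
        centers, dens = fm.histogram_ppb(np.zeros(1000), B0)
        assert centers[np.argmax(dens)] == pytest.approx(0.0, abs=0.5)
        assert dens.sum() * 1.0 == pytest.approx(1.0)

    def test_compartment_histograms_unit_area(self, net2d, config):
        grid = fm.field_on_grid_analytic(net2d, 128, config)
        mask = voxelize_mask(net2d, 128)
        h = fm.field_histogram(grid, mask)
        for name in ("total", "ev", "iv"):
            centers, dens = h[name]
            width = centers[1] - centers[0]
            assert dens.sum() * width == pytest.approx(1.0, abs=0.02)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            fm.histogram_ppb(np.zeros(10), B0, bin_width=0.0)

    def test_average_histograms_shapes(self, net2d, config):
        grid = fm.field_on_grid_analytic(net2d, 64, config)
        mask = voxelize_mask(net2d, 64)
        h = fm.field_histogram(grid, mask)
        avg = fm.average_histograms([h, h])
        centers, mean, sd = avg["iv"]
        assert mean == pytest.approx(h["iv"][1])
        assert np.all(sd == 0.0)
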