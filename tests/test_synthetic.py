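import math
import warnings

import numpy as np
import pytest

from hemoflow.network import network_volume
from hemoflow.synthetic import (
    GenerationError,
    GeneratorParams,
    ImageVolume,
    LabelVolume,
    generate_network,
    render_confocal,
    voxelize,
)

from conftest import DEFAULT_SPACING, single_tube


class TestGenerator:
    def test_determinism_byte_identical(self):
        a = generate_network(seed=3)
        b = generate_network(seed=3)
        assert a.to_json() == b.to_json()
        assert generate_network(seed=4).to_json() != a.to_json()

    def test_invariants_hold(self, default_network):
        default_network.validate()  # includes capillary <= 7 µm, connectivity, slab bounds
        assert default_network.has_inlet_outlet_path()
        assert len(default_network.inlets()) == 3
        assert len(default_network.outlets()) == 3

    def test_capillary_diameters_bounded(self, default_network):
        caps = [s for s in default_network.segments if s.vessel_class == "capillary"]
        assert caps and all(2 * s.radius <= 7.0 + 1e-9 for s in caps)

    def test_monotone_trunk_taper(self, default_network):
        # order-1 chains taper from root to tip within each tree
        net = default_network
        for root in net.inlets() + net.outlets():
            radius_by_depth = []
            node, prev, depth = root, None, 0
            adj = {}
            for s in net.segments:
                if s.vessel_class.endswith("_1"):
                    adj.setdefault(s.a, []).append(s)
                    adj.setdefault(s.b, []).append(s)
            while True:
                nxt = [s for s in adj.get(node, []) if (s.b if s.a == node else s.a) != prev]
                if not nxt:
                    break
                s = nxt[0]
                radius_by_depth.append(s.radius)
                prev, node = node, (s.b if s.a == node else s.a)
            assert radius_by_depth == sorted(radius_by_depth, reverse=True)

    def test_rat_scale_defaults(self, default_network):
        assert default_network.extents == (2300.0, 2300.0, 60.0)

    def test_degenerate_single_bridge(self):
        params = GeneratorParams(
            n_arteriole_trees=1,
            n_venule_trees=1,
            trunk_inner_radius=100.0,
            trunk_outer_radius=100.0,  # zero trunk steps: roots are the tips
            branches_per_trunk=0,
            mesh_keep_prob=0.0,
            adapt_iterations=0,
        )
        net = generate_network(params, seed=1)
        assert net.n_segments == 1
        assert net.n_nodes == 2
        assert set(net.roots.values()) == {"arteriole_inlet", "venule_outlet"}

    def test_infeasible_settings_fail_loudly(self):
        # rung window too short to bridge the combs: no arteriole-venule path
        params = GeneratorParams(rung_window=(1.0, 2.0), mesh_keep_prob=0.0)
        with pytest.raises(GenerationError):
            generate_network(params, seed=1)

    def test_total_vessel_volume_reported(self, default_network):
        v = network_volume(default_network)
        manual = sum(
            math.pi * s.radius**2 * default_network.length(s) for s in default_network.segments
        )
        assert v == pytest.approx(manual, rel=1e-12) and v > 0


class TestVoxelize:
    def test_cylinder_cross_section_area(self):
        net = single_tube(radius_um=4.0, length_um=160.0)
        net.positions = {0: (20.0, 50.0, 20.0), 1: (180.0, 50.0, 20.0)}
        net.extents = (200.0, 100.0, 40.0)
        label = voxelize(net, (1.0, 1.0, 1.0))
        # per-slice labeled area vs analytic disc area πR²
        for x in (60, 100, 140):
            area = label.data[:, :, x].sum()
            assert area == pytest.approx(math.pi * 16.0, rel=0.10)

    def test_empty_network_all_zero(self):
        from hemoflow.network import VesselNetwork

        net = VesselNetwork(positions={}, segments=[], roots={}, extents=(100.0, 100.0, 20.0))
        label = voxelize(net, (2.0, 2.0, 2.0))
        assert label.data.sum() == 0

    def test_volume_converges_to_analytic(self, mini_network):
        """Voxelized volume approaches Σ πR²L as the grid refines."""
        analytic = network_volume(mini_network)
        errs = []
        for sp in ((3.0, 3.0, 1.5), (1.5, 1.5, 0.75)):
            label = voxelize(mini_network, sp)
            vox = label.data.sum() * sp[0] * sp[1] * sp[2]
            errs.append(abs(vox - analytic) / analytic)
        assert errs[1] < errs[0]
        assert errs[1] < 0.15

    def test_default_grid_matches_acquisition_geometry(self, default_network):
        # 75 axial slices over the 60 µm depth; in-plane grid spans 2.3 mm
        crop = voxelize(default_network, DEFAULT_SPACING, origin=(0, 0, 0), size=(2300.0, 2300.0, 60.0))
        nz, ny, nx = crop.shape
        assert nz == 75
        assert ny * 2.25 == pytest.approx(2300.0, rel=0.01)

    def test_coarse_spacing_warns(self):
        net = single_tube(radius_um=2.0)
        net.extents = (120.0, 20.0, 20.0)
        with pytest.warns(UserWarning, match="not be resolved"):
            voxelize(net, (5.0, 5.0, 5.0))


class TestRender:
    def test_pure_copy_without_blur_and_noise(self, crop_label):
        img = render_confocal(crop_label, psf_sigma_um=0.0, read_noise_sd=0.0, shot_noise=False, signal=150.0, background=20.0)
        assert np.array_equal((img.data - 20.0) / 150.0, crop_label.data.astype(float))

    def test_deterministic_under_seed(self, crop_label):
        a = render_confocal(crop_label, seed=9)
        b = render_confocal(crop_label, seed=9)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, render_confocal(crop_label, seed=10).data)

    def test_negative_noise_rejected(self, crop_label):
        with pytest.raises(ValueError):
            render_confocal(crop_label, read_noise_sd=-1.0)
        with pytest.raises(ValueError):
            render_confocal(crop_label, psf_sigma_um=-1.0)

    def test_otsu_recovers_vessels_from_default_rendering(self, crop_label, crop_image):
        """Plain Otsu on the default rendering already overlaps well with truth."""
        from skimage.filters import threshold_otsu

        from hemoflow.segmentation import dice

        thr = threshold_otsu(crop_image.data)
        mask = LabelVolume(data=(crop_image.data > thr).astype(np.uint8), spacing=crop_image.spacing)
        assert dice(mask, crop_label) >= 0.8


class TestVolumeContainers:
    def test_binary_enforced(self):
        with pytest.raises(ValueError):
            LabelVolume(data=np.full((4, 4, 4), 2.0), spacing=(1, 1, 1))

    def test_spacing_positive(self):
        with pytest.raises(ValueError):
            ImageVolume(data=np.zeros((4, 4, 4)), spacing=(1.0, 0.0, 1.0))

    def test_anisotropic_sigma_conversion(self):
        vol = ImageVolume(data=np.zeros((4, 4, 4)), spacing=(2.0, 2.0, 0.5))
        assert vol.sigma_voxels(2.0) == (4.0, 1.0, 1.0)  # (z, y, x) order
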