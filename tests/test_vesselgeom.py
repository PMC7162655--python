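"""Segmentation, skeleton graphs, plexus planes, diameters, group tests."""
import numpy as np
import pytest
from scipy import ndimage

from _oracles import student_t_oracle, welch_t_oracle
from retinaquant import synthgen as sg
from retinaquant import vesselgeom as vg


class TestSegmentation:
    def test_otsu_recovers_ground_truth_tube(self, plexus_scene):
        vm = vg.segment_vessels(plexus_scene["vol"], "vessels", method="otsu")
        truth_mask = plexus_scene["truth"].vessel_mask
        overlap = (vm.mask & truth_mask).sum() / truth_mask.sum()
        assert overlap >= 0.95

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="no vessels"):
            vg.segment_vessels(np.zeros((8, 8, 8)), method="otsu")

    def test_fixed_threshold_zero_keeps_everything(self):
        img = np.full((6, 6, 6), 0.2)
        vm = vg.segment_vessels(img, method="fixed_threshold", threshold=0.0)
        assert vm.mask.all()

    def test_min_component_cleanup_removes_specks(self):
        img = np.zeros((12, 12, 12))
        img[2, 2, 2] = 1.0                # single-voxel speck
        img[6:9, 2:10, 6:9] = 1.0         # solid bar
        vm = vg.segment_vessels(
            img, method="fixed_threshold", threshold=0.5, min_component_um3=5.0
        )
        assert vm.mask.sum() == 3 * 8 * 3


class TestSkeletonGraph:
    def test_straight_tube_single_edge_with_correct_length(self):
        mask = np.zeros((16, 110, 16), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[8, 4, 8], [8, 104, 8]]), 3.0)
        skel = vg.skeletonize_mask(mask, (1, 1, 1))
        edges = skel.edges()
        assert len(edges) == 1
        assert edges[0][3] == pytest.approx(100.0, abs=2.0)

    def test_y_junction_has_exactly_one_degree3_node(self):
        mask = np.zeros((16, 80, 80), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[8, 4, 40], [8, 40, 40]]), 3.0)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[8, 40, 40], [8, 74, 14]]), 3.0)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[8, 40, 40], [8, 74, 66]]), 3.0)
        skel = vg.skeletonize_mask(mask, (1, 1, 1))
        degrees = [skel.node_degree(n) for n in skel.graph.nodes]
        assert sum(d == 3 for d in degrees) == 1

    def test_isolated_blob_single_node_no_edges(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[6, 6, 6] = True
        skel = vg.skeletonize_mask(mask, (1, 1, 1))
        assert skel.graph.number_of_nodes() == 1
        assert skel.graph.number_of_edges() == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vg.skeletonize_mask(np.zeros((4, 4, 4), bool), (1, 1, 1))

    def test_anisotropic_spacing_scales_edge_length(self):
        mask = np.zeros((16, 60, 16), bool)
        mask[8, 2:58, 8] = True
        skel = vg.skeletonize_mask(mask, (2.0, 0.5, 0.5))
        assert skel.edges()[0][3] == pytest.approx(55 * 0.5, abs=1.0)


class TestPlexusPlane:
    def _skeleton_from_points(self, pts):
        class Fake:
            points_um = np.asarray(pts, float)
            spacing = (1.0, 1.0, 1.0)

        return Fake()

    def test_exact_planar_points(self, rng):
        pts = np.column_stack(
            [np.full(50, 5.0), rng.uniform(0, 40, 50), rng.uniform(0, 40, 50)]
        )
        plane = vg.fit_plexus_plane(self._skeleton_from_points(pts), (5, 20, 20), 50)
        np.testing.assert_allclose(np.abs(plane.normal), [1, 0, 0], atol=1e-9)
        assert plane.fit_residual_um == pytest.approx(0.0, abs=1e-9)

    def test_rotation_equivariance(self, rng):
        pts = np.column_stack(
            [np.zeros(60), rng.uniform(-20, 20, 60), rng.uniform(-20, 20, 60)]
        )
        a = np.deg2rad(30)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        plane = vg.fit_plexus_plane(
            self._skeleton_from_points(pts @ rot.T), (0, 0, 0), 60
        )
        expected = rot @ np.array([1.0, 0.0, 0.0])
        assert abs(plane.normal @ expected) == pytest.approx(1.0, abs=1e-9)
        assert plane.fit_residual_um == pytest.approx(0.0, abs=1e-9)

    def test_sphere_normal_within_3_degrees(self, plexus_scene):
        vm = vg.segment_vessels(plexus_scene["vol"], "vessels", method="otsu")
        skel = vg.skeletonize_mask(vm)
        cp = plexus_scene["truth"].vessels[-1]["control_points_zyx_um"]
        site = cp[len(cp) // 2]
        plane = vg.fit_plexus_plane(skel, site, fit_radius_um=30.0)
        surf = plexus_scene["truth"].surface
        true_n = surf.normal_at(site[1], site[2])
        angle = np.degrees(np.arccos(np.clip(abs(plane.normal @ true_n), -1, 1)))
        assert angle < 3.0

    def test_sparse_neighborhood_rejected(self):
        skel = self._skeleton_from_points(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="sparse"):
            vg.fit_plexus_plane(skel, (0, 0, 0), fit_radius_um=5.0)


class TestDiameters:
    def _measure(self, vol, truth, site_y, modality="lsfm"):
        from retinaquant.studies import _measure_tube

        return _measure_tube(vol, truth, site_y, modality)

    def test_undistorted_tube_width_depth_within_one_voxel(self, plexus_scene):
        m = self._measure(plexus_scene["vol"], plexus_scene["truth"], plexus_scene["site_y"])
        assert m.width_um == pytest.approx(10.0, abs=1.0)
        assert m.depth_um == pytest.approx(10.0, abs=1.0)

    def test_compressed_tube_depth_scales_width_invariant(self, plexus_scene):
        vol_c, truth_c = sg.apply_flatmount_distortion(
            plexus_scene["vol"], plexus_scene["truth"], 0.4, unbend=True
        )
        m = self._measure(vol_c, truth_c, plexus_scene["site_y"], "confocal")
        assert m.width_um == pytest.approx(10.0, abs=1.0)
        assert m.depth_um == pytest.approx(4.0, abs=1.0)

    def test_rotation_equivariance_of_measurement(self):
        # tube along y on a flat plexus, rotated rigidly by 25° about y:
        # measuring against the rotated plane must reproduce W and D
        mask = np.zeros((60, 60, 60), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[30, -5, 30], [30, 65, 30]]), 5.0)
        img = ndimage.gaussian_filter(mask.astype(float), 0.7)
        rot = ndimage.rotate(img, 25.0, axes=(0, 2), reshape=False, order=1)
        vm = vg.segment_vessels(rot, method="fixed_threshold", threshold=0.5)
        skel = vg.skeletonize_mask(vm, (1, 1, 1))
        a = np.deg2rad(25.0)
        # scipy rotates about the volume centre in the (z, x) plane
        normal = np.array([np.cos(a), 0.0, np.sin(a)])
        plane = vg.PlexusPlane((30.0, 30.0, 30.0), normal, 30.0, 0.0)
        m = vg.measure_diameters(vm, (30.0, 30.0, 30.0), plane, skel, chord_image=rot)
        assert m.width_um == pytest.approx(10.0, abs=1.0)
        assert m.depth_um == pytest.approx(10.0, abs=1.0)

    def test_vessel_axis_near_normal_rejected(self):
        mask = np.zeros((60, 20, 20), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[2, 10, 10], [58, 10, 10]]), 4.0)
        skel = vg.skeletonize_mask(mask, (1, 1, 1))
        plane = vg.PlexusPlane((30, 10, 10), (1, 0, 0), 30, 0.0)
        with pytest.raises(ValueError, match="not measurable"):
            vg.measure_diameters(mask.astype(float), (30, 10, 10), plane, skel)


class TestGroupComparison:
    def test_identical_groups_t_zero_p_one(self):
        res = vg.unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_student_t_matches_hand_computed_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = vg.unpaired_ttest(a, b, equal_var=True)
        t, df, p = student_t_oracle(a, b)
        assert res["t"] == pytest.approx(t, abs=1e-12)
        assert res["df"] == pytest.approx(df)
        assert res["p"] == pytest.approx(p, abs=1e-12)

    def test_welch_t_matches_hand_computed_oracle(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 2, 14)
        res = vg.unpaired_ttest(a, b, equal_var=False)
        t, df, p = welch_t_oracle(a, b)
        assert res["t"] == pytest.approx(t, abs=1e-12)
        assert res["df"] == pytest.approx(df, abs=1e-9)
        assert res["p"] == pytest.approx(p, abs=1e-12)

    def test_group_sizes_sixty_and_twentyeight_accepted(self, rng):
        lsfm = [
            vg.DiameterMeasurement(np.zeros(3), w, d, "lsfm")
            for w, d in zip(rng.normal(10, 1, 60), rng.normal(10, 1, 60))
        ]
        conf = [
            vg.DiameterMeasurement(np.zeros(3), w, d, "confocal")
            for w, d in zip(rng.normal(11, 1, 28), rng.normal(4, 1, 28))
        ]
        report = vg.compare_distortion(lsfm, conf)
        assert report["lsfm"]["n"] == 60
        assert report["confocal"]["n"] == 28
        assert report["tests"]["depth_um"]["student"]["p"] < 1e-6

    def test_degenerate_equal_constant_groups_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = vg.unpaired_ttest([2.0, 2.0], [2.0, 2.0])
        assert res["p"] == 1.0 and res["degenerate"]

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            vg.unpaired_ttest([1.0], [1.0, 2.0])
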