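"""Generator contracts: geometry, determinism, distortion, ground truth."""
import numpy as np
import pytest
from scipy import ndimage

from retinaquant import synthgen as sg


class TestPlexusVolume:
    def test_tube_voxelization_matches_analytic_cylinder_volume(self):
        # tube spans beyond the volume so the spherical end caps are
        # clipped and the rasterized solid is a plain cylinder
        mask = np.zeros((24, 120, 24), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[12, -10, 12], [12, 130, 12]]), 5.0)
        expected = np.pi * 5.0**2 * 120
        assert abs(mask.sum() - expected) / expected < 0.05

    def test_zero_vessels_gives_empty_mask_and_truth(self):
        spec = sg.SceneSpec(seed=0, volume_shape=(16, 32, 32))
        vol, truth = sg.make_plexus_volume(spec)
        assert not truth.vessel_mask.any()
        assert truth.vessels == []

    def test_same_seed_bit_identical(self):
        def build():
            spec = sg.SceneSpec(
                seed=5,
                volume_shape=(24, 48, 48),
                vessels=[sg.VesselSpec(np.array([[12, 0, 24], [12, 48, 24]]), 4.0)],
            )
            return sg.make_plexus_volume(spec)[0].data

        np.testing.assert_array_equal(build(), build())

    def test_unresolvable_radius_rejected(self):
        spec = sg.SceneSpec(
            seed=0,
            volume_shape=(16, 32, 32),
            spacing_um=(2.0, 2.0, 2.0),
            vessels=[sg.VesselSpec(np.array([[8, 0, 32], [8, 64, 32]]), 3.0)],
        )
        with pytest.raises(ValueError, match="unresolvable"):
            sg.make_plexus_volume(spec)

    def test_truth_records_radius_and_surface_normals(self, plexus_scene):
        rec = plexus_scene["truth"].vessels[-1]
        assert rec["radius_um"] == 5.0
        norms = np.linalg.norm(rec["normals_zyx"], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestFlatmountDistortion:
    def test_identity_when_compression_one(self, plexus_scene):
        vol, truth = plexus_scene["vol"], plexus_scene["truth"]
        out, _ = sg.apply_flatmount_distortion(vol, truth, 1.0, unbend=False)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_expected_depth_scales_by_compression(self, plexus_scene):
        _, truth2 = sg.apply_flatmount_distortion(
            plexus_scene["vol"], plexus_scene["truth"], 0.4, unbend=True
        )
        rec = truth2.vessels[-1]
        assert rec["expected_depth_um"] == pytest.approx(4.0)
        assert rec["expected_width_um"] == pytest.approx(10.0)

    def test_composition_multiplies_compressions(self, plexus_scene):
        vol2, truth2 = sg.apply_flatmount_distortion(
            plexus_scene["vol"], plexus_scene["truth"], 0.4, unbend=True
        )
        _, truth3 = sg.apply_flatmount_distortion(vol2, truth2, 0.4)
        assert truth3.vessels[-1]["expected_depth_um"] == pytest.approx(1.6)
        assert truth3.compression_applied == pytest.approx(0.16)

    def test_invalid_compression_rejected(self, plexus_scene):
        with pytest.raises(ValueError):
            sg.apply_flatmount_distortion(plexus_scene["vol"], plexus_scene["truth"], 0.0)

    def test_width_truth_invariant_under_distortion(self, plexus_scene):
        _, truth2 = sg.apply_flatmount_distortion(
            plexus_scene["vol"], plexus_scene["truth"], 0.6, unbend=False
        )
        for before, after in zip(plexus_scene["truth"].vessels, truth2.vessels):
            assert after["expected_width_um"] == before["expected_width_um"]


class TestTuftVolume:
    def test_tuftspec_invariants(self):
        with pytest.raises(ValueError):
            sg.TuftSpec((0, 0), n_nuclei=0)
        with pytest.raises(ValueError):
            sg.TuftSpec((0, 0), n_nuclei=2, n_connections=0)
        with pytest.raises(ValueError, match="n_tunnels"):
            sg.TuftSpec((0, 0), n_nuclei=2, n_tunnels=3)

    def test_smallest_tuft_two_parallel_nuclei(self):
        surf = sg.SphericalCapSurface(1700.0, apex_zyx=(14.0, 40.0, 40.0))
        spec = sg.SceneSpec(
            seed=3,
            volume_shape=(64, 80, 80),
            surface=surf,
            vessels=sg.plexus_vessel_grid(surf, (80, 80)),
            tufts=[
                sg.TuftSpec((40, 40), n_nuclei=2, n_connections=1,
                            target_volume_um3=6e3, protrusion_height_um=28)
            ],
        )
        vol, truth = sg.make_tuft_volume(spec)
        rec = truth.tufts[0]
        assert rec["n_nuclei"] == 2
        lab, n = ndimage.label(truth.nuclei_mask, structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_nuclei_conservation_over_scene(self, tuft_scene):
        truth = tuft_scene["truth"]
        lab, n = ndimage.label(truth.nuclei_mask, structure=np.ones((3, 3, 3)))
        assert n == sum(t["n_nuclei"] for t in truth.tufts)

    def test_tunnel_count_by_construction(self, tuft_scene):
        from retinaquant.tuftmorph import tuft_topology

        labels = tuft_scene["truth"].tuft_labels
        assert tuft_topology(np.pad(labels == 1, 1)) == 1


class TestTimelapse:
    def test_scripted_filopodium_ground_truth(self):
        f = sg.FilopodiumScript((10, 20, 20), (0, 0, 1), [0, 2, 4, 6, 4, 2, 0])
        _, tracks, truth = sg.make_timelapse([f], dt_min=1.0, render=False)
        rec = truth.filopodia[0]
        assert rec["max_length_um"] == 6.0
        assert rec["lifetime_min"] == 5.0
        assert not rec["censored"]
        assert len(tracks) == 7

    def test_bundle_path_length_closed_form(self):
        pos = np.column_stack([np.zeros(11), np.zeros(11), np.arange(11.0)])
        b = sg.BundleScript(pos)
        _, _, truth = sg.make_timelapse([], [b], dt_min=1.0, render=False)
        assert truth.bundles[0]["path_length_um"] == pytest.approx(10.0)
        assert truth.bundles[0]["average_speed_um_min"] == pytest.approx(1.0)

    def test_same_seed_identical_track_bytes(self, tmp_path):
        def build(path):
            rng = np.random.default_rng(9)
            scripts = sg.filopodia_cohort("oir", rng, n=5)
            _, tracks, _ = sg.make_timelapse(scripts, seed=9, render=False)
            tracks.to_csv(path, index=False)
            return path.read_bytes()

        assert build(tmp_path / "a.csv") == build(tmp_path / "b.csv")

    def test_rendered_stack_is_4d(self):
        f = sg.FilopodiumScript((10, 20, 20), (0, 0, 1), [0, 3, 6])
        vol, _, _ = sg.make_timelapse([f], volume_shape=(24, 40, 40), render=True)
        assert vol.axes == "TZYX"
        assert vol.data.shape[0] == 3

    def test_invalid_dt_rejected(self):
        f = sg.FilopodiumScript((0, 0, 0), (0, 0, 1), [0, 1])
        with pytest.raises(ValueError, match="dt_min"):
            sg.make_timelapse([f], dt_min=0.0, render=False)


class TestLayeredVolume:
    def test_exact_areal_density_in_truth(self):
        vol, truth = sg.make_layered_volume(5e-3, 60.0, volume_shape=(96, 100, 100), seed=4)
        assert truth.layers["n_nuclei"] == round(5e-3 * 100 * 100)
        assert truth.layers["density_per_um2"] == pytest.approx(5e-3, rel=1e-6)

    def test_zero_density_gives_empty_channel(self):
        vol, truth = sg.make_layered_volume(0.0, 60.0, volume_shape=(64, 48, 48), seed=0)
        assert truth.layers["n_nuclei"] == 0
        assert not truth.nuclei_mask.any()

    def test_overlap_warning_at_high_density(self):
        _, truth = sg.make_layered_volume(
            0.05, 12.0, volume_shape=(32, 48, 48), seed=0
        )
        assert truth.layers["overlap_warning"]
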