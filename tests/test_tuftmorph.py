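"""Tuft detection, morphometrics, topology, regressions, polarity."""
import numpy as np
import pytest
from scipy import ndimage

from _oracles import b1_oracle, r_squared_oracle
from retinaquant import synthgen as sg
from retinaquant import tuftmorph as tm
from retinaquant import vesselgeom as vg


class TestDetectTufts:
    def test_three_generated_tufts_three_labels(self):
        surf = sg.SphericalCapSurface(1700.0, apex_zyx=(16.0, 80.0, 80.0))
        tufts = [
            sg.TuftSpec((40, 40), 3, 1, 0, 0.0, 6e3, 28),
            sg.TuftSpec((40, 120), 4, 2, 0, 0.0, 1.3e4, 40),
            sg.TuftSpec((120, 80), 5, 2, 0, 0.0, 1.6e4, 40),
        ]
        spec = sg.SceneSpec(
            seed=21, volume_shape=(72, 160, 160), surface=surf,
            vessels=sg.plexus_vessel_grid(surf, (160, 160)), tufts=tufts,
        )
        vol, truth = sg.make_tuft_volume(spec)
        vm = vg.segment_vessels(vol, "vessels", method="fixed_threshold", threshold=0.5)
        labels = tm.detect_tufts(vm.mask, surf, (1, 1, 1))
        assert labels.max() == 3
        # each label sits at one ground-truth anchor
        for t in truth.tufts:
            a = t["anchor_zyx_um"]
            iy, ix = int(a[1]), int(a[2])
            col = labels[:, iy, ix]
            assert col.max() > 0

    def test_flat_plexus_yields_no_tufts(self, plexus_scene):
        truth = plexus_scene["truth"]
        labels = tm.detect_tufts(truth.vessel_mask, truth.surface, (1, 1, 1))
        assert labels.max() == 0

    def test_min_height_above_tallest_protrusion_dominates(self, tuft_scene):
        truth = tuft_scene["truth"]
        labels = tm.detect_tufts(
            truth.vessel_mask, truth.surface, (1, 1, 1), min_height_um=60.0
        )
        assert labels.max() == 0

    def test_missing_plexus_model_rejected(self, tuft_scene):
        with pytest.raises(ValueError, match="plexus"):
            tm.detect_tufts(tuft_scene["truth"].vessel_mask, None, (1, 1, 1))


class TestTuftVolumeDepth:
    def test_digital_ellipsoid_volume_within_5pct(self):
        mask = np.zeros((32, 32, 32), bool)
        sg.rasterize_ellipsoid(mask, (1, 1, 1), (16, 16, 16), (10, 5, 5))
        assert tm.tuft_volume(mask, (1, 1, 1)) == pytest.approx(1047.2, rel=0.05)

    def test_single_voxel_anisotropic(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        assert tm.tuft_volume(mask, (2, 1, 1)) == pytest.approx(2.0)

    def test_volume_scales_with_spacing_cubed(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        v1 = tm.tuft_volume(mask, (1, 1, 1))
        assert tm.tuft_volume(mask, (2, 2, 2)) == pytest.approx(8 * v1)

    def test_depth_matches_protrusion_height(self, tuft_scene):
        truth = tuft_scene["truth"]
        lab = truth.tuft_labels == 1
        depth = tm.tuft_depth(lab, truth.surface, (1, 1, 1))
        assert depth == pytest.approx(truth.tufts[0]["protrusion_height_um"], abs=2.0)


class TestClassification:
    @pytest.mark.parametrize(
        "n,expected",
        [(1, "small"), (2, "small"), (3, "small"), (4, "medium"), (10, "medium"),
         (20, "medium"), (21, "large"), (100, "large")],
    )
    def test_boundaries(self, n, expected):
        assert tm.classify_tuft(n) == expected

    def test_zero_nuclei_invalid(self):
        with pytest.raises(ValueError):
            tm.classify_tuft(0)


class TestNuclei:
    def test_generated_tuft_nuclei_recovered_exactly(self, tuft_scene):
        vol, truth = tuft_scene["vol"], tuft_scene["truth"]
        lab = truth.tuft_labels == 1
        records = tm.detect_nuclei(
            vol.channel("nuclei"), (1, 1, 1), within_label=lab, threshold=0.5
        )
        assert len(records) == truth.tufts[0]["n_nuclei"]

    def test_touching_blob_pair_split_by_watershed(self):
        mask = np.zeros((32, 32, 32), bool)
        sg.rasterize_ellipsoid(mask, (1, 1, 1), (16, 16, 13.5), (3, 3, 3))
        sg.rasterize_ellipsoid(mask, (1, 1, 1), (16, 16, 18.5), (3, 3, 3))
        img = ndimage.gaussian_filter(mask.astype(float), 0.5)
        records = tm.detect_nuclei(
            img, (1, 1, 1), threshold=0.5, split_touching=True, min_volume_um3=5.0
        )
        assert len(records) == 2

    def test_empty_channel_warns_returns_nothing(self):
        with pytest.warns(UserWarning):
            records = tm.detect_nuclei(np.zeros((8, 8, 8)), (1, 1, 1))
        assert records == []

    def test_straight_capsule_is_flat(self):
        mask = np.zeros((24, 24, 24), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[12, 7, 12], [12, 17, 12]]), 1.6)
        rec = tm.detect_nuclei(mask.astype(float), (1, 1, 1), threshold=0.5)[0]
        assert tm.classify_nucleus_curvature(rec) == "flat"
        assert rec.bend_ratio == pytest.approx(1.0, abs=0.05)

    def test_c_shaped_nucleus_is_curved(self):
        theta = np.radians(170.0)
        rho = 14.0 / theta
        c = np.array([16.0, 16.0, 16.0])
        ts = np.linspace(-theta / 2, theta / 2, 11)
        poly = np.stack([c + rho * np.sin(t) * np.array([0, 1, 0])
                         + rho * (1 - np.cos(t)) * np.array([0, 0, 1]) for t in ts])
        mask = np.zeros((32, 32, 32), bool)
        sg.rasterize_tube(mask, (1, 1, 1), poly, 1.6)
        rec = tm.detect_nuclei(mask.astype(float), (1, 1, 1), threshold=0.5)[0]
        assert tm.classify_nucleus_curvature(rec) == "curved"

    def test_two_parallel_straight_nuclei_stay_two_flat_records(self):
        # the known pitfall: two side-by-side flat nuclei must not fuse
        # into one apparently-curved record
        mask = np.zeros((32, 32, 32), bool)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[14, 10, 14], [14, 22, 14]]), 1.6)
        sg.rasterize_tube(mask, (1, 1, 1), np.array([[20, 10, 14], [20, 22, 14]]), 1.6)
        img = ndimage.gaussian_filter(mask.astype(float), 0.5)
        records = tm.detect_nuclei(img, (1, 1, 1), threshold=0.5)
        assert len(records) == 2
        assert all(tm.classify_nucleus_curvature(r) == "flat" for r in records)

    def test_degenerate_tiny_nucleus_flagged_flat(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        rec = tm.detect_nuclei(
            mask.astype(float), (1, 1, 1), threshold=0.5, min_volume_um3=0.5
        )[0]
        assert tm.classify_nucleus_curvature(rec) == "flat"
        assert rec.degenerate


class TestConnections:
    def test_stalk_counts_recovered(self):
        surf = sg.SphericalCapSurface(1700.0, apex_zyx=(18.0, 60.0, 60.0))
        for n_conn in (1, 3):
            spec = sg.SceneSpec(
                seed=30 + n_conn, volume_shape=(88, 120, 120), surface=surf,
                vessels=sg.plexus_vessel_grid(surf, (120, 120)),
                tufts=[sg.TuftSpec((60, 60), 6, n_conn, 0, 0.0, 2e4, 42)],
            )
            vol, truth = sg.make_tuft_volume(spec)
            vm = vg.segment_vessels(vol, "vessels", method="fixed_threshold", threshold=0.5)
            lab = tm.detect_tufts(vm.mask, surf, (1, 1, 1)) == 1
            sk = vg.skeletonize_mask(vm)
            assert tm.count_connections(sk, lab, surf) == n_conn

    def test_count_stable_under_min_height_perturbation(self, tuft_scene):
        truth = tuft_scene["truth"]
        vm = vg.segment_vessels(
            tuft_scene["vol"], "vessels", method="fixed_threshold", threshold=0.5
        )
        lab = tm.detect_tufts(vm.mask, truth.surface, (1, 1, 1)) == 1
        sk = vg.skeletonize_mask(vm)
        counts = {
            h: tm.count_connections(sk, lab, truth.surface, min_height_um=h)
            for h in (8.0, 10.0, 12.0)
        }
        assert len(set(counts.values())) == 1

    def test_detached_tuft_warns_zero(self, tuft_scene):
        truth = tuft_scene["truth"]
        vm = vg.segment_vessels(
            tuft_scene["vol"], "vessels", method="fixed_threshold", threshold=0.5
        )
        lab = tm.detect_tufts(vm.mask, truth.surface, (1, 1, 1)) == 1
        # a skeleton that lives entirely above the threshold height
        sk = vg.skeletonize_mask(lab, (1, 1, 1))
        with pytest.warns(UserWarning, match="detached"):
            assert tm.count_connections(sk, lab, truth.surface) == 0


class TestTopology:
    def test_solid_ball_no_tunnels(self):
        mask = np.zeros((24, 24, 24), bool)
        sg.rasterize_ellipsoid(mask, (1, 1, 1), (12, 12, 12), (8, 8, 8))
        assert tm.tuft_topology(mask) == 0

    def test_solid_torus_one_tunnel(self):
        mask = np.zeros((32, 40, 40), bool)
        sg.rasterize_torus(mask, (1, 1, 1), (16, 20, 20), 10, 4, axis=(1, 0, 0))
        assert tm.tuft_topology(mask) == 1

    def test_double_torus_two_tunnels(self):
        mask = np.zeros((32, 60, 40), bool)
        sg.rasterize_torus(mask, (1, 1, 1), (16, 20, 20), 10, 4, axis=(1, 0, 0))
        sg.rasterize_torus(mask, (1, 1, 1), (16, 40, 20), 10, 4, axis=(1, 0, 0))
        assert tm.tuft_topology(mask) == 2

    def test_hollow_ball_counts_cavity_not_tunnel(self):
        mask = np.zeros((28, 28, 28), bool)
        sg.rasterize_ellipsoid(mask, (1, 1, 1), (14, 14, 14), (10, 10, 10))
        inner = np.zeros_like(mask)
        sg.rasterize_ellipsoid(inner, (1, 1, 1), (14, 14, 14), (5, 5, 5))
        assert tm.tuft_topology(mask & ~inner) == 0

    def test_border_contact_requires_padding(self):
        mask = np.ones((6, 6, 6), bool)
        with pytest.raises(ValueError, match="pad"):
            tm.tuft_topology(mask)

    def test_matches_independent_euler_oracle_on_phantoms(self):
        from retinaquant.studies import topology_phantoms

        for name, mask, _ in topology_phantoms(seed=3):
            assert tm.tuft_topology(np.pad(mask, 1)) == b1_oracle(mask), name


class TestRegressionsAndFolds:
    def test_exact_line_r2_one(self):
        recs = [
            tm.TuftRecord(i, 2.0 * i + 1, i, 0, 1, 0, 1.0, "small") for i in range(1, 8)
        ]
        res = tm.regress_morphometrics(recs, "n_nuclei", "volume_um3")
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_constant_response_r2_zero(self):
        recs = [tm.TuftRecord(i, 7.0, i, 0, 1, 0, 1.0, "small") for i in range(1, 6)]
        assert tm.regress_morphometrics(recs, "n_nuclei", "volume_um3").r_squared == 0.0

    def test_matches_arithmetic_oracle_on_random_points(self, rng):
        xs = rng.uniform(0, 10, 10)
        ys = 3 * xs + rng.normal(0, 2, 10)
        recs = [
            tm.TuftRecord(i, y, int(round(x * 10)), 0, 1, 0, 1.0, "small")
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        res = tm.regress_morphometrics(recs, "n_nuclei", "volume_um3")
        _, _, r2 = r_squared_oracle([r.n_nuclei for r in recs], ys)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)

    def test_r2_invariant_under_affine_rescaling(self, rng):
        xs = rng.uniform(0, 10, 12)
        ys = 2 * xs + rng.normal(0, 1, 12)
        recs = [
            tm.TuftRecord(i, y, int(x * 100), 0, 1, 0, 1.0, "small")
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        recs_scaled = [
            tm.TuftRecord(r.label, 5.0 * r.volume_um3 - 3.0, r.n_nuclei * 2,
                          0, 1, 0, 1.0, "small")
            for r in recs
        ]
        r2a = tm.regress_morphometrics(recs, "n_nuclei", "volume_um3").r_squared
        r2b = tm.regress_morphometrics(recs_scaled, "n_nuclei", "volume_um3").r_squared
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_fold_change_arithmetic(self):
        recs = [
            tm.TuftRecord(0, 2.0, 10, 0, 2, 0, 1.0, "medium"),
            tm.TuftRecord(1, 2.0, 15, 0, 2, 0, 1.0, "medium"),
            tm.TuftRecord(2, 5.0, 25, 0, 5, 0, 1.0, "large"),
        ]
        assert tm.class_fold_change(recs, "volume_um3") == pytest.approx(2.5)

    def test_identical_means_fold_one(self):
        recs = [
            tm.TuftRecord(0, 3.0, 10, 0, 2, 0, 1.0, "medium"),
            tm.TuftRecord(1, 3.0, 25, 0, 2, 0, 1.0, "large"),
        ]
        assert tm.class_fold_change(recs, "volume_um3") == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        recs = [tm.TuftRecord(0, 3.0, 10, 0, 2, 0, 1.0, "medium")]
        with pytest.raises(ValueError):
            tm.class_fold_change(recs, "volume_um3")


class TestPolarity:
    def test_reference_aligned_angle_zero(self):
        v = tm.nucleus_golgi_polarity([(0, 0, 0)], [(0, 0, 1)], (0, 0, 1))[0]
        assert v.angle_deg == pytest.approx(0.0)

    def test_reference_opposed_angle_180(self):
        v = tm.nucleus_golgi_polarity([(0, 0, 0)], [(0, 0, 1)], (0, 0, -1))[0]
        assert v.angle_deg == pytest.approx(180.0)

    def test_pairing_matches_brute_force_nearest_search(self, rng):
        nuclei = rng.uniform(0, 50, (5, 3))
        golgi = rng.uniform(0, 50, (5, 3))
        vecs = tm.nucleus_golgi_polarity(nuclei, golgi, (1, 0, 0))
        for nuc, v in zip(nuclei, vecs):
            d = [np.linalg.norm(nuc - g) for g in golgi]
            np.testing.assert_allclose(v.golgi_um, golgi[int(np.argmin(d))])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.nucleus_golgi_polarity(np.empty((0, 3)), [(0, 0, 0)], (1, 0, 0))
        with pytest.raises(ValueError, match="reference"):
            tm.nucleus_golgi_polarity([(0, 0, 0)], [(1, 0, 0)], (0, 0, 0))
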