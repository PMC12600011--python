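"""Segmentation: thresholds, masks, watershed, filters, population gate."""

import numpy as np
import pytest
from scipy import ndimage

from synaptomap import (
    ImagingGeometry,
    MultiChannelVolume,
    SceneParams,
    SegmentationConfig,
    cell_body_mask,
    detect_clusters,
    generate_scene,
    neuropil_mask,
    normalize_section_histograms,
    render_volume,
    select_synaptic_population,
    split_touching_clusters,
    two_level_otsu,
)
from conftest import make_cluster


def brute_force_two_level_otsu(values, nbins=256):
    """Naive reference: scan all threshold pairs, recomputing class stats."""
    flat = np.asarray(values).ravel()
    hist = np.bincount(flat, minlength=nbins).astype(float)
    levels = np.arange(hist.size)
    best, best_pair = -1.0, None
    for t1 in range(hist.size - 2):
        for t2 in range(t1 + 1, hist.size - 1):
            var_b = 0.0
            for cls in (
                slice(0, t1 + 1),
                slice(t1 + 1, t2 + 1),
                slice(t2 + 1, hist.size),
            ):
                w = hist[cls].sum()
                if w > 0:
                    m = (hist[cls] * levels[cls]).sum() / w
                    var_b += w * m * m
            if var_b > best + 1e-9:
                best, best_pair = var_b, (t1, t2)
    return best_pair


class TestTwoLevelOtsu:
    def test_three_spike_histogram_thresholds_between_modes(self):
        vals = np.repeat([10, 100, 200], [50, 30, 20])
        t_low, t_high = two_level_otsu(vals)
        assert 10 <= t_low < 100 <= t_high < 200

    def test_uniform_histogram_near_tertiles(self):
        vals = np.arange(256).repeat(4)
        t_low, t_high = two_level_otsu(vals)
        assert abs(t_low - 85) <= 3
        assert abs(t_high - 170) <= 3

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_level_otsu(np.repeat([0, 255], 10))

    def test_matches_exhaustive_search_on_random_histograms(self):
        # oracle equivalence on 64-level histograms, exact
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_modes = rng.integers(3, 6)
            centers = rng.choice(64, size=n_modes, replace=False)
            vals = np.concatenate(
                [
                    np.clip(
                        rng.normal(c, rng.uniform(1, 4), size=rng.integers(20, 200)),
                        0,
                        63,
                    ).astype(int)
                    for c in centers
                ]
            )
            if len(np.unique(vals)) < 3:
                continue
            assert two_level_otsu(vals, nbins=64) == brute_force_two_level_otsu(
                vals, nbins=64
            )

    def test_agrees_with_skimage_multiotsu_up_to_convention(self):
        # independent cross-check; conventions differ by at most one level
        from skimage.filters import threshold_multiotsu

        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [
                rng.normal(30, 5, 300),
                rng.normal(120, 10, 200),
                rng.normal(220, 8, 100),
            ]
        ).clip(0, 255).astype(int)
        t_low, t_high = two_level_otsu(vals)
        sk_low, sk_high = threshold_multiotsu(hist=np.bincount(vals, minlength=256))
        assert abs(t_low - sk_low) <= 1
        assert abs(t_high - sk_high) <= 1


class TestNormalization:
    def _volume(self, channels, geom):
        zeros = {
            n: np.zeros(geom.grid_shape, np.uint8)
            for n in ("homer1", "bassoon", "vglut2", "ctb")
        }
        zeros.update(channels)
        return MultiChannelVolume(geom, zeros)

    def test_identical_sections_map_to_rescaled_self(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(32, 32, 4))
        rng = np.random.default_rng(1)
        plane = rng.integers(0, 200, size=(32, 32)).astype(np.uint8)
        arr = np.stack([plane] * 4)
        vol = self._volume({"vglut2": arr}, geom)
        out = normalize_section_histograms(vol).channel("vglut2")
        lo, hi = int(arr.min()), int(arr.max())
        expected = np.round((arr.astype(float) - lo) * 255.0 / (hi - lo))
        # zero background stays zero; positive values rescale monotonically
        assert np.array_equal(out[0], out[1])
        assert (np.diff(np.unique(out[arr > 0])) > 0).all()

    def test_gain_variance_across_sections_is_removed(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(64, 64, 2))
        rng = np.random.default_rng(2)
        base = rng.integers(20, 120, size=(64, 64))
        arr = np.stack([base * 2, base]).astype(np.uint8)
        vol = self._volume({"vglut2": arr}, geom)
        out = normalize_section_histograms(vol).channel("vglut2").astype(float)
        m0, m1 = out[0].mean(), out[1].mean()
        assert abs(m0 - m1) / max(m0, m1) < 0.05

    def test_single_section_is_eight_bit_rescale(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(32, 32, 1))
        rng = np.random.default_rng(3)
        arr = rng.integers(10, 100, size=(1, 32, 32)).astype(np.uint8)
        vol = self._volume({"vglut2": arr}, geom)
        out = normalize_section_histograms(vol).channel("vglut2")
        lo, hi = int(arr.min()), int(arr.max())
        expected = np.round((arr.astype(float) - lo) * 255.0 / (hi - lo)).astype(
            np.uint8
        )
        assert np.array_equal(out, expected)

    def test_constant_channel_returned_unchanged(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(8, 8, 2))
        vol = self._volume({}, geom)
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_section_histograms(vol)
        assert out.channel("homer1").sum() == 0


@pytest.fixture(scope="module")
def cell_body_volume():
    geom = ImagingGeometry(voxel_xy=78.125, voxel_z=70.0, shape=(256, 256, 90))
    params = SceneParams(
        density_sAZ_eyeB=0.004,
        density_sAZ_eyeA=0.0,
        density_mAZ_eyeA=0.0,
        density_mAZ_eyeB=0.0,
        cell_body_count=1,
        cell_body_radius=3.0,
        section_gain_sd=0.0,
        seed=8,
    )
    scene = generate_scene(params, geom)
    return geom, scene, render_volume(scene, geom, params)


class TestCellBodyAndNeuropilMasks:
    def test_no_large_component_gives_empty_mask(self, small_scene, desk_geom):
        _, vol = small_scene
        mask = cell_body_mask(vol.channel("homer1"), desk_geom)
        assert not mask.any()

    def test_sphere_covered_and_puncta_spared(self, cell_body_volume):
        geom, scene, vol = cell_body_volume
        mask = cell_body_mask(vol.channel("homer1"), geom)
        center, radius = scene.cell_bodies[0]
        spacing = np.asarray(geom.spacing_nm)
        idx = np.argwhere(np.ones(geom.grid_shape, bool))
        # coverage of the planted sphere
        zz = np.argwhere(mask)
        assert len(zz) > 0
        inside = np.linalg.norm(zz * spacing + spacing / 2 - center, axis=1) <= radius
        sphere_vox = np.ceil(4 / 3 * np.pi * radius**3 / np.prod(spacing))
        assert inside.sum() >= 0.9 * (4 / 3 * np.pi * radius**3 / np.prod(spacing))
        # no synaptic punctum swallowed
        for p in scene.inputs:
            vox = np.floor(np.asarray(p.homer_centroids_nm[0]) / spacing).astype(int)
            vox = np.clip(vox, 0, np.asarray(geom.grid_shape) - 1)
            assert not mask[tuple(vox)]

    def test_mask_robust_to_size_threshold_order_of_magnitude(self, cell_body_volume):
        geom, scene, vol = cell_body_volume
        masks = [
            cell_body_mask(
                vol.channel("homer1"), geom,
                SegmentationConfig(cellbody_min_voxels=t),
            )
            for t in (1e4, 3e4, 1e5)
        ]
        for m in masks[1:]:
            assert np.array_equal(m, masks[0])

    def test_neuropil_full_when_ctb_everywhere(self):
        ctb = np.full((4, 16, 16), 200, np.uint8)
        with pytest.warns(UserWarning, match="degenerate"):
            mask = neuropil_mask(ctb)
        assert mask.all()

    def test_neuropil_hull_excludes_empty_half(self):
        rng = np.random.default_rng(1)
        ctb = np.zeros((2, 32, 32), np.uint8)
        ctb[:, :, :14] = rng.integers(100, 255, size=(2, 32, 14))
        ctb[:, :, 14:16] = rng.integers(1, 40, size=(2, 32, 2))
        mask = neuropil_mask(ctb)
        assert mask[:, :, :14].mean() > 0.9
        assert not mask[:, :, 20:].any()

    def test_cell_bodies_subtracted_from_hull(self):
        ctb = np.full((2, 16, 16), 200, np.uint8)
        ctb[0, 0, 0] = 10
        ctb[1, 5, 5] = 30
        bodies = np.zeros((2, 16, 16), bool)
        bodies[:, 4:8, 4:8] = True
        mask = neuropil_mask(ctb, bodies)
        assert not mask[bodies].any()
        assert mask[~bodies].mean() > 0.9

    def test_no_ctb_signal_raises(self):
        with pytest.raises(ValueError, match="neuropil"):
            neuropil_mask(np.zeros((2, 8, 8), np.uint8))


class TestWatershedSplit:
    def test_single_convex_blob_unchanged(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(24, 24, 24))
        zz, yy, xx = np.indices(geom.grid_shape)
        blob = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 64
        parts = split_touching_clusters(blob, geom)
        assert len(parts) == 1
        assert len(parts[0]) == blob.sum()

    def test_dumbbell_splits_into_two_even_halves(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(48, 24, 24))
        zz, yy, xx = np.indices(geom.grid_shape)  # grid is (nz=24, ny=24, nx=48)
        s1 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 14) ** 2 <= 49
        s2 = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 34) ** 2 <= 49
        neck = (
            (np.abs(zz - 12) <= 1)
            & (np.abs(yy - 12) <= 1)
            & (xx > 14)
            & (xx < 34)
        )
        mask = s1 | s2 | neck
        parts = split_touching_clusters(mask, geom)
        assert len(parts) == 2
        sphere_vox = s1.sum()
        for p in parts:
            assert abs(len(p) - sphere_vox) / sphere_vox < 0.2

    def test_partition_property(self):
        geom = ImagingGeometry(voxel_xy=100, voxel_z=100, shape=(16, 24, 24))
        rng = np.random.default_rng(5)
        mask = ndimage.binary_dilation(
            rng.random(geom.grid_shape) > 0.995, iterations=3
        )
        parts = split_touching_clusters(mask, geom)
        all_vox = np.concatenate(parts) if parts else np.empty((0, 3))
        assert len(all_vox) == mask.sum()
        assert len(np.unique(all_vox, axis=0)) == len(all_vox)


class TestDetectClusters:
    def test_two_separated_puncta_recovered_near_planted_positions(self, desk_geom):
        from synaptomap.scene import _paint_punctum

        arr = np.zeros(desk_geom.grid_shape, np.float32)
        spots = [
            np.array([1400.0, 5000.0, 5000.0]),
            np.array([1400.0, 5000.0, 9000.0]),
        ]
        for s in spots:
            _paint_punctum(arr, desk_geom, s, 60.0)
        clusters = detect_clusters(
            arr.astype(np.uint8), None, desk_geom, SegmentationConfig()
        )
        assert len(clusters) == 2
        got = sorted(c.weighted_centroid_nm[2] for c in clusters)
        for centroid, spot in zip(
            sorted(clusters, key=lambda c: c.weighted_centroid_nm[2]), spots
        ):
            assert np.linalg.norm(centroid.weighted_centroid_nm - spot) < 50.0

    def test_single_section_punctum_dropped(self, desk_geom):
        arr = np.zeros(desk_geom.grid_shape, np.uint8)
        arr[20, 90:96, 90:96] = 220  # confined to one 70-nm section
        arr[5, 10, 10] = 30  # keep histogram non-degenerate
        arr[6, 11, 11] = 60
        clusters = detect_clusters(arr, None, desk_geom, SegmentationConfig())
        assert all(c.section_span >= 2 for c in clusters)
        assert not any(
            abs(c.weighted_centroid_nm[0] - 20 * 70) < 200 for c in clusters
        )

    def test_edge_punctum_dropped(self, desk_geom):
        from synaptomap.scene import _paint_punctum

        arr = np.zeros(desk_geom.grid_shape, np.float32)
        _paint_punctum(arr, desk_geom, np.array([1400.0, 5000.0, 40.0]), 60.0)
        _paint_punctum(arr, desk_geom, np.array([1400.0, 5000.0, 9000.0]), 60.0)
        clusters = detect_clusters(
            arr.astype(np.uint8), None, desk_geom, SegmentationConfig()
        )
        assert len(clusters) == 1
        assert clusters[0].weighted_centroid_nm[2] > 5000

    def test_cluster_invariants_hold(self, small_scene, desk_geom):
        _, vol = small_scene
        clusters = detect_clusters(
            vol.channel("vglut2"), vol.conventional["vglut2"], desk_geom,
            SegmentationConfig(), channel_name="vglut2",
        )
        assert clusters
        for c in clusters:
            assert c.volume_voxels >= 1
            assert 0.0 <= c.signal_density <= 1.0
            assert c.volume_um3 == pytest.approx(
                c.volume_voxels * desk_geom.voxel_volume_um3
            )
            lo = desk_geom.voxel_to_nm(c.voxels.min(axis=0) - 1)
            hi = desk_geom.voxel_to_nm(c.voxels.max(axis=0) + 1)
            assert np.all(c.weighted_centroid_nm >= lo)
            assert np.all(c.weighted_centroid_nm <= hi)


class TestPopulationGate:
    def test_synaptic_population_separated_from_background(self, desk_geom):
        rng = np.random.default_rng(0)
        geom = desk_geom
        synaptic = [
            make_cluster(
                np.argwhere(np.ones((6, 8, 8), bool)) + rng.integers(0, 20, 3),
                geom, cid=i,
            )
            for i in range(40)
        ]
        # background: small and sparse (low signal density)
        background = []
        for i in range(20):
            vox = np.argwhere(np.ones((2, 3, 3), bool)) + rng.integers(0, 20, 3)
            raw = np.zeros(geom.grid_shape, np.int64)
            pick = vox[rng.random(len(vox)) < 0.3]
            if len(pick):
                raw[tuple(pick.T)] = 150
            background.append(make_cluster(vox, geom, cid=40 + i, raw=raw))
        kept, rejected = select_synaptic_population(synaptic + background)
        kept_ids = {c.id for c in kept}
        recall = len(kept_ids & set(range(40))) / 40
        rejection = len({c.id for c in rejected} & set(range(40, 60))) / 20
        assert recall >= 0.95
        assert rejection >= 0.9

    def test_identical_clusters_fall_back_to_keep_all(self, desk_geom):
        clusters = [
            make_cluster(np.argwhere(np.ones((3, 3, 3), bool)) + i, desk_geom, cid=i)
            for i in range(10)
        ]
        with pytest.warns(UserWarning, match="not separable"):
            kept, rejected = select_synaptic_population(clusters)
        assert len(kept) == 10 and not rejected

    def test_partition_is_deterministic_and_exhaustive(self, desk_geom):
        rng = np.random.default_rng(7)
        clusters = []
        for i in range(30):
            size = rng.integers(2, 6)
            vox = np.argwhere(np.ones((size, size, size), bool)) + rng.integers(0, 30, 3)
            clusters.append(make_cluster(vox, desk_geom, cid=i))
        out1 = select_synaptic_population(clusters)
        out2 = select_synaptic_population(clusters)
        assert [c.id for c in out1[0]] == [c.id for c in out2[0]]
        assert len(out1[0]) + len(out1[1]) == 30
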