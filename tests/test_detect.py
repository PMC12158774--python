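"""Gated puncta detection: thresholding, gating, filtering, centroids."""

import numpy as np
import pytest

from synaptomap import detect, volcore
from synaptomap.detect import DetectParams, RegionRecord
from synaptomap.errors import ConfigurationError, GeometryError

from conftest import add_blob, make_volume
from oracles import brute_force_otsu


def region(rid, vox=100, z=15, maxs=0.0, centroid=(0.0, 0.0, 0.0)):
    return RegionRecord(rid, vox, z, maxs, centroid)


class TestOtsuThreshold:
    def test_matches_brute_force_on_random_data(self, rng):
        """Both formulations maximize the same between-class variance; inside
        an empty histogram gap any split is optimal, so compare the induced
        partitions rather than the raw threshold value."""
        for _ in range(25):
            n = int(rng.integers(2, 400))
            vals = rng.choice([20.0, 500.0], size=n) + 10 * rng.random(n)
            expected = brute_force_otsu(vals)
            got = detect.otsu_threshold(vals)
            np.testing.assert_array_equal(vals > got, vals > expected)

    def test_degenerate_inputs_return_none(self):
        assert detect.otsu_threshold(np.array([])) is None
        assert detect.otsu_threshold(np.full(10, 3.3)) is None

    def test_partition_respects_threshold_edge(self, rng):
        """value > threshold must reproduce the bin partition exactly, even
        when a whole population shares one histogram bin."""
        vals = np.concatenate([140 + 6 * rng.random(10), 1500 + 400 * rng.random(12)])
        thr = detect.otsu_threshold(vals)
        assert np.sum(vals > thr) == 12


class TestStructuralGate:
    def test_bimodal_maxima_split(self):
        regions = [region(i + 1, maxs=m) for i, m in enumerate([200, 210, 220, 20, 25])]
        gated = detect.structural_gate(regions)
        assert [r.gate for r in gated] == ["specific"] * 3 + ["unspecific"] * 2
        # agrees with the brute-force histogram split
        thr = brute_force_otsu(np.array([200.0, 210, 220, 20, 25]))
        assert all((r.max_structural > thr) == (r.gate == "specific") for r in gated)

    def test_empty_and_degenerate(self):
        assert detect.structural_gate([]) == []
        gated = detect.structural_gate([region(1, maxs=5.0), region(2, maxs=5.0)])
        assert all(r.gate == "specific" for r in gated)

    def test_permutation_invariance(self, rng):
        maxima = list(rng.uniform(0, 1000, size=12))
        regions = [region(i + 1, maxs=m) for i, m in enumerate(maxima)]
        gated = {r.region_id: r.gate for r in detect.structural_gate(regions)}
        perm = list(regions)
        rng.shuffle(perm)
        gated_perm = {r.region_id: r.gate for r in detect.structural_gate(perm)}
        assert gated == gated_perm


class TestSizeFilter:
    @pytest.mark.parametrize(
        "vox,z,min_vox,min_z,expected",
        [
            (60, 15, 60, 13, None),  # boundary: "less than 60" removed, 60 kept
            (59, 15, 60, 13, "size"),
            (100, 13, 60, 13, None),  # 13 planes at the 300-nm preset survive
            (100, 12, 60, 13, "z_extent"),
        ],
    )
    def test_strict_less_removal(self, vox, z, min_vox, min_z, expected):
        out = detect.size_filter([region(1, vox=vox, z=z)], min_vox, min_z)
        assert out[0].filtered_out_by == expected

    def test_monotonicity_in_thresholds(self, rng):
        regions = [
            region(i + 1, vox=int(rng.integers(1, 200)), z=int(rng.integers(1, 30)))
            for i in range(50)
        ]
        surviving = [
            sum(r.filtered_out_by is None for r in detect.size_filter(regions, mv, mz))
            for mv, mz in [(10, 5), (50, 5), (50, 15), (100, 20)]
        ]
        assert surviving == sorted(surviving, reverse=True)


class TestWeightedCentroid:
    def test_single_voxel(self):
        assert detect.weighted_centroid(np.array([[3, 4, 5]]), np.array([2.0])) == (3, 4, 5)

    def test_two_voxel_closed_form(self):
        coords = np.array([[0, 0, 0], [0, 0, 4]])
        assert detect.weighted_centroid(coords, np.array([1.0, 3.0]))[2] == pytest.approx(3.0)

    def test_matches_brute_force_sum(self, rng):
        coords = rng.integers(0, 40, size=(50, 3)).astype(float)
        weights = rng.random(50)
        got = detect.weighted_centroid(coords, weights)
        expected = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        assert np.allclose(got, expected)

    def test_zero_weights_fall_back_to_unweighted(self, rng):
        coords = rng.integers(0, 10, size=(8, 3)).astype(float)
        assert np.allclose(detect.weighted_centroid(coords, np.zeros(8)), coords.mean(axis=0))

    def test_empty_region_is_error(self):
        with pytest.raises(ConfigurationError):
            detect.weighted_centroid(np.empty((0, 3)))


def _fixture_scene(rng, n_specific=5, n_unspecific=3, shape=(64, 64, 64)):
    """Hand-built molecular/structural pair: bright structural features under
    the specific puncta, dim background under the rest."""
    mol = np.full(shape, 100.0, dtype=np.float32)
    structural = np.full(shape, 120.0, dtype=np.float32)
    centres = [
        (12, 14, 14), (12, 46, 44), (30, 30, 30), (48, 14, 44), (48, 46, 14),
        (14, 32, 50), (46, 30, 30), (30, 50, 12),
    ]
    specific = centres[:n_specific]
    for c in specific:
        add_blob(mol, c, (2.5, 2.5, 2.5), 900.0)
        add_blob(structural, c, (2.5, 2.5, 2.5), 1500.0)
    for c in centres[n_specific:n_specific + n_unspecific]:
        add_blob(mol, c, (2.5, 2.5, 2.5), 900.0)
    return make_volume(mol), make_volume(structural, role="structural"), specific


@pytest.fixture
def detect_params():
    return DetectParams(
        lo_count=101, hi_percentile=99.5, sigma_signal=2.0, sigma_background=6.0,
        min_voxels=60, min_zplanes=5, kind="pre", source="bassoon",
    )


class TestDetectPuncta:
    def test_empty_channel_gives_no_points(self, detect_params):
        mol = make_volume(np.zeros((32, 32, 32)))
        structural = make_volume(np.zeros((32, 32, 32)), role="structural")
        det = detect.detect_puncta(mol, structural, detect_params)
        assert det.points == []

    def test_specific_puncta_recovered_exactly(self, rng, detect_params):
        mol, structural, planted = _fixture_scene(rng)
        det = detect.detect_puncta(mol, structural, detect_params)
        assert len(det.points) == len(planted)
        for p in det.points:
            nearest = min(np.linalg.norm(np.subtract(p.location, c)) for c in planted)
            assert nearest < 1.0
        # removed regions are retained with their cause
        assert sum(r.gate == "unspecific" for r in det.regions) == 3

    def test_zplane_filter_records_cause(self, rng):
        mol = np.full((64, 64, 64), 100.0, dtype=np.float32)
        structural = np.full((64, 64, 64), 500.0, dtype=np.float32)
        add_blob(mol, (32, 32, 32), (1.0, 4.0, 4.0), 900.0)  # pancake blob
        params = DetectParams(
            hi_percentile=99.9, sigma_signal=1.0, sigma_background=5.0,
            min_voxels=10, min_zplanes=40, kind="pre",
        )
        det = detect.detect_puncta(make_volume(mol), make_volume(structural, "structural"), params)
        assert det.points == []
        assert any(r.filtered_out_by == "z_extent" for r in det.regions)

    def test_mismatched_grids_rejected(self, detect_params):
        mol = make_volume(np.zeros((16, 16, 16)))
        structural = make_volume(np.zeros((16, 16, 17)), role="structural")
        with pytest.raises(GeometryError):
            detect.detect_puncta(mol, structural, detect_params)

    def test_points_lie_inside_their_regions(self, rng, detect_params):
        mol, structural, _ = _fixture_scene(rng)
        det = detect.detect_puncta(mol, structural, detect_params)
        labels = det.label_volume.data
        for p in det.points:
            idx = tuple(int(round(c)) for c in p.location)
            assert labels[idx] == p.region_id

    def test_raising_minima_never_adds_points(self, rng, detect_params):
        mol, structural, _ = _fixture_scene(rng)
        base = len(detect.detect_puncta(mol, structural, detect_params).points)
        import dataclasses
        for mv, mz in [(200, 5), (60, 12), (500, 20)]:
            params = dataclasses.replace(detect_params, min_voxels=mv, min_zplanes=mz)
            assert len(detect.detect_puncta(mol, structural, params).points) <= base


class TestPresets:
    @pytest.mark.parametrize(
        "marker,z_step,hi,sigmas,min_z",
        [
            ("bassoon", 300, 99.5, (5, 11), 13),
            ("shank2", 300, 99.0, (4, 11), 13),
            ("bassoon", 200, 99.95, (6, 10), 14),
            ("shank2", 200, 99.0, (6, 12), 12),
            ("shank2", 400, 99.0, (6, 12), 12),
        ],
    )
    def test_published_parameter_table(self, marker, z_step, hi, sigmas, min_z):
        p = DetectParams.from_preset(marker, z_step)
        assert (p.hi_percentile, (p.sigma_signal, p.sigma_background), p.min_zplanes) == (
            hi, sigmas, min_z,
        )
        assert p.min_voxels == 60

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectParams.from_preset("gephyrin", 300)


class TestDetectSimple:
    def test_empty_channel(self):
        params = DetectParams(sigma_signal=2, sigma_background=6, min_voxels=20, min_zplanes=3)
        det = detect.detect_simple(make_volume(np.zeros((32, 32, 32))), params)
        assert det.points == []

    def test_opening_erases_small_blob(self):
        mol = np.full((48, 48, 48), 100.0, dtype=np.float32)
        add_blob(mol, (24, 24, 24), (0.8, 0.8, 0.8), 2000.0)  # ~1-voxel-radius spot
        params = DetectParams(sigma_signal=0.7, sigma_background=4, min_voxels=1, min_zplanes=1)
        det = detect.detect_simple(make_volume(mol), params, opening_radius=2)
        assert det.points == []

    def test_large_blobs_survive_opening(self):
        mol = np.full((64, 64, 64), 100.0, dtype=np.float32)
        centres = [(16, 16, 16), (16, 48, 48), (48, 16, 48), (48, 48, 16)]
        for c in centres:
            add_blob(mol, c, (3.0, 3.0, 3.0), 1500.0)
        params = DetectParams(sigma_signal=1.5, sigma_background=6, min_voxels=30, min_zplanes=3)
        det = detect.detect_simple(make_volume(mol), params, opening_radius=2)
        assert len(det.points) == 4


class TestPredmapToPoints:
    def test_zero_prediction(self):
        pred = make_volume(np.zeros((32, 32, 32)), role="prediction")
        structural = make_volume(np.zeros((32, 32, 32)), role="structural")
        assert detect.predmap_to_points(pred, structural).points == []

    def test_planted_blobs_recovered_near_truth(self, rng):
        shape = (72, 72, 72)
        pred = np.zeros(shape, dtype=np.float32)
        structural = np.full(shape, 150.0, dtype=np.float32)
        centres = [(20, 20, 20), (20, 52, 52), (52, 36, 20)]
        for c in centres:
            add_blob(pred, c, (3.0, 3.0, 3.0), 1.0)
            add_blob(structural, c, (3.0, 3.0, 3.0), 1000.0)
        det = detect.predmap_to_points(
            make_volume(pred, role="prediction"), make_volume(structural, "structural")
        )
        assert len(det.points) == len(centres)
        for p in det.points:
            assert min(np.linalg.norm(np.subtract(p.location, c)) for c in centres) < 2.0


class TestMakeTrainingTarget:
    def test_empty_channel_gives_zero_target(self):
        mol = make_volume(np.zeros((32, 32, 32)))
        structural = make_volume(np.zeros((32, 32, 32)), role="structural")
        target, struct8 = detect.make_training_target(mol, structural)
        assert np.all(target.data == 0)
        assert struct8.data.dtype == np.uint8

    def test_unspecific_punctum_absent_from_target(self):
        shape = (64, 64, 64)
        mol = np.full(shape, 100.0, dtype=np.float32)
        structural = np.full(shape, 120.0, dtype=np.float32)
        add_blob(mol, (20, 20, 20), (2.0, 2.0, 2.0), 800.0)  # specific
        add_blob(structural, (20, 20, 20), (2.0, 2.0, 2.0), 1500.0)
        add_blob(mol, (44, 44, 44), (2.0, 2.0, 2.0), 800.0)  # over dim background
        target, _ = detect.make_training_target(mol := make_volume(mol), make_volume(structural, "structural"))
        assert target.data[20, 20, 20] > 0.5
        assert target.data[44, 44, 44] == 0.0
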