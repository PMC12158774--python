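"""Two-pass synapse pairing, synapse tables and structural rescue."""

import numpy as np
import pytest

from synaptomap import assemble, detect, volcore
from synaptomap.assemble import MatchingMatrix, PairingConfig, RescueParams
from synaptomap.errors import ConfigurationError
from synaptomap.volcore import PointAnnotation, Volume, VoxelGrid

from conftest import add_blob, make_volume
from oracles import brute_force_two_pass


def pts(coords, kind):
    return [PointAnnotation(tuple(map(float, c)), kind) for c in coords]


class TestPairSynapses:
    def test_single_pair_within_cutoff(self):
        M = assemble.pair_synapses(pts([(0, 0, 0)], "pre"), pts([(0, 0, 10)], "post"))
        assert M.edges == {(0, 0)}

    def test_cutoff_is_strictly_below(self):
        M = assemble.pair_synapses(
            pts([(0, 0, 0)], "pre"), pts([(0, 0, 30)], "post"), PairingConfig(30.0)
        )
        assert M.edges == set()

    def test_one_to_many_motifs(self):
        """Posts A, B both nearest pre P1; floating P2 attaches to A in pass 2,
        yielding a 1:2 (P1) and a 2:1 (A) motif in the same configuration."""
        pre = pts([(0, 0, 0), (0, 0, 35)], "pre")  # P1, P2
        post = pts([(0, 0, 10), (0, 0, -20)], "post")  # A, B
        M = assemble.pair_synapses(pre, post, PairingConfig(30.0))
        assert M.edges == {(0, 0), (1, 0), (0, 1)}
        assert M.pre_degree(0) == 2 and M.post_degree(0) == 2

    def test_empty_inputs(self):
        assert assemble.pair_synapses([], pts([(0, 0, 0)], "post")).edges == set()
        assert assemble.pair_synapses(pts([(0, 0, 0)], "pre"), []).edges == set()

    def test_matches_brute_force_rule(self, rng):
        cfg = PairingConfig(30.0)
        for _ in range(60):
            n_pre, n_post = rng.integers(0, 9, size=2)
            pre = rng.uniform(0, 60, size=(n_pre, 3))
            post = rng.uniform(0, 60, size=(n_post, 3))
            M = assemble.pair_synapses(pts(pre, "pre"), pts(post, "post"), cfg)
            assert M.edges == brute_force_two_pass(pre, post, 30.0)

    def test_pass_structure_invariants(self, rng):
        """Each post gains at most one pass-1 edge; each pre at most one
        pass-2 edge; edge count decomposes accordingly."""
        for _ in range(30):
            pre = rng.uniform(0, 50, size=(rng.integers(1, 9), 3))
            post = rng.uniform(0, 50, size=(rng.integers(1, 9), 3))
            M = assemble.pair_synapses(pts(pre, "pre"), pts(post, "post"))
            assert all(M.post_degree(i) <= 1 + max(0, len(pre) - 1) for i in range(len(post)))
            # pass-1 edges: one per paired post; extra edges come from pass 2,
            # at most one per pre
            from collections import Counter

            per_pre = Counter(j for _, j in M.edges)
            n_pass2 = sum(1 for j, c in per_pre.items())
            assert len(M.edges) <= len(post) + len(pre)


class TestSynapseTable:
    def test_empty_matrix(self):
        grid = VoxelGrid((1, 1, 1), (19.4, 9.7, 9.7))
        table = assemble.synapse_table(MatchingMatrix(0, 0), [], [], grid)
        assert len(table) == 0

    def test_anisotropic_distance_scaling(self):
        grid = VoxelGrid((64, 64, 64), (19.4, 9.7, 9.7))
        pre = pts([(0, 0, 0)], "pre")
        post = pts([(10, 0, 0)], "post")  # 10 voxels along z
        M = assemble.pair_synapses(pre, post)
        table = assemble.synapse_table(M, pre, post, grid)
        assert table.loc[0, "dist_vox"] == pytest.approx(10.0)
        assert table.loc[0, "dist_nm"] == pytest.approx(194.0)

    def test_motif_degrees_tallied(self):
        pre = pts([(0, 0, 0)], "pre")
        post = pts([(0, 0, 10), (0, 0, -12)], "post")
        M = assemble.pair_synapses(pre, post)
        table = assemble.synapse_table(M, pre, post, VoxelGrid((64, 64, 64), (1, 1, 1)))
        assert set(table["pre_degree"]) == {2}
        assert set(table["post_degree"]) == {1}


class TestRescueThreshold:
    def test_formula(self):
        assert assemble.rescue_threshold(100.0, 200.0, 0.4) == pytest.approx(140.0)
        assert assemble.rescue_threshold(100.0, 200.0, 0.5) == pytest.approx(150.0)

    def test_on_percentile_fixture(self, rng):
        data = rng.permutation(np.linspace(0.0, 100.0, 1001))
        p95, p100 = np.percentile(data, [95, 100])
        assert assemble.rescue_threshold(p95, p100, 0.4) == pytest.approx(95 + 0.4 * 5)

    def test_coefficient_bounds(self):
        with pytest.raises(ConfigurationError):
            RescueParams(thr_coefficient=1.5)


def _detection_set(points, grid, label_data=None):
    labels = Volume(grid, np.zeros(grid.shape, dtype=np.int32) if label_data is None else label_data, role="label")
    return detect.DetectionSet(labels, [], points, detect.DetectParams())


class TestRescueUnpaired:
    def test_flat_structural_rescues_nothing(self):
        grid = VoxelGrid((64, 64, 64), (1, 1, 1))
        structural = Volume(grid, np.full(grid.shape, 100.0, dtype=np.float32), role="structural")
        pre = pts([(32, 32, 32)], "pre")
        pre_det = _detection_set(pre, grid)
        post_det = _detection_set([], grid)
        M = assemble.pair_synapses(pre, [])
        new_pre, new_post, logs, M2 = assemble.rescue_unpaired(M, pre_det, post_det, structural)
        assert new_post == [] and M2.edges == set()

    def test_bright_feature_rescued_and_paired(self):
        grid = VoxelGrid((64, 64, 64), (1, 1, 1))
        data = np.full(grid.shape, 100.0, dtype=np.float32)
        add_blob(data, (32, 32, 44), (3, 3, 3), 600.0)  # PSD-like feature
        structural = Volume(grid, data, role="structural")
        pre = pts([(32, 32, 32)], "pre")
        M = assemble.pair_synapses(pre, [])
        new_pre, new_post, logs, M2 = assemble.rescue_unpaired(
            M, _detection_set(pre, grid), _detection_set([], grid), structural
        )
        assert len(new_post) == 1
        assert new_post[0].kind == "post"
        assert np.linalg.norm(np.subtract(new_post[0].location, (32, 32, 44))) < 3.0
        assert M2.edges == {(0, 0)}

    def test_existing_detections_never_removed(self):
        grid = VoxelGrid((48, 48, 48), (1, 1, 1))
        data = np.full(grid.shape, 100.0, dtype=np.float32)
        add_blob(data, (24, 24, 36), (3, 3, 3), 600.0)
        structural = Volume(grid, data, role="structural")
        pre = pts([(24, 24, 24)], "pre")
        post = pts([(10, 10, 10)], "post")
        M = assemble.pair_synapses(pre, post)
        new_pre, new_post, _, _ = assemble.rescue_unpaired(
            M, _detection_set(pre, grid), _detection_set(post, grid), structural
        )
        assert new_pre[: len(pre)] == pre and new_post[: len(post)] == post

    def test_masked_labels_excluded_from_candidates(self):
        """A bright feature already claimed by an existing detection label
        must not be rescued again."""
        grid = VoxelGrid((64, 64, 64), (1, 1, 1))
        data = np.full(grid.shape, 100.0, dtype=np.float32)
        add_blob(data, (32, 32, 44), (3, 3, 3), 600.0)
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[19:46, 19:46, 31:58] = 1  # post label claims the blob (+/-4 sigma)
        structural = Volume(grid, data, role="structural")
        pre = pts([(32, 32, 32)], "pre")
        M = assemble.pair_synapses(pre, [])
        _, new_post, _, _ = assemble.rescue_unpaired(
            M, _detection_set(pre, grid), _detection_set([], grid, labels), structural
        )
        assert new_post == []

    def test_accept_radius_respected(self):
        grid = VoxelGrid((64, 128, 128), (1, 1, 1))
        data = np.full(grid.shape, 100.0, dtype=np.float32)
        add_blob(data, (32, 64, 110), (3, 3, 3), 600.0)  # 46 voxels from seed
        structural = Volume(grid, data, role="structural")
        pre = pts([(32, 64, 64)], "pre")
        M = assemble.pair_synapses(pre, [])
        _, new_post, logs, _ = assemble.rescue_unpaired(
            M, _detection_set(pre, grid), _detection_set([], grid), structural
        )
        assert new_post == []
        assert any(log["rejected"] >= 1 for log in logs)
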