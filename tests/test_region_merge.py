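import numpy as np
import pytest

from ovaseg import (
    BandwidthParams,
    GrayImage,
    LabelMap,
    filter_image,
    label_modes,
    merge_nonprotruding,
    merge_regions,
    region_adjacency,
    remove_fragments,
)
from ovaseg.meanshift import ModeMap


def fake_modes(mode_gray):
    """ModeMap whose pixels converged in place (positions = grid)."""
    mg = np.asarray(mode_gray, dtype=float)
    rr, cc = np.mgrid[0 : mg.shape[0], 0 : mg.shape[1]]
    pos = np.stack([rr.astype(float), cc.astype(float)], axis=-1)
    return ModeMap(mg, pos, np.ones(mg.shape, dtype=np.int64), BandwidthParams())


def assert_partition(labels: LabelMap, shape):
    assert labels.shape == shape
    assert labels.labels.min() >= 1
    uniq = np.unique(labels.labels)
    np.testing.assert_array_equal(uniq, np.arange(1, len(uniq) + 1))


class TestLabelModes:
    def test_constant_is_one_region(self):
        lab = label_modes(fake_modes(np.full((5, 5), 3.0)))
        assert lab.n_regions == 1

    def test_checkerboard_fragments_fully(self):
        board = np.indices((4, 4)).sum(0) % 2 * 200.0
        lab = label_modes(fake_modes(board), gray_tol=5.0, connectivity=4)
        assert lab.n_regions == 16

    def test_two_halves(self):
        mg = np.zeros((6, 6))
        mg[:, 3:] = 100.0
        assert label_modes(fake_modes(mg)).n_regions == 2

    def test_8_connectivity_bridges_diagonals(self):
        board = np.indices((4, 4)).sum(0) % 2 * 200.0
        lab = label_modes(fake_modes(board), gray_tol=5.0, connectivity=8)
        assert lab.n_regions == 2


class TestMergeRegions:
    def _two_region_image(self, mean_left, mean_right):
        px = np.zeros((4, 6))
        px[:, :3], px[:, 3:] = mean_left, mean_right
        labels = np.ones((4, 6), dtype=np.int64)
        labels[:, 3:] = 2
        return LabelMap(labels), GrayImage(px)

    def test_close_means_merge(self):
        lab, img = self._two_region_image(100.0, 102.0)
        assert merge_regions(lab, img, H=10.0).n_regions == 1

    def test_distant_means_stay(self):
        lab, img = self._two_region_image(0.0, 200.0)
        out = merge_regions(lab, img, H=10.0)
        assert out.n_regions == 2
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_chain_merges_transitively_with_recomputed_means(self):
        # equal-size regions with means 0, 6, 12 and H = 10: the 0/6
        # pair merges first (mean 3), then |3 - 12| = 9 < 10 merges too
        px = np.zeros((2, 6))
        px[:, 2:4], px[:, 4:] = 6.0, 12.0
        labels = np.repeat(np.array([[1, 1, 2, 2, 3, 3]]), 2, axis=0)
        out = merge_regions(LabelMap(labels), GrayImage(px), H=10.0)
        assert out.n_regions == 1

    def test_tiny_threshold_is_identity(self, rng):
        labels = LabelMap(rng.integers(1, 5, (6, 6)))
        img = GrayImage(rng.integers(0, 256, (6, 6)).astype(float))
        out = merge_regions(labels.compacted(), img, H=1e-9)
        assert out.n_regions == labels.compacted().n_regions

    def test_huge_threshold_merges_everything(self, rng):
        labels = LabelMap(rng.integers(1, 6, (6, 6))).compacted()
        img = GrayImage(rng.integers(0, 256, (6, 6)).astype(float))
        assert merge_regions(labels, img, H=256.0).n_regions == 1

    def test_deterministic_under_ties(self):
        px = np.zeros((2, 6))
        px[:, 2:4], px[:, 4:] = 6.0, 12.0
        labels = LabelMap(np.repeat(np.array([[1, 1, 2, 2, 3, 3]]), 2, axis=0))
        img = GrayImage(px)
        a = merge_regions(labels, img, H=6.5)
        b = merge_regions(labels, img, H=6.5)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestMergeNonprotruding:
    def test_single_region_unchanged(self):
        img = GrayImage(np.full((5, 5), 50.0))
        modes = fake_modes(np.full((5, 5), 50.0))
        lab = LabelMap(np.ones((5, 5), dtype=np.int64))
        out = merge_nonprotruding(lab, modes, img)
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_equal_density_regions_unchanged(self):
        px = np.zeros((6, 8))
        px[:, 4:] = 200.0
        lab = LabelMap((px > 0).astype(np.int64) + 1)
        out = merge_nonprotruding(lab, fake_modes(px), GrayImage(px), prominence=0.5)
        assert out.n_regions == 2

    def test_sparse_satellite_absorbed(self):
        # a 4-pixel bright blob in a large flat field: its mode density
        # is far below the field's, so it is absorbed
        px = np.full((20, 20), 100.0)
        px[9:11, 9:11] = 200.0
        lab = LabelMap((px > 150).astype(np.int64) + 1)
        out = merge_nonprotruding(lab, fake_modes(px), GrayImage(px), prominence=0.3)
        assert out.n_regions == 1

    def test_prominence_bounds(self):
        lab = LabelMap(np.ones((3, 3), dtype=np.int64))
        with pytest.raises(ValueError):
            merge_nonprotruding(lab, fake_modes(np.zeros((3, 3))), GrayImage(np.zeros((3, 3))), prominence=1.5)


class TestRemoveFragments:
    def test_large_regions_untouched(self):
        labels = np.ones((6, 6), dtype=np.int64)
        labels[:, 3:] = 2
        img = GrayImage(np.zeros((6, 6)))
        out = remove_fragments(LabelMap(labels), img, min_size=10)
        np.testing.assert_array_equal(out.labels, LabelMap(labels).labels)

    def test_fragment_joins_closest_mean_neighbour(self):
        # a 3-px fragment (mean 12) between neighbours with means 10
        # and 180 must join the mean-10 side
        px = np.zeros((3, 9))
        px[:, :3], px[:, 3:4], px[:, 4:] = 10.0, 12.0, 180.0
        labels = np.zeros((3, 9), dtype=np.int64)
        labels[:, :3], labels[:, 3:4], labels[:, 4:] = 1, 2, 3
        out = remove_fragments(LabelMap(labels), GrayImage(px), min_size=5)
        assert out.n_regions == 2
        # fragment column inherits the label of the left (mean 10) side
        assert out.labels[0, 3] == out.labels[0, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_no_fragment_survives(self, seed):
        rng = np.random.default_rng(seed)
        mg = rng.integers(0, 8, (24, 24)) * 30.0
        lab = label_modes(fake_modes(mg), gray_tol=1.0)
        img = GrayImage(mg)
        out = remove_fragments(lab, img, min_size=20)
        assert_partition(out, (24, 24))
        sizes = np.bincount(out.labels.ravel())[1:]
        assert sizes.min() >= 20 or out.n_regions == 1
        assert out.n_regions <= lab.n_regions


class TestInvariants:
    def test_every_stage_preserves_partition_and_region_count(self, rng):
        mg = rng.integers(0, 6, (16, 16)) * 40.0
        img = GrayImage(mg + rng.normal(0, 1, mg.shape))
        modes = fake_modes(mg)
        lab = label_modes(modes)
        assert_partition(lab, mg.shape)
        n0 = lab.n_regions
        l1 = merge_regions(lab, img, H=15.0)
        assert_partition(l1, mg.shape)
        assert l1.n_regions <= n0
        l2 = merge_nonprotruding(l1, modes, img)
        assert_partition(l2, mg.shape)
        assert l2.n_regions <= l1.n_regions
        l3 = remove_fragments(l2, img, min_size=10)
        assert_partition(l3, mg.shape)
        assert l3.n_regions <= l2.n_regions

    def test_region_adjacency_bookkeeping(self):
        labels = np.ones((4, 4), dtype=np.int64)
        labels[2:, :] = 2
        img = GrayImage(np.arange(16, dtype=float).reshape(4, 4))
        adj = region_adjacency(LabelMap(labels), img)
        assert sum(n for _, n, _ in adj.regions) == 16
        assert adj.edges == {(1, 2)}
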