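import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kd2.descriptor import Descriptor, comp_desc, default_beta
from kd2.errors import ConfigurationError
from kd2.image_io import DensityImage, PointOfInterest
from kd2.index_search import (
    db_index,
    db_search,
    descriptor_distance,
    grid_centers,
    local_variance_filter,
    read_index,
    write_index,
)



@pytest.fixture
def patterned_images(icons):
    """Two 200x200 images with icons pasted at known positions."""
    out = []
    for k, positions in enumerate([((60, 60), (60, 140)), ((140, 60), (140, 140))]):
        f = np.zeros((200, 200))
        for i, (cx, cy) in enumerate(positions):
            ic = icons[(k * 2 + i) % len(icons)]
            f[cx - 30 : cx + 30, cy - 30 : cy + 30] = ic
        out.append((DensityImage(f, image_id=f"img{k}"), positions))
    return out


@pytest.fixture
def small_index(patterned_images):
    images = [img for img, _ in patterned_images]
    pois = [[PointOfInterest(*p) for p in pos] for _, pos in patterned_images]
    return db_index(images, 100, pois=pois)


class TestVarianceFilter:
    def test_constant_image_keeps_everything(self):
        f = DensityImage(np.full((128, 128), 77.0))
        centers = [PointOfInterest(20, 20), PointOfInterest(64, 64)]
        assert local_variance_filter(f, centers, 40) == centers

    def test_only_contrast_windows_survive(self):
        f = np.full((128, 128), 50.0)
        f[20:40, 20:40] = 200.0  # single high-contrast patch
        img = DensityImage(f)
        keep = PointOfInterest(30, 30)
        drop = PointOfInterest(100, 100)
        assert local_variance_filter(img, [drop, keep], 40) == [keep]

    def test_order_preserved(self):
        f = np.full((128, 128), 50.0)
        f[10:50, 10:50] = 220.0
        img = DensityImage(f)
        centers = [PointOfInterest(40, 40), PointOfInterest(15, 15), PointOfInterest(30, 30)]
        kept = local_variance_filter(img, centers, 40)
        assert kept == sorted(kept, key=centers.index)


class TestDbIndex:
    def test_grid_mode_row_count(self, icons):
        f = np.tile(np.pad(icons[0], 2), (2, 3))[:128, :192]
        img = DensityImage(np.ascontiguousarray(f), image_id="tiles")
        table = db_index([img], 64, stride=64)
        assert len(table) == (128 // 64) * (192 // 64)

    def test_grid_centers_counting(self):
        assert len(grid_centers(600, 600, 150)) == 16

    def test_explicit_pois_deterministic(self, patterned_images):
        images = [img for img, _ in patterned_images]
        pois = [[PointOfInterest(*p) for p in pos] for _, pos in patterned_images]
        t1 = db_index(images, 100, pois=pois)
        t2 = db_index(images, 100, pois=pois)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        assert len(t1) == 4

    def test_empty_database_rejected(self):
        with pytest.raises(ConfigurationError):
            db_index([], 40, stride=8)

    def test_duplicate_pois_rejected(self, patterned_images):
        img = patterned_images[0][0]
        with pytest.raises(ConfigurationError):
            db_index([img], 100, pois=[[PointOfInterest(60, 60)] * 2])

    def test_blank_windows_skipped_with_warning(self, caplog):
        f = np.zeros((200, 200))
        f[10:30, 10:30] = 200.0
        img = DensityImage(f, image_id="sparse")
        pois = [[PointOfInterest(20, 20), PointOfInterest(170, 170)]]
        with caplog.at_level("WARNING", logger="kd2.index_search"):
            table = db_index([img], 40, pois=pois)
        assert len(table) == 1
        assert any("blank" in r.message for r in caplog.records)


class TestDistance:
    def _desc(self, v, S=100):
        return Descriptor(v=np.asarray(v, float), S=S, beta=default_beta(S))

    def test_identity_and_unit_vectors(self):
        a = self._desc([1, 0, 0, 0, 0, 0])
        b = self._desc([0, 1, 0, 0, 0, 0])
        assert descriptor_distance(a, a) == 0.0
        assert descriptor_distance(a, b) == 2.0

    @given(st.lists(st.floats(-1e3, 1e3), min_size=12, max_size=12))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_symmetric_and_nonnegative(self, vals):
        a = self._desc(vals[:6])
        b = self._desc(vals[6:])
        assert descriptor_distance(a, b) == descriptor_distance(b, a) >= 0.0

    def test_mismatched_metadata_rejected(self):
        a = self._desc([0] * 6, S=100)
        b = self._desc([0] * 6, S=150)
        with pytest.raises(ConfigurationError):
            descriptor_distance(a, b)


class TestDbSearch:
    def _query(self, small_index, row=0):
        r = small_index.table.iloc[row]
        return Descriptor(
            v=r[["q20", "q02", "q12", "q21", "q30", "q03"]].to_numpy(float),
            S=small_index.meta["S"],
            beta=small_index.meta["beta"],
        )

    def test_exact_match_ranks_first_with_zero_distance(self, small_index):
        res = db_search(self._query(small_index), small_index, k=3)
        assert res.ranked.loc[0, "distance"] == 0.0
        assert len(res.ranked) == 3
        assert not res.truncated

    def test_distances_non_decreasing(self, small_index):
        res = db_search(self._query(small_index, 2), small_index, k=4)
        d = res.ranked["distance"].to_numpy()
        assert np.all(np.diff(d) >= 0) and np.all(d >= 0)

    def test_row_order_has_no_effect(self, small_index):
        shuffled = small_index
        shuffled.table = small_index.table.sample(frac=1, random_state=5).reset_index(
            drop=True
        )
        q = self._query(small_index)
        res = db_search(q, shuffled, k=4)
        d = res.ranked["distance"].to_numpy()
        assert np.all(np.diff(d) >= 0)
        assert res.ranked.loc[0, "distance"] == 0.0

    def test_oversized_k_returns_all_flagged(self, small_index):
        res = db_search(self._query(small_index), small_index, k=99)
        assert res.truncated
        assert len(res.ranked) == len(small_index)

    def test_metadata_mismatch_rejected(self, small_index):
        q = Descriptor(v=np.zeros(6), S=40, beta=default_beta(40))
        with pytest.raises(ConfigurationError):
            db_search(q, small_index, k=1)


class TestIndexFile:
    def test_roundtrip_preserves_ranking(self, small_index, tmp_path):
        path = tmp_path / "index.tsv"
        write_index(small_index, path)
        loaded = read_index(path)
        assert loaded.meta == small_index.meta
        q = Descriptor(
            v=small_index.table.iloc[1][
                ["q20", "q02", "q12", "q21", "q30", "q03"]
            ].to_numpy(float),
            S=small_index.meta["S"],
            beta=small_index.meta["beta"],
        )
        before = db_search(q, small_index, k=4).ranked
        after = db_search(q, loaded, k=4).ranked
        assert list(before.image_id) == list(after.image_id)
        assert list(before.x_p) == list(after.x_p)
        np.testing.assert_allclose(before.distance, after.distance, rtol=1e-6, atol=1e-6)

    def test_eight_significant_digits(self, small_index, tmp_path):
        path = tmp_path / "index.tsv"
        write_index(small_index, path)
        loaded = read_index(path)
        a = small_index.table[["q20", "q02", "q12", "q21", "q30", "q03"]].to_numpy(float)
        b = loaded.table[["q20", "q02", "q12", "q21", "q30", "q03"]].to_numpy(float)
        np.testing.assert_allclose(a, b, rtol=1e-7, atol=1e-10)

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "junk.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ConfigurationError):
            read_index(path)
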