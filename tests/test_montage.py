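import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytocycle.montage import (
    Montage,
    build_montages,
    estimate_background,
    load_montage,
    reshape_image,
    save_montage,
    split_montage,
)


class TestEstimateBackground:
    def test_constant_image_samples_constant(self):
        sampler = estimate_background(np.full((20, 20), 0.3))
        vals = sampler.sample(50, np.random.default_rng(0))
        assert np.all(vals == 0.3)

    def test_only_border_frame_is_sampled(self):
        img = np.full((20, 20), 0.9)
        img[:2, :] = img[-2:, :] = 0.2
        img[:, :2] = img[:, -2:] = 0.2
        sampler = estimate_background(img)
        vals = sampler.sample(200, np.random.default_rng(1))
        assert np.all(vals == 0.2)

    def test_samples_stay_within_border_range(self, small_population):
        _, records, _ = small_population
        img = records[0].brightfield
        sampler = estimate_background(img)
        vals = sampler.sample(500, np.random.default_rng(2))
        border = np.concatenate([img[:2].ravel(), img[-2:].ravel(), img[:, :2].ravel(), img[:, -2:].ravel()])
        assert vals.min() >= border.min() and vals.max() <= border.max()


class TestReshapeImage:
    def test_padding_centers_smaller_input(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.1, 0.2, (30, 30))
        out = reshape_image(img, 55, rng=rng)
        assert out.shape == (55, 55)
        # (55-30)//2 = 12: the original content sits at [12:42)
        assert np.array_equal(out[12:42, 12:42], img)

    def test_identity_at_target_size(self):
        img = np.random.default_rng(1).uniform(size=(55, 55))
        assert np.array_equal(reshape_image(img, 55), img)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(40, 40))
        once = reshape_image(img, 55, rng=np.random.default_rng(3))
        twice = reshape_image(once, 55, rng=np.random.default_rng(4))
        assert np.array_equal(once, twice)

    def test_center_crop_preserves_central_object(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = np.full((60, 60), 0.1)
        disk = (yy - 29.5) ** 2 + (xx - 29.5) ** 2 <= 100
        img[disk] = 0.9
        out = reshape_image(img, 55)
        assert out.shape == (55, 55)
        assert out.sum() == pytest.approx(img.sum() - (60 * 60 - 55 * 55) * 0.1)

    def test_cropping_into_object_warns(self):
        img = np.full((60, 60), 0.1)
        img[:, :] = 0.9  # object fills the frame; any crop removes object pixels
        img[:2] = img[-2:] = 0.1
        img[:, :2] = img[:, -2:] = 0.1
        with pytest.warns(UserWarning, match="non-background"):
            reshape_image(img, 55)

    def test_padding_values_come_from_border_distribution(self):
        img = np.zeros((31, 31))
        img[::2, :] = 0.4  # two-valued border frame
        out = reshape_image(img, 55, rng=np.random.default_rng(5))
        pad = np.concatenate([out[:12].ravel(), out[43:].ravel()])
        assert set(np.unique(pad)) <= {0.0, 0.4}

    @given(side=st.integers(min_value=20, max_value=80))
    @settings(max_examples=20, deadline=None)
    def test_output_side_always_target(self, side):
        img = np.random.default_rng(side).uniform(size=(side, side))
        assert reshape_image(img, 55, rng=np.random.default_rng(0)).shape == (55, 55)


class TestMontages:
    def test_grid_capacity_and_counts(self, small_population):
        _, records, _ = small_population
        montages = build_montages(records[:225], grid=15, tile=55)
        assert len(montages["brightfield"]) == 1
        assert montages["brightfield"][0].image.shape == (825, 825)

    def test_overflow_starts_second_montage(self, small_population):
        _, records, _ = small_population
        # 200 cells at grid 9 (81 per montage) -> 3 montages, last holds 38
        montages = build_montages(records, grid=9, tile=55)
        assert len(montages["brightfield"]) == 3
        assert len(montages["brightfield"][-1].index_map) == 200 - 2 * 81

    def test_channels_share_index_maps(self, small_population):
        _, records, _ = small_population
        montages = build_montages(records[:50], grid=8, tile=55)
        assert (
            montages["brightfield"][0].index_map == montages["darkfield"][0].index_map
        )

    def test_round_trip_is_bit_identical(self, small_population):
        _, records, _ = small_population
        chunk = records[:40]
        montages = build_montages(chunk, grid=7, tile=55, seed=9)
        tiles = dict(split_montage(montages["brightfield"][0]))
        for rec in chunk:
            direct = reshape_image(
                rec.brightfield,
                55,
                rng=np.random.default_rng(
                    np.random.SeedSequence((9, __import__("zlib").crc32(rec.cell_id.encode())))
                ),
            )
            assert np.array_equal(tiles[rec.cell_id], direct)

    def test_split_returns_index_order(self, small_population):
        _, records, _ = small_population
        montages = build_montages(records[:10], grid=5, tile=55)
        out = split_montage(montages["darkfield"][0])
        assert [cid for cid, _ in out] == [r.cell_id for r in records[:10]]

    def test_duplicate_index_map_rejected(self):
        img = np.zeros((110, 110))
        with pytest.raises(ValueError, match="duplicate"):
            Montage(image=img, grid=2, tile=55, index_map=["a", "a"], channel="brightfield")

    def test_index_map_longer_than_grid_rejected(self):
        img = np.zeros((110, 110))
        with pytest.raises(ValueError, match="grid"):
            Montage(image=img, grid=2, tile=55, index_map=list("abcde"), channel="brightfield")

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_montages([], grid=15, tile=55)

    def test_save_load_round_trip(self, small_population, tmp_path):
        _, records, _ = small_population
        m = build_montages(records[:9], grid=3, tile=55)["brightfield"][0]
        save_montage(m, tmp_path / "m.tif")
        back = load_montage(tmp_path / "m.tif")
        assert back.index_map == m.index_map
        assert np.allclose(back.image, m.image, atol=1.0 / 65535)
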