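import numpy as np
import pytest
from skimage import draw

from cytocycle.features import (
    GLCM_LEVELS,
    cooccurrence_matrix,
    extract_features,
    feature_manifest,
    granularity_spectrum,
    haralick_stats,
    haralick_texture,
    integrated_stain_intensity,
    intensity_features,
    radial_distribution,
    shape_features,
    zernike_indices,
    zernike_magnitudes,
)
from cytocycle.segment import segment_brightfield
from cytocycle.synth import CellRecord, CellState, PopulationConfig, render_cell


def _disk_mask(radius=12, side=41):
    mask = np.zeros((side, side), bool)
    rr, cc = draw.disk((side // 2, side // 2), radius)
    mask[rr, cc] = True
    return mask


def _ellipse_mask(a, b, side=61):
    mask = np.zeros((side, side), bool)
    rr, cc = draw.ellipse(side // 2, side // 2, a, b)
    mask[rr, cc] = True
    return mask


class TestManifest:
    def test_total_is_213(self):
        assert len(feature_manifest()) == 213

    def test_channel_breakdown_130_plus_83(self):
        m = feature_manifest()
        bf = sum(ch == "brightfield" for ch in m.channels)
        df = sum(ch == "darkfield" for ch in m.channels)
        assert (bf, df) == (130, 83)

    def test_five_categories(self):
        m = feature_manifest()
        assert set(m.categories) == {
            "size_shape",
            "granularity",
            "intensity",
            "radial_distribution",
            "texture",
        }

    def test_names_unique_and_stable(self):
        a, b = feature_manifest(), feature_manifest()
        assert a.names == b.names
        assert len(set(a.names)) == 213

    def test_zernike_index_count(self):
        assert len(zernike_indices(9)) == 30


class TestShapeFeatures:
    def test_disk_symmetry_metrics(self):
        vec = shape_features(_disk_mask(12))
        names = [f"bf_shape_{s}" for s in
                 ("area", "perimeter", "form_factor", "eccentricity", "solidity")]
        f = dict(zip([n.split("bf_shape_")[1] for n in names], vec[:5]))
        assert f["eccentricity"] <= 0.1
        assert f["solidity"] >= 0.95
        assert abs(f["form_factor"] - 1.0) <= 0.12  # discretized perimeter

    def test_area_scaling_law(self):
        a1 = shape_features(_disk_mask(8))[0]
        a2 = shape_features(_disk_mask(16))[0]
        assert a2 / a1 == pytest.approx(4.0, rel=0.06)  # rasterized disks

    def test_ellipse_eccentricity_analytic(self):
        # 2:1 ellipse: e = sqrt(1 - 1/4) ~ 0.866
        vec = shape_features(_ellipse_mask(20, 10))
        assert vec[3] == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shape_features(np.zeros((10, 10), bool))

    def test_zernike_rotation_invariance(self):
        m = _ellipse_mask(18, 9)
        z0 = zernike_magnitudes(m)
        z90 = zernike_magnitudes(m.T)
        assert np.allclose(z0, z90, atol=0.02)


class TestIntensityFeatures:
    def test_constant_region_degenerate_stats(self):
        vec = intensity_features(np.full((20, 20), 0.7), _disk_mask(6, 20))
        names = ["integrated", "mean", "std", "mad", "min", "max", "median",
                 "q1", "q3", "range", "e_int", "e_mean", "e_std", "e_min", "e_max", "mass_disp"]
        f = dict(zip(names, vec))
        assert f["std"] == pytest.approx(0.0, abs=1e-12)
        assert f["mad"] == 0 and f["range"] == 0
        assert f["mass_disp"] == pytest.approx(0.0, abs=1e-9)

    def test_single_bright_pixel_full_frame(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        vec = intensity_features(img, None)
        assert vec[0] == 1.0  # integrated

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(20, 20))
        v1 = intensity_features(img, _disk_mask(6, 20))
        v2 = intensity_features(2 * img, _disk_mask(6, 20))
        assert v2[0] == pytest.approx(2 * v1[0])


class TestRadialDistribution:
    def test_fracatd_sums_to_one(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.1, 1.0, (41, 41))
        vec = radial_distribution(img, _disk_mask(15))
        assert vec[:4].sum() == pytest.approx(1.0, abs=1e-6)

    def test_rotationally_symmetric_image_has_zero_radialcv(self):
        yy, xx = np.mgrid[0:41, 0:41]
        rr = np.hypot(yy - 20, xx - 20)
        img = np.exp(-rr / 10)
        vec = radial_distribution(img, _disk_mask(15))
        assert np.all(vec[8:] <= 0.05)

    def test_uniform_disk_meanfrac_near_one(self):
        img = np.ones((41, 41))
        vec = radial_distribution(img, _disk_mask(15))
        assert np.allclose(vec[4:8], 1.0, atol=0.1)

    def test_zero_intensity_returns_zeros(self):
        vec = radial_distribution(np.zeros((21, 21)), _disk_mask(8, 21))
        assert np.all(vec == 0)


class TestHaralick:
    def test_constant_region_conventions(self):
        vec = haralick_texture(np.full((20, 20), 0.3), _disk_mask(7, 20))
        per_scale = vec.reshape(3, 13)
        for stats in per_scale:
            assert stats[0] == 1.0  # ASM
            assert stats[1] == 0.0  # contrast
            assert stats[2] == 0.0  # correlation convention
            assert stats[8] == 0.0  # entropy

    def test_stripe_contrast_matches_hand_computed_cooccurrence(self):
        # vertical 1-px stripes alternating min/max: horizontal offset at
        # scale 1 always pairs the two extreme quantization levels, so the
        # co-occurrence matrix has all mass at (0,7)/(7,0) and the contrast
        # is 7^2 = 49; the vertical offset pairs equal levels: contrast 0.
        img = np.tile([0.0, 1.0], (8, 4))
        mask = np.ones_like(img, bool)
        q = np.where(img > 0, GLCM_LEVELS - 1, 0)
        P_h = cooccurrence_matrix(q, mask, (0, 1))
        assert P_h[0, 7] == pytest.approx(0.5) and P_h[7, 0] == pytest.approx(0.5)
        assert haralick_stats(P_h)[1] == pytest.approx(49.0)
        P_v = cooccurrence_matrix(q, mask, (1, 0))
        assert haralick_stats(P_v)[1] == 0.0

    def test_invariance_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(30, 30))
        mask = _disk_mask(10, 30)
        v1 = haralick_texture(img, mask)
        v2 = haralick_texture(3.0 * img + 0.5, mask)
        assert np.allclose(v1, v2, atol=1e-10)


class TestGranularity:
    def test_constant_image_all_zero(self):
        vec = granularity_spectrum(np.full((40, 40), 0.5), None)
        assert np.all(vec == 0)

    def test_nonnegative_and_bounded(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(45, 45))
        vec = granularity_spectrum(img, None)
        assert np.all(vec >= 0)
        assert vec.sum() <= 100 + 1e-9

    def test_grain_size_shifts_spectrum(self):
        def grain_field(radius, seed):
            rng = np.random.default_rng(seed)
            img = np.zeros((64, 64))
            for _ in range(12):
                cy, cx = rng.integers(8, 56, 2)
                rr, cc = draw.disk((cy, cx), radius, shape=img.shape)
                img[rr, cc] = 1.0
            return img

        small = granularity_spectrum(grain_field(2, 4), None)
        large = granularity_spectrum(grain_field(6, 4), None)
        assert small[:3].sum() >= 0.9 * small.sum()
        assert np.argmax(large) > np.argmax(small)


class TestExtractFeatures:
    def _cell(self, phase="G1", seed=0, with_stain=True, stain_cv=0.05):
        cfg = PopulationConfig(noise_sd=0.02, stain_cv=stain_cv, with_stain=with_stain)
        c = 2.0 if phase in ("G1",) else 4.0
        rec = render_cell(CellState(phase, 0.0, c, 9.0), cfg, np.random.default_rng(seed))
        seg = segment_brightfield(rec.brightfield)
        return rec, seg

    def test_vector_length_and_determinism(self):
        rec, seg = self._cell()
        v1 = extract_features(rec, seg)
        v2 = extract_features(rec, seg)
        assert v1.shape == (213,)
        assert np.array_equal(v1, v2)

    def test_channel_blocks_are_independent(self):
        rec, seg = self._cell(seed=5)
        v = extract_features(rec, seg)
        flat = CellRecord(
            cell_id=rec.cell_id,
            brightfield=rec.brightfield,
            darkfield=np.full_like(rec.darkfield, 0.2),
            stain=rec.stain,
        )
        v_flat = extract_features(flat, seg)
        m = feature_manifest()
        bf_idx = [i for i, ch in enumerate(m.channels) if ch == "brightfield"]
        assert np.array_equal(v[bf_idx], v_flat[bf_idx])
        # darkfield texture block at convention values for a constant frame
        tex0 = m.names.index("df_tex_asm_s1")
        assert v_flat[tex0] == 1.0

    def test_missing_channel_rejected(self):
        rec, seg = self._cell()
        rec.darkfield = None
        with pytest.raises(ValueError, match="channel"):
            extract_features(rec, seg)

    def test_stain_intensity_stoichiometric(self):
        cfg = PopulationConfig(noise_sd=0.0, stain_cv=0.0)
        rec = render_cell(CellState("G1", 0.0, 2.0, 9.0), cfg, np.random.default_rng(1))
        seg = segment_brightfield(rec.brightfield)
        val = integrated_stain_intensity(rec, seg)
        assert val == pytest.approx(2.0 * cfg.dna_g1, rel=0.01)

    def test_stain_linearity_and_zero(self):
        rec, seg = self._cell(seed=2)
        v = integrated_stain_intensity(rec, seg)
        doubled = CellRecord(rec.cell_id, rec.brightfield, rec.darkfield, 2 * rec.stain)
        assert integrated_stain_intensity(doubled, seg) == pytest.approx(2 * v, rel=1e-9)
        zero = CellRecord(rec.cell_id, rec.brightfield, rec.darkfield, np.zeros_like(rec.stain))
        assert integrated_stain_intensity(zero, seg) == 0.0

    def test_missing_stain_rejected(self):
        rec, seg = self._cell(with_stain=False)
        with pytest.raises(ValueError, match="stain"):
            integrated_stain_intensity(rec, seg)


class TestPopulationCoupling:
    def test_g2_cells_are_larger_than_g1(self, small_profiles):
        features, _, _, truth = small_profiles
        tt = truth.set_index("cell_id").loc[features.index]
        area = features["bf_shape_area"]
        g1 = area[tt["dna_content"] == 2.0]
        g2 = area[tt["dna_content"] == 4.0]
        assert g2.mean() > g1.mean()

    def test_feature_table_is_finite_and_213_wide(self, small_profiles):
        features, _, qc, _ = small_profiles
        assert features.shape[1] == 213
        assert np.isfinite(features.to_numpy()).all()
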