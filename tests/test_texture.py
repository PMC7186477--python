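import numpy as np
import pytest

import _oracles
from dcehabitat import texture
from dcehabitat._dwt import DEC_LO, dec_hi
from dcehabitat.errors import EmptyMatrixError, EmptyRegionError
from conftest import disk_mask


class TestCatalogue:
    def test_total_is_488(self):
        assert len(texture.FEATURE_NAMES) == 488

    def test_block_sizes(self):
        names = texture.FEATURE_NAMES
        hist = [n for n in names if n in texture.HISTOGRAM_NAMES]
        grlm = [n for n in names if "°" in n]
        dwt = [n for n in names if n.split(" ")[0] in ("haar", "deubechies2", "symlet4")]
        glcm = [n for n in names if n not in hist + grlm + dwt]
        assert (len(hist), len(glcm), len(grlm), len(dwt)) == (4, 380, 44, 60)

    def test_names_unique_and_order_stable(self):
        assert len(set(texture.FEATURE_NAMES)) == 488
        assert texture.FEATURE_NAMES == texture._build_catalogue()


class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        img = np.full((8, 8), 42.0)
        q = texture.quantize(img, np.ones((8, 8), bool), 64)
        assert np.all(q.levels == 1)

    def test_identity_mapping_64_levels(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        q = texture.quantize(img, np.ones((8, 8), bool), 64)
        np.testing.assert_array_equal(q.levels, np.arange(1, 65).reshape(8, 8))

    def test_matches_floor_formula_oracle(self, rng):
        img = rng.uniform(-50, 150, size=(15, 15))
        mask = disk_mask((15, 15), radius=6)
        q = texture.quantize(img, mask, 32)
        np.testing.assert_array_equal(q.levels, _oracles.quantize_loop(img, mask, 32))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            texture.quantize(np.zeros((4, 4)), np.zeros((4, 4), bool), 8)

    def test_levels_in_range(self, rng):
        img = rng.normal(size=(20, 20))
        mask = disk_mask((20, 20), radius=8)
        q = texture.quantize(img, mask, 16)
        assert q.levels[mask].min() >= 1 and q.levels[mask].max() <= 16
        assert np.all(q.levels[~mask] == 0)


class TestHistogramFeatures:
    def test_constant_region_flags_higher_moments(self):
        img = np.full((6, 6), 5.0)
        f = texture.histogram_features(img, np.ones((6, 6), bool))
        assert f["variance"] == 0.0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])

    def test_symmetric_two_point_has_zero_skew(self):
        img = np.array([[1.0, 1.0, 3.0, 3.0]] * 3)
        f = texture.histogram_features(img, np.ones((3, 4), bool))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        vals = rng.normal(10, 4, size=1000)
        f = texture.histogram_features(vals.reshape(25, 40), np.ones((25, 40), bool))
        mean, var, skew, kurt = _oracles.moments_loop(vals.tolist())
        assert f["mean"] == pytest.approx(mean, rel=1e-10)
        assert f["variance"] == pytest.approx(var, rel=1e-10)
        assert f["skewness"] == pytest.approx(skew, rel=1e-10)
        assert f["kurtosis"] == pytest.approx(kurt, rel=1e-10)

    def test_small_region_flagged(self):
        img = np.ones((3, 3))
        mask = np.zeros((3, 3), bool)
        mask[0, :2] = True
        f = texture.histogram_features(img, mask, min_region_pixels=10)
        assert all(np.isnan(v) for v in f.values())


class TestGLCM:
    def test_uniform_2x2_single_entry(self):
        img = np.zeros((2, 2))
        q = texture.quantize(img, np.ones((2, 2), bool), 4)
        mat = texture.glcm(q, (1, 0))
        assert mat[0, 0] == 1.0 and mat.sum() == 1.0

    def test_constant_region_degenerate_features(self, rng):
        q = texture.quantize(np.full((6, 6), 9.0), np.ones((6, 6), bool), 8)
        f = texture.glcm_features(texture.glcm(q, (0, 1)))
        assert f["ENE"] == pytest.approx(1.0)
        assert f["CON"] == 0.0

    def test_matrix_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            img = rng.integers(0, 40, size=(5, 5)).astype(float)
            mask = rng.random((5, 5)) > 0.2
            if mask.sum() < 4:
                continue
            q = texture.quantize(img, mask, 8)
            for offset in [(1, 0), (0, 1), (1, 1), (-1, -1), (2, 0)]:
                try:
                    got = texture.glcm(q, offset)
                except EmptyMatrixError:
                    brute = _oracles.glcm_loop(q.levels, mask, offset, 8)
                    assert brute.sum() == 0
                    continue
                np.testing.assert_allclose(
                    got, _oracles.glcm_loop(q.levels, mask, offset, 8), atol=1e-12
                )

    def test_matrix_sums_to_one(self, seeded_region):
        img, mask = seeded_region
        q = texture.quantize(img, mask, 64)
        for d in (1, 2, 3, 4):
            for off in texture.glcm_offsets(d):
                assert texture.glcm(q, off).sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_pairs_raises(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        mask[4, 4] = True
        q = texture.quantize(np.eye(5), mask, 4)
        with pytest.raises(EmptyMatrixError):
            texture.glcm(q, (1, 0))


class TestGLCMFeatures:
    def test_delta_distribution(self):
        mat = np.zeros((4, 4))
        mat[0, 0] = 1.0
        f = texture.glcm_features(mat)
        assert f["MP"] == 1.0 and f["ENE"] == 1.0 and f["ENT"] == 0.0
        assert f["CON"] == 0.0 and f["DIS"] == 0.0 and f["HOM"] == 1.0

    def test_uniform_two_level_closed_form(self):
        # hand computation over the four cells of the uniform 2x2 matrix
        mat = np.full((2, 2), 0.25)
        f = texture.glcm_features(mat)
        assert f["ENT"] == pytest.approx(np.log(4.0))
        assert f["COR"] == pytest.approx(0.0, abs=1e-12)

    def test_all_stats_match_double_loop_oracle(self, rng):
        for _ in range(25):
            raw = rng.random((6, 6))
            mat = raw + raw.T
            mat /= mat.sum()
            got = texture.glcm_features(mat)
            want = _oracles.glcm_stats_loop(mat)
            for stat in texture.GLCM_STATS:
                assert got[stat] == pytest.approx(want[stat], rel=1e-10, abs=1e-10), stat


class TestGLCMFeatureBlock:
    def test_exactly_380_entries(self, seeded_region):
        img, mask = seeded_region
        q = texture.quantize(img, mask, 16)
        assert len(texture.glcm_feature_block(q)) == 380

    def test_angular_mean_is_arithmetic_mean(self, seeded_region):
        img, mask = seeded_region
        q = texture.quantize(img, mask, 16)
        block = texture.glcm_feature_block(q)
        for d in (1, 2, 3, 4):
            for s in texture.GLCM_STATS:
                directional = [
                    block[f"{s} ({a},{b})"] for a, b in texture.glcm_offsets(d)
                ]
                assert block[f"{s} d{d} avg"] == pytest.approx(
                    np.mean(directional), rel=1e-12
                )

    def test_rotation_permutes_axis_aligned_offsets(self, rng):
        img = rng.normal(size=(20, 20))
        mask = disk_mask((20, 20), radius=8)
        q1 = texture.quantize(img, mask, 16)
        q2 = texture.quantize(np.rot90(img), np.rot90(mask), 16)
        for d in (1, 2):
            f_row = texture.glcm_features(texture.glcm(q1, (d, 0)))
            f_col_rot = texture.glcm_features(texture.glcm(q2, (0, d)))
            for s in texture.GLCM_STATS:
                assert f_row[s] == pytest.approx(f_col_rot[s], rel=1e-9), s


class TestGRLM:
    def test_checkerboard_unit_runs(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 10.0
        q = texture.quantize(img, np.ones((8, 8), bool), 4)
        f = texture.grlm_features(q)
        for angle in (0, 90):
            assert f[f"{angle}°SRE"] == pytest.approx(1.0)
            assert f[f"{angle}°LRE"] == pytest.approx(1.0)

    def test_exactly_44_entries(self, seeded_region):
        img, mask = seeded_region
        q = texture.quantize(img, mask, 16)
        assert len(texture.grlm_features(q)) == 44

    def test_matrices_match_run_walk_oracle(self, rng):
        for _ in range(20):
            img = rng.integers(0, 3, size=(7, 9)).astype(float)
            mask = rng.random((7, 9)) > 0.25
            if mask.sum() < 4:
                continue
            q = texture.quantize(img, mask, 4)
            rows, cols = np.nonzero(mask)
            crop_levels = q.levels[
                rows.min() : rows.max() + 1, cols.min() : cols.max() + 1
            ]
            crop_mask = mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
            for angle in texture.GRLM_ANGLES:
                got = texture.grlm_matrix(q, angle)
                want = _oracles.grlm_loop(
                    crop_levels, crop_mask, angle, 4, max(crop_levels.shape)
                )
                np.testing.assert_array_equal(got, want)

    def test_empty_region_raises(self):
        q = texture.QuantizedRegion(
            levels=np.zeros((4, 4), int),
            mask=np.zeros((4, 4), bool),
            n_levels=4,
            intensity_range=(0, 0),
        )
        with pytest.raises(EmptyRegionError):
            texture.grlm_matrix(q, 0)


class TestDWT:
    def test_constant_image_annihilated_by_details(self):
        img = np.full((32, 32), 7.0)
        mask = np.ones((32, 32), bool)
        for wavelet in ("haar", "deubechies2", "symlet4"):
            f = texture.dwt_features(img, mask, wavelet)
            for level in (1, 2, 3, 4):
                for sb in ("HH", "HV", "HD", "D"):
                    assert f[f"{wavelet} {sb}_{level}"] == pytest.approx(0.0, abs=1e-9)
                # 2-D approximation DC gain is 2 per level
                assert f[f"{wavelet} L_{level}"] == pytest.approx(
                    7.0 * 2.0**level, rel=1e-9
                )

    def test_sixty_entries_over_three_wavelets(self, seeded_region):
        img, mask = seeded_region
        total = {}
        for wavelet in ("haar", "deubechies2", "symlet4"):
            f = texture.dwt_features(img, mask, wavelet)
            assert len(f) == 20
            total.update(f)
        assert len(total) == 60

    def test_vertical_stripes_load_hv_not_hd(self):
        img = np.tile(np.arange(32) % 2 * 10.0, (32, 1))  # varies across columns
        mask = np.ones((32, 32), bool)
        f = texture.dwt_features(img, mask, "haar")
        assert f["haar HV_1"] > f["haar HD_1"]
        assert f["haar HD_1"] == pytest.approx(0.0, abs=1e-9)

    def test_filter_bank_oracle_level1(self):
        # direct filter-bank computation on a tiny image
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16))
        mask = np.ones((16, 16), bool)
        lo = DEC_LO["haar"]
        hi = dec_hi(lo)

        def analyze(x, f0, f1):
            tmp = np.zeros((8, 16))
            for k in range(8):
                for mth in range(2):
                    tmp[k] += f0[mth] * x[(2 * k + mth) % 16]
            out = np.zeros((8, 8))
            for k in range(8):
                for mth in range(2):
                    out[:, k] += f1[mth] * tmp[:, (2 * k + mth) % 16]
            return out

        hv = analyze(img, lo, hi)
        f = texture.dwt_features(img, mask, "haar")
        assert f["haar HV_1"] == pytest.approx(np.abs(hv).mean(), rel=1e-9)


class TestExtractAll:
    def test_length_488(self, seeded_region):
        img, mask = seeded_region
        feats = texture.extract_all(img, mask)
        assert len(feats) == 488
        assert list(feats) == list(texture.FEATURE_NAMES)

    def test_deterministic(self, seeded_region):
        img, mask = seeded_region
        a = texture.extract_all(img, mask)
        b = texture.extract_all(img, mask)
        assert a == b

    def test_small_region_fully_flagged(self):
        img = np.random.default_rng(0).normal(size=(20, 20))
        mask = np.zeros((20, 20), bool)
        mask[5, 5:9] = True
        feats = texture.extract_all(img, mask, min_region_pixels=10)
        assert all(np.isnan(v) for v in feats.values())

    def test_translation_invariance(self, rng):
        patch = rng.normal(100, 20, size=(18, 18))
        mask_patch = disk_mask((18, 18), radius=7)
        img1 = np.zeros((48, 48))
        img1[3:21, 3:21] = patch
        mask1 = np.zeros((48, 48), bool)
        mask1[3:21, 3:21] = mask_patch
        img2 = np.zeros((48, 48))
        img2[22:40, 25:43] = patch
        mask2 = np.zeros((48, 48), bool)
        mask2[22:40, 25:43] = mask_patch
        f1 = texture.extract_all(img1, mask1)
        f2 = texture.extract_all(img2, mask2)
        for name in texture.FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-9, abs=1e-12), name

    def test_all_finite_on_nondegenerate_region(self, seeded_region):
        img, mask = seeded_region
        feats = texture.extract_all(img, mask)
        assert all(np.isfinite(v) for v in feats.values())
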