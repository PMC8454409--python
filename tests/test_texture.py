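"""Texture families: counts, trivial limits, independent oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from perirad import PhantomSpec, build_ring_masks, generate_phantom
from perirad.haralick import (
    METRIC_NAMES,
    cooccurrence_maps,
    glcm_probability_stack,
    quantize,
)
from perirad.phantoms import NEG_TEXTURE, POS_TEXTURE
from perirad.texture import (
    FAMILY_NAMES,
    LAWS_KERNELS,
    TextureConfig,
    collage_maps,
    extract_features,
    gabor_maps,
    gradient_maps,
    gray_stats_maps,
    haralick_maps,
    laws_maps,
    pool_statistics,
    vocabulary,
    zscore_apply,
    zscore_fit,
)

FAMILY_MAP_COUNTS = {"gray": 16, "gradient": 40, "haralick": 52, "laws": 20, "gabor": 28, "collage": 52}


def haralick_oracle(patch, n_levels):
    """Exhaustive neighbor-pair enumeration: build the direction-averaged
    symmetric GLCM of the whole patch and apply the textbook formulas."""
    L = n_levels
    h, w = patch.shape
    P = np.zeros((L, L))
    for dy, dx in ((0, 1), (1, 1), (1, 0), (1, -1)):
        M = np.zeros((L, L))
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w:
                    a, b = patch[y, x], patch[y2, x2]
                    M[a, b] += 1
                    M[b, a] += 1
        P += M / M.sum() / 4.0
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    px = P.sum(axis=1)
    lv = np.arange(L)
    mu = (lv * px).sum()
    var = ((lv - mu) ** 2 * px).sum()

    def xlog(p):
        return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1)), 0)

    out = {
        "contrast": ((i - j) ** 2 * P).sum(),
        "correlation": 0.0 if var == 0 else ((i * j * P).sum() - mu * mu) / var,
        "energy": (P**2).sum(),
        "entropy": -xlog(P).sum(),
        "homogeneity": (P / (1 + (i - j) ** 2)).sum(),
        "variance": ((i - mu) ** 2 * P).sum(),
    }
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (i + j).ravel(), P.ravel())
    k = np.arange(2 * L - 1)
    out["sum_average"] = (k * psum).sum()
    out["sum_variance"] = ((k - out["sum_average"]) ** 2 * psum).sum()
    out["sum_entropy"] = -xlog(psum).sum()
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(i - j).ravel(), P.ravel())
    out["difference_average"] = (lv * pdiff).sum()
    out["difference_variance"] = ((lv - out["difference_average"]) ** 2 * pdiff).sum()
    out["difference_entropy"] = -xlog(pdiff).sum()
    hx = -xlog(px).sum()
    pp = np.outer(px, px)
    m = (P > 0) & (pp > 0)
    hxy1 = -np.where(m, P * np.log2(np.where(m, pp, 1)), 0).sum()
    out["imc1"] = 0.0 if hx == 0 else (out["entropy"] - hxy1) / hx
    return out


class TestVocabulary:
    @pytest.mark.parametrize("family", FAMILY_NAMES)
    def test_per_family_map_counts(self, family):
        cfg = TextureConfig.default()
        assert len(cfg.map_names(family)) == FAMILY_MAP_COUNTS[family]

    def test_total_maps_and_descriptor_count(self):
        cfg = TextureConfig.default()
        n_maps = sum(len(cfg.map_names(f)) for f in cfg.families)
        assert n_maps == 208
        voc = vocabulary(cfg)
        assert len(voc) == 208 * 5 * 4
        assert len(set(voc)) == len(voc)  # unique descriptors

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            TextureConfig(windows=(4,))

    def test_subpixel_gabor_scale_rejected(self):
        with pytest.raises(ValueError, match="wavelength"):
            TextureConfig(gabor_wavelengths_px=(0.5,))


class TestGrayAndGradient:
    def test_constant_slice_limits(self):
        c = np.full((12, 12), 7.0)
        g = gray_stats_maps(c)
        assert np.all(g["std_w5"] == 0) and np.all(g["mean_w5"] == 7.0)
        assert np.all(g["range_w9"] == 0)
        for m in gradient_maps(c).values():
            assert np.all(m == 0)

    def test_window3_mean_equals_nine_pixel_average(self, rng):
        a = rng.normal(size=(10, 11))
        got = gray_stats_maps(a, windows=(3,))["mean_w3"]
        y, x = 5, 6
        assert got[y, x] == pytest.approx(a[y - 1 : y + 2, x - 1 : x + 2].mean(), abs=1e-12)

    def test_linear_ramp_gradient_magnitude(self):
        slope = 1.7
        ramp = np.outer(np.arange(16), np.ones(16)) * slope
        m = gradient_maps(ramp, windows=(3,))
        interior = m["mean_mag_w3"][3:-3, 3:-3]
        assert np.allclose(interior, slope, atol=1e-10)
        assert np.allclose(m["std_mag_w3"][3:-3, 3:-3], 0.0, atol=1e-10)

    def test_window_larger_than_slice_rejected(self):
        with pytest.raises(ValueError, match="larger than slice"):
            gray_stats_maps(np.zeros((5, 5)), windows=(9,))


class TestHaralick:
    def test_constant_slice_degenerate_values(self):
        m = haralick_maps(np.full((9, 9), 3.0), windows=(3,), n_levels=8)
        assert np.all(m["contrast_w3"] == 0)
        assert np.all(m["energy_w3"] == 1)
        assert np.all(m["entropy_w3"] == 0)
        assert np.all(m["correlation_w3"] == 0)  # single-level convention

    def test_metrics_match_pair_enumeration_oracle(self, rng):
        """50+ random patches: implementation center-pixel values equal the
        exhaustive pair-counting oracle to 1e-10."""
        worst = 0.0
        for trial in range(50):
            L = int(rng.integers(2, 9))
            size = int(rng.choice([5, 7]))
            patch = rng.integers(0, L, size=(size, size))
            maps = cooccurrence_maps(patch, L, size)
            oracle = haralick_oracle(patch, L)
            c = size // 2
            for name in METRIC_NAMES:
                worst = max(worst, abs(maps[name][c, c] - oracle[name]))
        # checkerboard as an explicit structured case
        board = np.indices((5, 5)).sum(axis=0) % 2
        maps = cooccurrence_maps(board, 2, 5)
        oracle = haralick_oracle(board, 2)
        for name in METRIC_NAMES:
            worst = max(worst, abs(maps[name][2, 2] - oracle[name]))
        assert worst < 1e-10

    def test_per_pixel_glcm_symmetric_and_normalized(self, rng):
        codes = rng.integers(0, 6, size=(12, 10))
        pc, P = glcm_probability_stack(codes, 6, 5)
        assert np.abs(P.sum(axis=0) - 1.0).max() < 1e-12
        idx = {int(c): k for k, c in enumerate(pc)}
        for a in range(6):
            for b in range(6):
                if a * 6 + b in idx and b * 6 + a in idx:
                    assert np.abs(P[idx[a * 6 + b]] - P[idx[b * 6 + a]]).max() < 1e-12

    def test_masked_evaluation_matches_full(self, rng):
        codes = rng.integers(0, 8, size=(14, 12))
        mask = rng.random((14, 12)) > 0.4
        full = cooccurrence_maps(codes, 8, 3)
        masked = cooccurrence_maps(codes, 8, 3, pixel_mask=mask)
        for name in METRIC_NAMES:
            assert np.array_equal(full[name][mask], masked[name][mask])


class TestLaws:
    def test_constant_slice_all_zero(self):
        for name, m in laws_maps(np.full((10, 10), 5.0)).items():
            assert np.allclose(m, 0.0, atol=1e-9), name

    def test_impulse_response_is_flipped_outer_product(self):
        imp = np.zeros((11, 11))
        imp[5, 5] = 1.0
        maps = laws_maps(imp)
        ka, kb = LAWS_KERNELS["E5"], LAWS_KERNELS["L5"]
        expected = np.outer(ka, kb)
        assert np.allclose(maps["E5L5"][3:8, 3:8], expected, atol=1e-12)

    def test_twenty_ordered_distinct_pairs(self):
        maps = laws_maps(np.zeros((8, 8)))
        assert len(maps) == 20
        assert "E5L5" in maps and "L5R5" in maps and "L5L5" not in maps


class TestGabor:
    def test_constant_slice_zero_response(self):
        maps = gabor_maps(np.full((16, 16), 100.0), (22.5, 90.0), (2.0, 4.0))
        for m in maps.values():
            assert np.abs(m).max() < 1e-9

    def test_matched_grating_beats_orthogonal_filter(self):
        wavelength = 4.0
        y, x = np.mgrid[0:32, 0:32]
        theta = np.deg2rad(22.5)
        grating = np.sin(2 * np.pi / wavelength * (x * np.cos(theta) + y * np.sin(theta)))
        maps = gabor_maps(grating, (22.5, 112.5), (wavelength,))
        matched = maps[f"t22.5_l{wavelength:g}"][8:-8, 8:-8].mean()
        orthogonal = maps[f"t112.5_l{wavelength:g}"][8:-8, 8:-8].mean()
        assert matched > orthogonal

    def test_empty_grids_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            gabor_maps(np.zeros((8, 8)), (), (2.0,))


class TestCollage:
    def test_ramp_has_uniform_orientation_and_zero_entropy(self):
        ramp = np.outer(np.arange(16), np.ones(16)) * 2.0
        m = collage_maps(ramp, windows=(3,), n_bins=16)
        assert np.allclose(m["entropy_w3"], 0.0, atol=1e-12)

    def test_orientation_boundary_has_higher_entropy_than_interiors(self):
        y, x = np.mgrid[0:40, 0:40]
        left = np.sin(2 * np.pi * x / 4.0)
        right = np.sin(2 * np.pi * y / 4.0)
        img = np.where(x < 20, left, right)
        m = collage_maps(img, windows=(5,), n_bins=16)
        ent = m["entropy_w5"]
        boundary = ent[10:30, 18:22].mean()
        interior = max(ent[10:30, 5:12].mean(), ent[10:30, 28:35].mean())
        assert boundary > interior


class TestAggregation:
    def test_pool_of_three(self):
        st = pool_statistics([1.0, 2.0, 3.0])
        assert st["mean"] == 2.0 and st["median"] == 2.0

    def test_statistics_match_textbook_moments(self, rng):
        pool = rng.normal(size=400)
        st = pool_statistics(pool)
        assert st["mean"] == pytest.approx(pool.mean(), abs=1e-12)
        assert st["median"] == pytest.approx(np.median(pool), abs=1e-12)
        assert st["std"] == pytest.approx(pool.std(ddof=0), abs=1e-12)
        assert st["skewness"] == pytest.approx(stats.skew(pool, bias=True), abs=1e-10)
        assert st["kurtosis"] == pytest.approx(stats.kurtosis(pool, fisher=True, bias=True), abs=1e-10)

    def test_constant_pool_conventions(self):
        st = pool_statistics(np.full(50, 3.3))
        assert st["std"] == 0.0 and st["skewness"] == 0.0 and st["kurtosis"] == 0.0

    def test_empty_pool_is_nan(self):
        st = pool_statistics(np.array([]))
        assert all(np.isnan(v) for v in st.values())


class TestAggregationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_pool_statistics_agree_with_scipy_moments(self, pool):
        pool = np.asarray(pool)
        st_ = pool_statistics(pool)
        assert st_["mean"] == pytest.approx(pool.mean(), rel=1e-9, abs=1e-9)
        assert st_["std"] == pytest.approx(pool.std(ddof=0), rel=1e-9, abs=1e-9)
        if pool.std() > 1e-6 * (1 + np.abs(pool).max()):
            assert st_["skewness"] == pytest.approx(
                stats.skew(pool, bias=True), rel=1e-6, abs=1e-6
            )
            assert st_["kurtosis"] == pytest.approx(
                stats.kurtosis(pool, fisher=True, bias=True), rel=1e-6, abs=1e-6
            )


class TestExtractFeatures:
    def test_deterministic_and_slice_order_free(self, phantom_pair, fast_config):
        vol, mask, comps = phantom_pair
        a = extract_features(vol, comps, fast_config)
        b = extract_features(vol, comps, fast_config)
        assert a.equals(b)

    def test_full_vocabulary_size_and_order(self, phantom_pair):
        vol, mask, comps = phantom_pair
        cfg = TextureConfig(families=("gray", "laws"), windows=(3,))
        s = extract_features(vol, comps, cfg)
        assert list(s.index) == vocabulary(cfg)
        assert len(s) == (4 + 20) * 5 * 4
        assert s.notna().all()

    def test_offset_invariance_of_filter_families(self, rng, phantom_pair, fast_config):
        """Adding a constant leaves Laws, Gabor, gradient and orientation
        co-occurrence maps unchanged (to 1e-8); the gray local mean shifts by
        exactly that constant."""
        a = rng.normal(50.0, 10.0, size=(20, 18))
        b = a + 137.0
        for fn in (lambda s: gradient_maps(s, (3,)), laws_maps,
                   lambda s: gabor_maps(s, (45.0,), (4.0,)),
                   lambda s: collage_maps(s, (3,), 16)):
            ma, mb = fn(a), fn(b)
            for name in ma:
                assert np.allclose(ma[name], mb[name], atol=1e-8), name
        ga, gb = gray_stats_maps(a, (3,)), gray_stats_maps(b, (3,))
        assert np.allclose(gb["mean_w3"], ga["mean_w3"] + 137.0, atol=1e-8)
        assert np.allclose(gb["std_w3"], ga["std_w3"], atol=1e-8)

        # volume level: descriptors behave the same way (float32 storage
        # limits agreement to ~1e-4)
        vol, mask, comps = phantom_pair
        sa = extract_features(vol, comps, fast_config)
        from perirad.core import ImageVolume

        vol2 = ImageVolume(np.asarray(vol.data, dtype=np.float64) + 25.0, vol.spacing_mm)
        sb = extract_features(vol2, comps, fast_config)
        for name in sa.index:
            fam, mname, stat, comp = name.split(".")
            if fam in ("gradient", "collage"):
                assert sb[name] == pytest.approx(sa[name], abs=1e-4), name
            elif fam == "gray" and mname.startswith("mean") and stat in ("mean", "median"):
                assert sb[name] == pytest.approx(sa[name] + 25.0, abs=1e-4), name

    def test_class_separation_of_cooccurrence_correlation(self):
        """The positive phenotype (long correlation length, homogeneous
        texture) shows higher intratumoral co-occurrence correlation than the
        negative one.  The window (17 px) spans several correlation lengths:
        much smaller windows bias the local correlation estimate downward for
        the smooth class and can invert the physical ordering."""
        cfg = TextureConfig(families=("haralick",), windows=(17,), glcm_levels=32)
        med = {"pos": [], "neg": []}
        for s in range(20):
            for label, tex in (("pos", POS_TEXTURE), ("neg", NEG_TEXTURE)):
                vol, mask = generate_phantom(PhantomSpec(seed=500 + s, class_label=label, texture=tex))
                comps = build_ring_masks(mask, vol.spacing_mm)
                feats = extract_features(vol, comps, cfg)
                med[label].append(feats["haralick.correlation_w17.mean.intra"])
        assert np.median(med["pos"]) > np.median(med["neg"])


class TestZScore:
    def test_hand_example_population_sd(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        p = zscore_fit(df)
        z = zscore_apply(p, df)
        assert np.allclose(z["a"], [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_constant_column_flagged_and_zeroed(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant column"):
            p = zscore_fit(df)
        z = zscore_apply(p, df)
        assert p.zero_sd_columns == ["b"]
        assert np.all(z["b"] == 0.0)

    def test_training_columns_standardized(self, rng):
        df = pd.DataFrame(rng.normal(2.0, 3.0, size=(50, 4)), columns=list("abcd"))
        z = zscore_apply(zscore_fit(df), df)
        assert np.abs(z.mean(axis=0)).max() < 1e-8
        assert np.abs(z.std(axis=0, ddof=0) - 1).max() < 1e-8

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            zscore_fit(pd.DataFrame({"a": [1.0]}))
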