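"""Neighborhood statistics, 48-feature schema, balancing, candidates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tissuefate import features, geometry


def brute_force_stats(block: np.ndarray) -> np.ndarray:
    """Independent 12-statistic oracle built on numpy/scipy defaults."""
    x = block.reshape(-1)
    if np.ptp(x) == 0:
        skew = kurt = 0.0
    else:
        skew = sps.skew(x)
        kurt = sps.kurtosis(x)          # excess, population moments
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    return np.array([
        np.ptp(x), x.mean(), np.median(x), x.min(), x.max(), sd, skew, kurt,
        np.percentile(x, 10), np.percentile(x, 25),
        np.percentile(x, 75), np.percentile(x, 90),
    ])


class TestNeighborhoodStats:
    def test_constant_neighborhood(self):
        vol = np.full((3, 5, 5), 7.5)
        s = features.neighborhood_stats(vol, (1, 2, 2))
        expected = [0, 7.5, 7.5, 7.5, 7.5, 0, 0, 0, 7.5, 7.5, 7.5, 7.5]
        assert s == pytest.approx(expected)

    def test_enumerated_1_to_75(self):
        vol = np.arange(1.0, 76.0).reshape(3, 5, 5)
        s = features.neighborhood_stats(vol, (1, 2, 2))
        assert len(s) == 12
        assert s[features.STAT_NAMES.index("mean")] == pytest.approx(38.0)
        assert s[features.STAT_NAMES.index("median")] == pytest.approx(38.0)
        assert s[features.STAT_NAMES.index("min")] == 1.0
        assert s[features.STAT_NAMES.index("max")] == 75.0
        assert s[features.STAT_NAMES.index("range")] == 74.0
        assert s == pytest.approx(brute_force_stats(vol))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           voxel=st.tuples(st.integers(0, 3), st.integers(0, 6),
                           st.integers(0, 6)))
    def test_matches_oracle_with_border_clipping(self, seed, voxel):
        vol = np.random.default_rng(seed).normal(size=(4, 7, 7))
        s, r, c = voxel
        block = vol[max(s - 1, 0):s + 2, max(r - 2, 0):r + 3,
                    max(c - 2, 0):c + 3]
        got = features.neighborhood_stats(vol, voxel)
        assert got == pytest.approx(brute_force_stats(block), rel=1e-9, abs=1e-9)

    def test_out_of_grid_voxel_rejected(self):
        with pytest.raises(ValueError):
            features.neighborhood_stats(np.zeros((2, 4, 4)), (5, 0, 0))


class TestFeatureVector:
    def test_schema_is_48_ordered_blocks(self):
        assert features.N_FEATURES == 48
        assert len(features.FEATURE_SCHEMA) == 48
        blocks = [n.rsplit("_", 1)[0] for n in features.FEATURE_SCHEMA[::12]]
        assert [features.FEATURE_SCHEMA[i * 12].startswith(b)
                for i, b in enumerate(("adc_ipsi", "rttp_ipsi",
                                       "adc_contra", "rttp_contra"))]
        for i, block in enumerate(features.BLOCK_NAMES):
            chunk = features.FEATURE_SCHEMA[i * 12:(i + 1) * 12]
            assert all(name.startswith(block) for name in chunk)
            assert tuple(n[len(block) + 1:] for n in chunk) == features.STAT_NAMES

    def test_vector_length_and_symmetric_input_blocks(self):
        rng = np.random.default_rng(3)
        half = rng.normal(900, 50, size=(6, 32, 16))
        adc = np.concatenate([half, half[:, :, ::-1]], axis=2)
        rttp = np.zeros_like(adc)
        t = geometry.MidlineTransform(0.0, 0.0, adc.shape, 2.0)
        v = features.extract_voxel_features(adc, rttp, t, (3, 10, 5))
        assert v.shape == (48,)
        np.testing.assert_allclose(v[:12], v[24:36], atol=1e-9)   # ADC blocks
        np.testing.assert_allclose(v[12:24], v[36:48], atol=1e-9)  # rTTP blocks

    def test_vectorized_extraction_matches_per_voxel(self):
        rng = np.random.default_rng(5)
        adc = rng.normal(size=(6, 20, 20))
        rttp = rng.normal(size=(6, 20, 20))
        t = geometry.MidlineTransform(3.0, 1.5, adc.shape, 2.0)
        vox = np.array([[1, 4, 3], [3, 0, 0], [4, 19, 19], [2, 10, 7]])
        X = features.extract_case_features(adc, rttp, t, vox)
        assert X.shape == (4, 48)
        for i, v in enumerate(vox):
            np.testing.assert_allclose(
                X[i], features.extract_voxel_features(adc, rttp, t, tuple(v)),
                atol=1e-9)


class TestCandidatesAndWindow:
    def test_window_maximizes_lesion_coverage(self):
        brain = np.zeros((20, 8, 8), bool)
        brain[2:18] = True
        lesion = np.zeros_like(brain)
        lesion[8:15, 2:6, 2:6] = True      # lesion on slices 8..14
        assert features.select_slice_window(lesion, brain) == (8, 14)

    def test_window_shrinks_with_warning_for_thin_brain(self):
        brain = np.zeros((5, 4, 4), bool)
        brain[1:4] = True
        with pytest.warns(UserWarning, match="shrink"):
            lo, hi = features.select_slice_window(np.zeros_like(brain), brain)
        assert hi - lo + 1 == 3

    def test_candidates_confined_to_hemisphere_and_window(self):
        brain = np.ones((10, 6, 6), bool)
        hemi = np.zeros_like(brain)
        hemi[:, :, :3] = True
        vox = features.candidate_voxels(brain, hemi, (2, 8))
        assert len(vox) == 7 * 6 * 3
        assert vox[:, 0].min() >= 2 and vox[:, 0].max() <= 8
        assert (vox[:, 2] < 3).all()


def _fake_case(case_id, n_pos, n_neg, scenario="SR", seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    return features.CaseFeatures(
        case_id=case_id, scenario=scenario,
        X=rng.normal(size=(n, 48)).astype(np.float32),
        labels=np.r_[np.ones(n_pos, np.int8), np.zeros(n_neg, np.int8)],
        voxels=np.zeros((n, 3), np.intp),
        window=(0, 6), voxel_volume_mm3=5.7129)


class TestBalancing:
    def test_balancing_rule_1000_5000_gives_2000_rows(self):
        m = features.build_training_matrix([_fake_case("a", 1000, 5000)], seed=1)
        assert m.X.shape == (2000, 48)
        assert m.labels.mean() == 0.5

    def test_balance_exact_across_multiple_cases(self):
        m = features.build_training_matrix(
            [_fake_case("a", 100, 700), _fake_case("b", 300, 400, seed=2)],
            seed=3)
        assert m.labels.mean() == 0.5
        assert m.X.shape[0] == 2 * (100 + 300)

    def test_undersampling_reproducible_under_seed(self):
        cfs = [_fake_case("a", 50, 500)]
        m1 = features.build_training_matrix(cfs, seed=9)
        m2 = features.build_training_matrix(cfs, seed=9)
        assert (m1.X == m2.X).all()

    def test_zero_infarct_case_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no infarct"):
            m = features.build_training_matrix(
                [_fake_case("empty", 0, 100), _fake_case("b", 10, 90)], seed=0)
        assert set(m.case_ids) == {"b"}

    def test_zero_noninfarct_case_is_error(self):
        with pytest.raises(ValueError, match="non-infarct"):
            features.build_training_matrix([_fake_case("a", 10, 0)], seed=0)
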