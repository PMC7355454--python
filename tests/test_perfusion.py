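"""Concentration conversion, TTP/rTTP, threshold masks and volumes."""

import numpy as np
import pytest

from tissuefate import perfusion


def _series(curves, shape=(1, 1)):
    """Stack per-voxel curves into a (frames, *shape) array."""
    arr = np.asarray(curves, dtype=np.float64).T
    return arr.reshape(arr.shape[0], *shape)


class TestSignalToConcentration:
    def test_flat_signal_gives_zero_concentration(self):
        s = _series([[100.0] * 10])
        conc, valid = perfusion.signal_to_concentration(s, te_s=0.035,
                                                        n_baseline=5)
        assert valid.all()
        assert conc == pytest.approx(0.0, abs=1e-9)

    def test_known_drop_hand_value(self):
        # S = S0 * e^-1 at TE 35 ms -> C = 1/0.035 = 28.571 1/s
        curve = [100.0] * 8 + [100.0 * np.exp(-1.0)]
        conc, _ = perfusion.signal_to_concentration(_series([curve]), 0.035)
        assert conc[-1, 0, 0] == pytest.approx(28.5714, abs=2e-3)

    def test_nonpositive_signal_clamped_and_s0_invalid_flagged(self):
        good = [50.0] * 8 + [-5.0, 50.0]
        bad = [0.0] * 10
        conc, valid = perfusion.signal_to_concentration(
            _series([good, bad], shape=(2,)), 0.035)
        assert valid[0] and not valid[1]
        assert np.isfinite(conc[:, 0]).all()      # clamped, not -inf
        assert np.isnan(conc[:, 1]).all()

    def test_parameter_validation(self):
        s = _series([[1.0] * 10])
        with pytest.raises(ValueError):
            perfusion.signal_to_concentration(s, te_s=0.0)
        with pytest.raises(ValueError):
            perfusion.signal_to_concentration(s, 0.035, n_baseline=2)


class TestComputeTTP:
    def test_peak_frame_times_tr(self):
        conc = np.zeros((50, 1, 1, 1))
        conc[20] = 5.0
        assert perfusion.compute_ttp(conc, 1.5)[0, 0, 0] == pytest.approx(30.0)

    def test_constant_curve_takes_earliest_tie(self):
        conc = np.ones((50, 1, 1))
        assert perfusion.compute_ttp(conc, 1.7)[0, 0] == 0.0

    def test_monotone_curve_peaks_at_last_frame(self):
        conc = np.arange(50.0)[:, None, None] * np.ones((1, 2, 2))
        assert perfusion.compute_ttp(conc, 1.5) == pytest.approx(49 * 1.5)

    def test_all_invalid_voxel_is_nan(self):
        conc = np.full((10, 1, 1), np.nan)
        assert np.isnan(perfusion.compute_ttp(conc, 1.5)).all()


class TestComputeRTTP:
    def test_hand_arithmetic_on_constructed_map(self):
        ttp = np.zeros((1, 2, 4))
        ttp[0, :, :2] = 18.0       # left hemisphere
        ttp[0, :, 2:] = 24.0       # right hemisphere
        ttp[0, 0, 3] = 25.0        # lesion-side voxel
        left = np.zeros_like(ttp, bool); left[0, :, :2] = True
        right = np.zeros_like(ttp, bool); right[0, :, 2:] = True
        r = perfusion.compute_rttp(ttp, left, right)
        assert r.contralateral == "left"
        assert r.baseline_ttp_s == pytest.approx(18.0)
        assert r.rttp_s[0, 0, 3] == pytest.approx(7.0)
        assert r.lesion_side == "right"

    def test_median_tie_uses_hint_and_warns(self):
        ttp = np.full((1, 2, 4), 12.0)
        left = np.zeros_like(ttp, bool); left[0, :, :2] = True
        right = np.zeros_like(ttp, bool); right[0, :, 2:] = True
        with pytest.warns(UserWarning, match="tie"):
            r = perfusion.compute_rttp(ttp, left, right, lesion_hint="left")
        assert r.contralateral == "right"
        with pytest.warns(UserWarning):
            assert perfusion.compute_rttp(ttp, left, right).contralateral == "left"

    def test_empty_hemisphere_rejected(self):
        ttp = np.zeros((1, 2, 2))
        with pytest.raises(ValueError):
            perfusion.compute_rttp(ttp, np.zeros_like(ttp, bool),
                                   np.ones_like(ttp, bool))


class TestLesionVolumes:
    def test_voxel_count_to_ml_hand_value(self):
        # 175 voxels at 0.9375 x 0.9375 x 6.5 mm = 999.756 mm^3
        mask = np.zeros((22, 256, 256), bool)
        mask.flat[:175] = True
        ml = perfusion.mask_volume_ml(mask, (6.5, 0.9375, 0.9375))
        assert ml == pytest.approx(0.99976, abs=1e-4)

    def test_all_normal_tissue_has_zero_volumes(self):
        adc = np.full((2, 8, 8), 900.0)
        rttp = perfusion.RTTPMap(np.zeros((2, 8, 8)), 12.0, "left")
        brain = np.ones((2, 8, 8), bool)
        vols, _ = perfusion.lesion_masks_and_volumes(
            adc, rttp, brain, (6.5, 1.0, 1.0))
        assert vols.core_ml == vols.perfusion_ml == vols.severe_ml == 0.0

    def test_default_thresholds(self):
        assert perfusion.RTTP_PERFUSION_THRESHOLD_S == 4.5
        assert perfusion.ADC_CORE_THRESHOLD == 600.0
        vols = perfusion.LesionVolumes(1.0, 2.0, 0.5)
        assert vols.perfusion_threshold_s == 4.5

    def test_severe_nested_in_perfusion_mask(self):
        rng = np.random.default_rng(0)
        rttp = perfusion.RTTPMap(rng.normal(4, 3, (4, 8, 8)), 10.0, "left")
        brain = np.ones((4, 8, 8), bool)
        _, masks = perfusion.lesion_masks_and_volumes(
            np.full((4, 8, 8), 900.0), rttp, brain, (6.5, 1.0, 1.0))
        assert (masks["severe"] <= masks["perfusion"]).all()

    def test_missing_spacing_rejected(self):
        with pytest.raises(ValueError):
            perfusion.mask_volume_ml(np.ones((1, 1, 1), bool), (0.0, 1.0, 1.0))


def test_noiseless_phantom_rttp_matches_truth_within_one_tr(prepared_noiseless):
    prepared, case, gt, cfg = prepared_noiseless
    hypo = gt.hypoperfusion_mask
    err = np.abs(prepared.rttp.rttp_s[hypo] - gt.true_rttp_s[hypo])
    assert err.max() <= cfg.tr_s + 1e-9
    # contralateral hemisphere rTTP has median 0 by construction
    from tissuefate import geometry
    left, right = geometry.hemisphere_masks(gt.brain_mask, gt.midline)
    contra = left if prepared.rttp.contralateral == "left" else right
    assert np.nanmedian(prepared.rttp.rttp_s[contra]) == pytest.approx(0.0)
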