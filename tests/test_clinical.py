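"""Clinical chain: VFA T1 mapping, SPGR inversion, calibration, mapping."""
import numpy as np
import pytest

from dcepk.clinical import (
    DceAcquisition,
    VfaAcquisition,
    VfaMaps,
    calibration_factor,
    make_brain_mask,
    pixelwise_map,
    select_vof,
    signal_to_concentration,
    spgr_signal,
    vfa_fit,
)
from dcepk.forward_model import ConcentrationCurve, PKParams, TimeGrid, tofts_forward
from dcepk.nlsq import NlsqConfig

ANGLES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def synth_vfa(k, t10, shape=(1,), tr=4.43e-3):
    sig = np.stack([np.full(shape, spgr_signal(k, t10, a, tr))
                    for a in ANGLES], axis=-1)
    return VfaAcquisition(sig, flip_angles_deg=ANGLES, tr=tr)


class TestVfaFit:
    def test_recovery_within_tenth_percent(self):
        maps = vfa_fit(synth_vfa(1000.0, 1.4))
        assert maps.k_map[0] == pytest.approx(1000.0, rel=1e-3)
        assert maps.t10_map[0] == pytest.approx(1.4, rel=1e-3)
        assert maps.n_failed == 0

    def test_signal_vanishes_at_zero_flip_angle(self):
        assert spgr_signal(1000.0, 1.4, 0.0, 4.43e-3) == 0.0

    def test_two_angle_linearized_equals_nonlinear(self):
        # two unknowns, two noiseless equations: both solutions exact
        tr = 4.43e-3
        sig = np.array([[spgr_signal(800.0, 1.1, a, tr) for a in (10.0, 25.0)]])
        maps = vfa_fit(VfaAcquisition(sig, flip_angles_deg=(10.0, 25.0), tr=tr))
        assert maps.t10_map[0] == pytest.approx(1.1, rel=1e-6)
        assert maps.k_map[0] == pytest.approx(800.0, rel=1e-6)

    def test_bad_pixels_masked_and_counted(self):
        acq = synth_vfa(1000.0, 1.4, shape=(3,))
        signals = acq.signals.copy()
        signals[1] = 0.0  # dead pixel
        maps = vfa_fit(VfaAcquisition(signals, flip_angles_deg=ANGLES,
                                      tr=acq.tr))
        assert maps.n_failed == 1
        assert maps.t10_map[1] == 0.0


@pytest.fixture(scope="module")
def setting(reference_cp):
    """Synthetic single-pixel SPGR series from a known tissue curve."""
    dce = DceAcquisition()
    k, t10 = 1000.0, 1.4
    c_true = tofts_forward(reference_cp, PKParams(0.2, 0.3, 0.05, 45.0)).values
    r1_t = 1.0 / t10 + dce.r1 * c_true
    signal = spgr_signal(k, 1.0 / r1_t, dce.flip_angle_deg, dce.tr)
    maps = VfaMaps(k_map=np.array([k]), t10_map=np.array([t10]),
                   s0_map=np.array([0.0]))
    return dce, maps, c_true, signal


class TestSignalToConcentration:
    def test_baseline_signal_gives_zero_concentration(self, setting):
        dce, maps, _, _ = setting
        s0 = spgr_signal(maps.k_map, maps.t10_map, dce.flip_angle_deg, dce.tr)
        conc, _ = signal_to_concentration(np.repeat(s0, 5)[None, :], maps, dce)
        np.testing.assert_allclose(conc[0], 0.0, atol=1e-12)

    def test_forward_inverse_round_trip(self, setting):
        dce, maps, c_true, signal = setting
        conc, n_invalid = signal_to_concentration(signal[None, :], maps, dce)
        assert np.nanmax(np.abs(conc[0] - c_true)) < 1e-6
        assert n_invalid[0] == 0

    def test_cf_scales_linearly(self, setting):
        dce, maps, _, signal = setting
        c1, _ = signal_to_concentration(signal[None, :], maps, dce, cf=1.0)
        c2, _ = signal_to_concentration(signal[None, :], maps, dce, cf=2.0)
        np.testing.assert_allclose(c2, 2 * c1)

    def test_non_invertible_frames_flagged(self, setting):
        dce, maps, _, signal = setting
        bad = signal.copy()
        bad[5] = signal.max() * 50  # unphysically bright frame
        conc, n_invalid = signal_to_concentration(bad[None, :], maps, dce)
        assert n_invalid[0] == 1
        assert np.isnan(conc[0, 5])


class TestCalibrationFactor:
    def test_identical_curves(self, reference_cp):
        assert calibration_factor(reference_cp, reference_cp) == 1.0

    def test_doubled_vof_halves_cf(self, reference_cp):
        vof = ConcentrationCurve(reference_cp.grid, 2 * reference_cp.values)
        assert calibration_factor(reference_cp, vof) == pytest.approx(0.5)

    def test_hand_trapezoid_on_toy_curve(self):
        grid = TimeGrid(n_frames=3, dt=1.0)
        aif = ConcentrationCurve(grid, np.array([0.0, 2.0, 0.0]))  # AUC 2
        vof = ConcentrationCurve(grid, np.array([1.0, 1.0, 1.0]))  # AUC 2
        assert calibration_factor(aif, vof) == pytest.approx(1.0)

    def test_zero_vof_area_rejected(self, reference_cp):
        zero = ConcentrationCurve(reference_cp.grid,
                                  np.zeros(reference_cp.grid.n_frames))
        with pytest.raises(ValueError):
            calibration_factor(reference_cp, zero)


class TestSelectVof:
    def test_single_pixel_mask(self, grid):
        conc = np.random.default_rng(0).random((3, 3, grid.n_frames))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        curve = select_vof(conc, grid, mask=mask)
        np.testing.assert_array_equal(curve.values, conc[1, 2])

    def test_mean_over_two_pixel_mask(self, grid):
        conc = np.random.default_rng(1).random((2, 2, grid.n_frames))
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        curve = select_vof(conc, grid, mask=mask)
        np.testing.assert_allclose(curve.values,
                                   (conc[0, 0] + conc[1, 1]) / 2)

    def test_auto_selection_finds_hottest_pixel(self, grid):
        conc = np.zeros((4, 4, grid.n_frames))
        conc[2, 3, 10] = 9.0
        curve = select_vof(conc, grid)
        np.testing.assert_array_equal(curve.values, conc[2, 3])

    def test_empty_mask_rejected(self, grid):
        with pytest.raises(ValueError):
            select_vof(np.zeros((2, 2, grid.n_frames)), grid,
                       mask=np.zeros((2, 2), dtype=bool))


class TestMakeBrainMask:
    def test_uniform_image_gives_full_mask(self):
        assert make_brain_mask(np.ones((4, 4)), 0.5).all()

    def test_largest_component_survives(self):
        img = np.zeros((10, 10))
        img[1:6, 1:6] = 1.0  # 25-pixel blob
        img[8:10, 8:10] = 1.0  # 4-pixel blob
        mask = make_brain_mask(img, 0.5)
        assert mask[2, 2] and not mask[8, 8]

    def test_threshold_zero_keeps_positive_field(self):
        img = np.full((3, 3), 2.0)
        assert make_brain_mask(img, 0.0).all()


class TestRoiCcc:
    def test_identical_maps_give_unity(self):
        from dcepk.clinical import roi_ccc

        rng = np.random.default_rng(0)
        img = rng.random((5, 5))
        roi = np.zeros((5, 5), dtype=bool)
        roi[1:4, 1:4] = True
        assert roi_ccc(img, img, roi) == pytest.approx(1.0)

    def test_invalid_pixels_excluded(self):
        from dcepk.clinical import roi_ccc

        a = np.array([[1.0, 2.0, np.nan, 4.0]])
        b = np.array([[1.0, 2.0, 3.0, 4.0]])
        roi = np.ones((1, 4), dtype=bool)
        assert roi_ccc(a, b, roi) == pytest.approx(1.0)

    def test_too_small_roi_rejected(self):
        from dcepk.clinical import roi_ccc

        one_pixel = np.array([[True, False], [False, False]])
        with pytest.raises(ValueError):
            roi_ccc(np.ones((2, 2)), np.ones((2, 2)), one_pixel)


class TestPixelwiseMap:
    def test_nlsq_map_recovers_phantom_parameters(self, reference_cp):
        """8x8 phantom of four parameter quadrants, noiseless."""
        grid = reference_cp.grid
        quads = [PKParams(0.10, 0.30, 0.02, 42.0),
                 PKParams(0.25, 0.50, 0.06, 48.0),
                 PKParams(0.05, 0.10, 0.01, 44.0),
                 PKParams(0.30, 0.45, 0.09, 46.0)]
        conc = np.zeros((8, 8, grid.n_frames))
        truth_kep = np.zeros((8, 8))
        for q, p in enumerate(quads):
            r, c = divmod(q, 2)
            curve = tofts_forward(reference_cp, p).values
            conc[r * 4:(r + 1) * 4, c * 4:(c + 1) * 4] = curve
            truth_kep[r * 4:(r + 1) * 4, c * 4:(c + 1) * 4] = p.kep
        mask = np.ones((8, 8), dtype=bool)
        result = pixelwise_map(conc, reference_cp, NlsqConfig(), mask)
        np.testing.assert_allclose(result.values["kep"], truth_kep, rtol=0.01)
        assert result.uncertainties is None

    def test_constant_phantom_gives_constant_maps(self, reference_cp,
                                                  toy_dataset):
        from dcepk.rnn import TrainConfig, build_model, train_model
        from test_rnn import small_cfg

        model = build_model(small_cfg(dropout_rate=0.0), seed=9)
        train_model(model, toy_dataset, TrainConfig(epochs=1, batch_size=64,
                                                    seed=9))
        curve = toy_dataset.inputs[0, :, 1]
        conc = np.tile(curve, (3, 3, 1))
        result = pixelwise_map(conc, reference_cp, model,
                               np.ones((3, 3), dtype=bool), n_mc=4)
        kep_map = result.values["kep"]
        assert np.ptp(kep_map) < 1e-12  # per-pixel independence
        # dropout-0 model: zero uncertainty images
        assert np.all(result.uncertainties["kep"] == 0)

    def test_frame_count_mismatch_rejected(self, reference_cp):
        with pytest.raises(ValueError, match="frames"):
            pixelwise_map(np.zeros((2, 2, 10)), reference_cp, NlsqConfig(),
                          np.ones((2, 2), dtype=bool))

    def test_pixel_permutation_equivariance(self, reference_cp):
        grid = reference_cp.grid
        rng = np.random.default_rng(2)
        p1 = PKParams(0.2, 0.4, 0.05, 45.0)
        p2 = PKParams(0.1, 0.2, 0.02, 41.0)
        c1 = tofts_forward(reference_cp, p1).values
        c2 = tofts_forward(reference_cp, p2).values
        conc = np.stack([np.stack([c1, c2]), np.stack([c2, c1])])
        mask = np.ones((2, 2), dtype=bool)
        res = pixelwise_map(conc, reference_cp, NlsqConfig(), mask)
        assert res.values["kep"][0, 0] == pytest.approx(res.values["kep"][1, 1])
        assert res.values["kep"][0, 1] == pytest.approx(res.values["kep"][1, 0])
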