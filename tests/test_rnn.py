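"""Recurrent regressor tests: architecture, scaling, training, MC dropout."""
import numpy as np
import pytest

from dcepk.rnn import (
    ModelConfig,
    TrainConfig,
    build_model,
    load_model,
    mcd_predict,
    save_model,
    scale_targets,
    train_model,
    unscale_targets,
)
from dcepk.simulator import SimConfig, generate_dataset

RANGES = {"kep": (0.00025, 0.33), "ve": (0.04, 0.6), "vp": (0.005, 0.1),
          "tau_bat": (40.0, 50.0)}


def small_cfg(**kw):
    defaults = dict(cell_type="gru", n_layers=2, hidden_units=12,
                    dropout_rate=0.0, seq_len=65)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestBuildModel:
    def test_output_shape(self):
        model = build_model(small_cfg(), seed=0)
        x = np.random.default_rng(0).standard_normal((7, 65, 2))
        assert model.forward(x).shape == (7, 4)

    def test_lstm_has_more_parameters_than_gru(self):
        lstm = build_model(small_cfg(cell_type="lstm"))
        gru = build_model(small_cfg(cell_type="gru"))
        assert lstm.n_params() > gru.n_params()

    def test_no_dropout_forward_is_deterministic(self):
        model = build_model(small_cfg(), seed=1)
        x = np.random.default_rng(1).standard_normal((4, 65, 2))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(cell_type="transformer")

    def test_batch_order_invariance(self):
        """Per-sample computation: permuting the batch permutes outputs."""
        model = build_model(small_cfg(), seed=2)
        x = np.random.default_rng(2).standard_normal((6, 65, 2))
        perm = np.array([3, 1, 5, 0, 4, 2])
        np.testing.assert_allclose(model.forward(x)[perm],
                                   model.forward(x[perm]), atol=1e-12)


class TestBackpropagation:
    @pytest.mark.parametrize("cell", ["lstm", "gru"])
    def test_gradients_match_finite_differences(self, cell):
        """Analytic BPTT gradients agree with central finite differences."""
        cfg = ModelConfig(cell_type=cell, n_layers=3, hidden_units=5,
                          dropout_rate=0.0, seq_len=7, input_channels=2)
        model = build_model(cfg, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 7, 2))
        y = rng.standard_normal((4, 4))

        pred, cache = model.forward(x, training=True, keep_cache=True)
        grads = model.backward(2 * (pred - y) / pred.size, cache)

        def loss():
            return np.mean((model.forward(x, training=True) - y) ** 2)

        params = model.named_params()
        pick = np.random.default_rng(2)
        for name, p in params.items():
            for flat_idx in pick.choice(p.size, size=min(p.size, 4),
                                        replace=False):
                mi = np.unravel_index(flat_idx, p.shape)
                orig = p[mi]
                eps = 1e-6
                p[mi] = orig + eps
                lp = loss()
                p[mi] = orig - eps
                lm = loss()
                p[mi] = orig
                g_num = (lp - lm) / (2 * eps)
                g_ana = grads[name][mi]
                assert g_ana == pytest.approx(g_num, rel=1e-4, abs=1e-8), name


class TestTargetScaling:
    def test_range_low_maps_to_zero_and_mid_to_half(self):
        t = np.array([[0.00025, 0.04, 0.005, 40.0],
                      [(0.00025 + 0.33) / 2, 0.32, 0.0525, 45.0]])
        s = scale_targets(t, RANGES)
        np.testing.assert_allclose(s[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(s[1], 0.5, atol=1e-12)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        t = np.column_stack([rng.uniform(*RANGES[k], 50)
                             for k in ("kep", "ve", "vp", "tau_bat")])
        np.testing.assert_allclose(
            unscale_targets(scale_targets(t, RANGES), RANGES), t, atol=1e-12)

    def test_zero_width_range_with_varying_values_rejected(self):
        bad = dict(RANGES, kep=(0.1, 0.1))
        with pytest.raises(ValueError):
            scale_targets(np.array([[0.1, 0.3, 0.05, 45.0],
                                    [0.2, 0.3, 0.05, 45.0]]), bad)


class TestTraining:
    def test_loss_decreases_on_toy_set(self, toy_dataset):
        model = build_model(small_cfg(dropout_rate=0.0), seed=0)
        hist = train_model(model, toy_dataset,
                           TrainConfig(epochs=5, batch_size=64, seed=0))
        assert hist.train[-1] < hist.train[0]
        assert len(hist.train) == len(hist.val) == 5

    def test_fixed_seeds_reproduce_loss_history(self, toy_dataset):
        h = []
        for _ in range(2):
            model = build_model(small_cfg(), seed=3)
            h.append(train_model(model, toy_dataset,
                                 TrainConfig(epochs=2, batch_size=64, seed=3)))
        np.testing.assert_array_equal(h[0].train, h[1].train)
        np.testing.assert_array_equal(h[0].val, h[1].val)

    def test_empty_dataset_rejected(self, toy_dataset):
        import copy

        empty = copy.copy(toy_dataset)
        empty.inputs = empty.inputs[:0]
        empty.targets = empty.targets[:0]
        model = build_model(small_cfg())
        with pytest.raises(ValueError):
            train_model(model, empty, TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def trained_pair(toy_dataset):
    """Same init trained with dropout 0 and 0.25 on the toy set."""
    models = {}
    for dr in (0.0, 0.25):
        model = build_model(small_cfg(dropout_rate=dr), seed=5)
        train_model(model, toy_dataset,
                    TrainConfig(epochs=2, batch_size=64, seed=5))
        models[dr] = model
    return models


class TestMcdPredict:
    def test_dropout_zero_gives_exactly_zero_sd(self, trained_pair, toy_dataset):
        pred = mcd_predict(trained_pair[0.0], toy_dataset.inputs[:20],
                           n_mc=10, seed=0)
        assert np.all(pred.sd == 0.0)

    def test_fixed_seed_reproduces_prediction(self, trained_pair, toy_dataset):
        a = mcd_predict(trained_pair[0.25], toy_dataset.inputs[:10],
                        n_mc=8, seed=4)
        b = mcd_predict(trained_pair[0.25], toy_dataset.inputs[:10],
                        n_mc=8, seed=4)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_active_dropout_spreads_the_ensemble(self, trained_pair, toy_dataset):
        pred = mcd_predict(trained_pair[0.25], toy_dataset.inputs[:10],
                           n_mc=8, seed=4)
        assert np.all(pred.sd[:, :4].mean(axis=0) > 0)

    def test_ktrans_is_derived_per_pass(self, trained_pair, toy_dataset):
        # with dropout 0 the mean collapses to one pass: ktrans == kep*ve
        pred = mcd_predict(trained_pair[0.0], toy_dataset.inputs[:10],
                           n_mc=3, seed=0)
        np.testing.assert_allclose(pred.mean[:, 3],
                                   pred.mean[:, 0] * pred.mean[:, 1],
                                   rtol=1e-12)

    def test_single_pass_warns_and_reports_zero_sd(self, trained_pair,
                                                   toy_dataset):
        with pytest.warns(UserWarning):
            pred = mcd_predict(trained_pair[0.25], toy_dataset.inputs[:5],
                               n_mc=1, seed=0)
        assert np.all(pred.sd == 0)


class TestSerialization:
    def test_save_load_roundtrip(self, toy_dataset, tmp_path):
        model = build_model(small_cfg(dropout_rate=0.25), seed=7)
        train_model(model, toy_dataset,
                    TrainConfig(epochs=1, batch_size=64, seed=7))
        path = tmp_path / "model.dcepk"
        save_model(model, path)
        back = load_model(path)
        x = toy_dataset.inputs[:6]
        np.testing.assert_allclose(back.forward(x), model.forward(x),
                                   atol=1e-12)
        assert back.target_ranges == model.target_ranges
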