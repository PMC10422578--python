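"""Network architecture, weighted loss, training bookkeeping."""

import numpy as np
import pytest

from thermotau import (
    NetworkConfig,
    ThermalCNN,
    ThermalCNNResults,
    build_dataset,
    weighted_loss,
)
from thermotau.network import build_network, predict_spectrum, train
from thermotau.nn import Conv2D, Dense


@pytest.fixture(scope="module")
def smoke_config():
    return NetworkConfig(seed=0, epochs=5)


@pytest.fixture(scope="module")
def tiny_sets(smoke_config):
    return build_dataset(48, seed=10), build_dataset(16, seed=20)


@pytest.fixture(scope="module")
def smoke_results(tiny_sets, smoke_config):
    train_set, val_set = tiny_sets
    model = ThermalCNN(train_set, val_set, smoke_config)
    return model.fit(epochs=5)


class TestArchitecture:
    def test_layer_inventory(self):
        model = build_network()
        stack = model.stack
        weighted = [l for l in stack.layers if l.params]
        assert len(weighted) == 9  # dense + 6 conv(32) + conv(1) + dense
        assert isinstance(weighted[0], Dense) and weighted[0].W.shape == (1024, 1024)
        for conv in weighted[1:7]:
            assert isinstance(conv, Conv2D) and conv.c_out == 32 and conv.k == 3
            assert conv.activation == "sigmoid"
        assert weighted[7].c_out == 1  # single-channel map before flatten
        assert isinstance(weighted[8], Dense) and weighted[8].W.shape == (1024, 8)

    def test_flatten_emits_1024_and_output_8_in_unit_interval(self, rng):
        model = build_network()
        x = rng.uniform(0, 1, size=(3, 1024)).astype(np.float32)
        # capture the input to the last dense layer (the flattened map)
        flat_in = {}
        last = model.stack.layers[-1]
        orig_forward = last.forward

        def spy(arr):
            flat_in["shape"] = arr.shape
            return orig_forward(arr)

        last.forward = spy
        out = model.stack.forward(x)
        assert flat_in["shape"] == (3, 1024)
        assert out.shape == (3, 8)
        assert np.all((out > 0) & (out < 1))

    def test_identical_seeds_identical_predictions(self, rng):
        x = rng.uniform(0, 1, size=(2, 1024))
        a = build_network(NetworkConfig(seed=5)).predict_raw(x)
        b = build_network(NetworkConfig(seed=5)).predict_raw(x)
        np.testing.assert_array_equal(a, b)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(w_tau=0.3, w_amp=0.8)
        with pytest.raises(ValueError):
            NetworkConfig(epochs=0)
        with pytest.raises(ValueError):
            NetworkConfig(n_output=7)


class TestWeightedLoss:
    def test_perfect_fit_zero(self, rng):
        batch = rng.uniform(0, 1, size=(5, 8))
        assert weighted_loss(batch, batch) == 0.0

    def test_tau_block_closed_form(self):
        true = np.zeros((3, 8))
        pred = np.zeros((3, 8))
        pred[:, :4] = 0.1
        assert weighted_loss(pred, true) == pytest.approx(0.2 * 0.01, abs=1e-15)

    def test_amp_block_closed_form(self):
        true = np.zeros((3, 8))
        pred = np.zeros((3, 8))
        pred[:, 4:] = 0.1
        assert weighted_loss(pred, true) == pytest.approx(0.8 * 0.01, abs=1e-15)

    def test_against_independent_mse(self, rng):
        """Machine-precision agreement with an independently coded MSE."""
        pred = rng.uniform(0, 1, size=(11, 8))
        true = rng.uniform(0, 1, size=(11, 8))
        mse = lambda a, b: float(sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())) / a.size)
        expected = 0.2 * mse(pred[:, :4], true[:, :4]) + 0.8 * mse(pred[:, 4:], true[:, 4:])
        assert weighted_loss(pred, true) == pytest.approx(expected, abs=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_loss(np.zeros((2, 8)), np.zeros((3, 8)))


class TestTraining:
    def test_smoke_history_bookkeeping(self, smoke_results):
        h = smoke_results.history
        assert h.n_epochs == 5
        assert len(h.val_loss) == 5
        assert np.all(np.isfinite(h.train_loss))

    def test_training_progresses_without_divergence(self, smoke_results):
        """A tiny smoke run improves on its starting loss at some epoch and
        never blows up (the sustained decay contract is asserted on the
        full-protocol history in the acceptance suite, where SGD noise is
        small enough for it to be meaningful)."""
        h = smoke_results.history
        assert min(h.train_loss) <= h.train_loss[0]
        assert max(h.train_loss) < 0.5
        # tail-averaged weights may validate even better than any epoch
        assert smoke_results.best_val_loss <= min(h.val_loss)

    def test_reproducible_given_seeds(self, tiny_sets, smoke_config):
        train_set, val_set = tiny_sets
        a = ThermalCNN(train_set, val_set, smoke_config).fit(epochs=2)
        b = ThermalCNN(train_set, val_set, smoke_config).fit(epochs=2)
        assert a.history.val_loss == b.history.val_loss

    def test_functional_train_wrapper(self, tiny_sets, smoke_config):
        train_set, val_set = tiny_sets
        model = build_network(smoke_config)
        results, history = train(model, train_set, val_set, epochs=1)
        assert history.n_epochs == 1

    def test_history_csv(self, smoke_results, tmp_path):
        p = tmp_path / "history.csv"
        smoke_results.history.to_csv(p)
        arr = np.loadtxt(p, delimiter=",", skiprows=1)
        assert arr.shape == (5, 3)


class TestPrediction:
    def test_predictions_sorted_and_bounded(self, smoke_results, small_dataset):
        pred = smoke_results.predict(small_dataset.curves)
        assert pred.shape == (small_dataset.n, 8)
        assert np.all((pred > 0) & (pred < 1))
        assert np.all(np.diff(pred[:, :4], axis=1) >= 0)

    def test_predict_spectrum_contract(self, smoke_results, small_dataset):
        from thermotau import TemperatureCurve

        curve = TemperatureCurve(grid=small_dataset.grid, values=small_dataset.curves[0])
        s = smoke_results.predict_spectrum(curve)
        assert s.normalized
        assert s.n_components == 4
        assert np.all(s.tau > 0)
        s2 = predict_spectrum(smoke_results, curve)
        np.testing.assert_array_equal(s.tau, s2.tau)

    def test_wrong_length_rejected(self, smoke_results):
        with pytest.raises(ValueError):
            smoke_results.predict_spectrum(np.zeros(100))

    def test_save_load_round_trip(self, smoke_results, small_dataset, tmp_path):
        d = tmp_path / "model"
        smoke_results.save(d)
        back = ThermalCNNResults.load(d)
        np.testing.assert_array_equal(
            back.predict(small_dataset.curves), smoke_results.predict(small_dataset.curves)
        )
        assert back.history.val_loss == smoke_results.history.val_loss

    def test_summary_mentions_protocol(self, smoke_results):
        text = smoke_results.summary()
        assert "0.2" in text and "0.8" in text
        assert "SGD" in text
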