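import numpy as np
import pytest

from vhicast.convlstm import (
    CellParams,
    CellState,
    ConvLSTMModelSpec,
    TrainingProtocol,
    build_model,
    cell_step,
    epochs_without_improvement,
    train,
)
from vhicast.core_io import ValidationError


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def conv_same_loop(x, kernels):
    """Explicit-loop same-padded cross-correlation.

    x: (C_in, H, W); kernels: (F, C_in, k, k) -> (F, H, W).
    """
    F, C, k, _ = kernels.shape
    _, H, W = x.shape
    p = k // 2
    out = np.zeros((F, H, W))
    for f in range(F):
        for r in range(H):
            for c in range(W):
                acc = 0.0
                for ch in range(C):
                    for u in range(k):
                        for v in range(k):
                            rr, cc = r + u - p, c + v - p
                            if 0 <= rr < H and 0 <= cc < W:
                                acc += kernels[f, ch, u, v] * x[ch, rr, cc]
                out[f, r, c] = acc
    return out


def cell_step_loop_oracle(x, h, c, p: CellParams):
    """Gate equations evaluated with explicit convolution loops."""
    bi = p.b_i[:, None, None]
    bf = p.b_f[:, None, None]
    bc = p.b_c[:, None, None]
    bo = p.b_o[:, None, None]
    ai = conv_same_loop(x, p.W_xi) + conv_same_loop(h, p.W_hi) + bi
    af = conv_same_loop(x, p.W_xf) + conv_same_loop(h, p.W_hf) + bf
    if p.W_ci is not None:
        ai = ai + p.W_ci * c
        af = af + p.W_cf * c
    i = sigmoid(ai)
    f = sigmoid(af)
    c_new = f * c + i * np.tanh(conv_same_loop(x, p.W_xc) + conv_same_loop(h, p.W_hc) + bc)
    ao = conv_same_loop(x, p.W_xo) + conv_same_loop(h, p.W_ho) + bo
    if p.W_co is not None:
        ao = ao + p.W_co * c_new
    o = sigmoid(ao)
    return o * np.tanh(c_new), c_new


def random_params(rng, filters, in_channels, k, grid=None, peepholes=False):
    def w(*shape):
        return rng.uniform(-0.5, 0.5, shape).astype(np.float32)

    peep = {}
    if peepholes:
        peep = {g: w(filters, *grid) for g in ("W_ci", "W_cf", "W_co")}
    return CellParams(
        W_xi=w(filters, in_channels, k, k), W_xf=w(filters, in_channels, k, k),
        W_xc=w(filters, in_channels, k, k), W_xo=w(filters, in_channels, k, k),
        W_hi=w(filters, filters, k, k), W_hf=w(filters, filters, k, k),
        W_hc=w(filters, filters, k, k), W_ho=w(filters, filters, k, k),
        b_i=w(filters), b_f=w(filters), b_c=w(filters), b_o=w(filters),
        **peep,
    )


class TestCellStep:
    def test_zero_parameters_closed_form(self, rng):
        F, H, W = 2, 4, 4
        z = np.zeros
        params = CellParams(
            W_xi=z((F, 1, 3, 3)), W_xf=z((F, 1, 3, 3)), W_xc=z((F, 1, 3, 3)),
            W_xo=z((F, 1, 3, 3)), W_hi=z((F, F, 3, 3)), W_hf=z((F, F, 3, 3)),
            W_hc=z((F, F, 3, 3)), W_ho=z((F, F, 3, 3)),
            b_i=z(F), b_f=z(F), b_c=z(F), b_o=z(F),
        )
        c0 = rng.uniform(-1, 1, (F, H, W)).astype(np.float32)
        state = cell_step(rng.uniform(0, 1, (1, H, W)), CellState(z((F, H, W)), c0), params)
        np.testing.assert_allclose(state.c, 0.5 * c0, atol=1e-6)
        np.testing.assert_allclose(state.h, 0.5 * np.tanh(0.5 * c0), atol=1e-6)

    def test_zero_input_zero_state_zero_bias_gives_zero_hidden(self, rng):
        params = random_params(rng, 3, 1, 3)
        params.b_c[:] = 0.0
        state = cell_step(
            np.zeros((1, 5, 5)), CellState(np.zeros((3, 5, 5)), np.zeros((3, 5, 5))), params
        )
        np.testing.assert_allclose(state.h, 0.0, atol=1e-7)

    @pytest.mark.parametrize("peepholes", [False, True])
    def test_matches_explicit_loop_oracle_on_5x5(self, rng, peepholes):
        F, H, W = 3, 5, 5
        params = random_params(rng, F, 2, 3, grid=(H, W), peepholes=peepholes)
        x = rng.uniform(-1, 1, (2, H, W)).astype(np.float32)
        h0 = rng.uniform(-1, 1, (F, H, W)).astype(np.float32)
        c0 = rng.uniform(-1, 1, (F, H, W)).astype(np.float32)
        state = cell_step(x, CellState(h0, c0), params)
        h_ref, c_ref = cell_step_loop_oracle(
            x.astype(np.float64), h0.astype(np.float64), c0.astype(np.float64), params
        )
        np.testing.assert_allclose(state.h, h_ref, atol=1e-5)
        np.testing.assert_allclose(state.c, c_ref, atol=1e-5)

    def test_reduces_to_scalar_lstm_on_1x1_grid(self, rng):
        # same-padded 3x3 convolution on a 1x1 grid only sees the center tap
        F = 1
        params = random_params(rng, F, 1, 3)
        x = rng.uniform(-1, 1, (1, 1, 1)).astype(np.float32)
        h0 = rng.uniform(-1, 1, (F, 1, 1)).astype(np.float32)
        c0 = rng.uniform(-1, 1, (F, 1, 1)).astype(np.float32)
        state = cell_step(x, CellState(h0, c0), params)

        def center(w):
            return float(w[0, 0, 1, 1])

        xs, hs, cs = float(x[0, 0, 0]), float(h0[0, 0, 0]), float(c0[0, 0, 0])
        i = sigmoid(center(params.W_xi) * xs + center(params.W_hi) * hs + params.b_i[0])
        f = sigmoid(center(params.W_xf) * xs + center(params.W_hf) * hs + params.b_f[0])
        g = np.tanh(center(params.W_xc) * xs + center(params.W_hc) * hs + params.b_c[0])
        c_new = f * cs + i * g
        o = sigmoid(center(params.W_xo) * xs + center(params.W_ho) * hs + params.b_o[0])
        assert state.c[0, 0, 0] == pytest.approx(c_new, abs=1e-5)
        assert state.h[0, 0, 0] == pytest.approx(o * np.tanh(c_new), abs=1e-5)

    def test_nan_input_raises(self, rng):
        params = random_params(rng, 2, 1, 3)
        x = np.full((1, 3, 3), np.nan)
        with pytest.raises(FloatingPointError):
            cell_step(x, CellState(np.zeros((2, 3, 3)), np.zeros((2, 3, 3))), params)


def analytic_param_count(layers, filters, kernel):
    """4*(k^2*(C_in+F)*F + F) per layer plus the 1x1 conv head (F+1)."""
    total = 0
    for layer in range(layers):
        c_in = 1 if layer == 0 else filters
        total += 4 * (kernel**2 * (c_in + filters) * filters + filters)
    return total + filters + 1


class TestBuildModel:
    @pytest.mark.parametrize("layers", [1, 2, 3])
    def test_parameter_count_matches_symbolic_formula(self, layers):
        model = build_model(ConvLSTMModelSpec(layers=layers, filters=16, kernel_size=3))
        assert model.num_parameters() == analytic_param_count(layers, 16, 3)

    def test_output_shape_matches_input_grid(self, rng):
        for H, W in [(4, 4), (7, 5), (16, 16)]:
            model = build_model(ConvLSTMModelSpec(layers=2, filters=4))
            out = model.predict(rng.uniform(0, 1, (2, 6, H, W)).astype(np.float32))
            assert out.shape == (2, H, W)

    def test_predictions_clipped_to_unit_interval(self, rng):
        model = build_model(ConvLSTMModelSpec(layers=1, filters=4), seed=3)
        model.params["b_head"][:] = 50.0  # force raw outputs far above 1
        out = model.predict(rng.uniform(0, 1, (3, 4, 5, 5)).astype(np.float32))
        assert out.max() <= 1.0 and out.min() >= 0.0

    def test_invalid_layer_count_rejected(self):
        with pytest.raises(ValidationError):
            ConvLSTMModelSpec(layers=4)


class _ArrayDataset:
    def __init__(self, tx, ty, vx, vy):
        self.train_inputs, self.train_targets = tx, ty
        self.val_inputs, self.val_targets = vx, vy


class TestEarlyStopping:
    def test_strictly_improving_loss_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 100))
        ran = 0
        for e in range(100):
            ran += 1
            if epochs_without_improvement(losses[: e + 1]) >= 20:
                break
        assert ran == 100

    def test_constant_loss_stops_at_patience_plus_one(self):
        losses: list[float] = []
        ran = 0
        for _ in range(100):
            losses.append(0.5)
            ran += 1
            if epochs_without_improvement(losses) >= 20:
                break
        assert ran == 21

    def test_more_patience_never_fewer_epochs(self, rng):
        losses = list(rng.uniform(0.1, 1.0, 60))

        def epochs_run(patience):
            for e in range(len(losses)):
                if epochs_without_improvement(losses[: e + 1]) >= patience:
                    return e + 1
            return len(losses)

        runs = [epochs_run(p) for p in range(1, 40)]
        assert all(b >= a for a, b in zip(runs, runs[1:]))


class TestTraining:
    def _toy_dataset(self, rng, target_value=0.7, n=32, grid=4):
        tx = rng.uniform(0, 1, (n, 4, grid, grid)).astype(np.float32)
        ty = np.full((n, grid, grid), target_value, dtype=np.float32)
        vx = rng.uniform(0, 1, (8, 4, grid, grid)).astype(np.float32)
        vy = np.full((8, grid, grid), target_value, dtype=np.float32)
        return _ArrayDataset(tx, ty, vx, vy)

    def test_constant_target_beats_zero_predictor_100x(self, rng):
        ds = self._toy_dataset(rng)
        model = build_model(ConvLSTMModelSpec(layers=1, filters=4), seed=0)
        model, history = train(
            model, ds, TrainingProtocol(max_epochs=120, patience=119, batch_size=8, seed=0)
        )
        zero_predictor_mse = float((ds.val_targets**2).mean())
        assert min(history["val_loss"]) < zero_predictor_mse / 100.0

    def test_same_seed_identical_histories(self, rng):
        ds = self._toy_dataset(rng)
        runs = []
        for _ in range(2):
            model = build_model(ConvLSTMModelSpec(layers=1, filters=2), seed=5)
            _, history = train(
                model, ds, TrainingProtocol(max_epochs=5, patience=4, batch_size=8, seed=5)
            )
            runs.append(history)
        assert runs[0]["train_loss"] == runs[1]["train_loss"]
        assert runs[0]["val_loss"] == runs[1]["val_loss"]

    def test_best_weights_restored(self, rng):
        ds = self._toy_dataset(rng)
        model = build_model(ConvLSTMModelSpec(layers=1, filters=2), seed=1)
        model, history = train(
            model, ds, TrainingProtocol(max_epochs=15, patience=14, batch_size=8, seed=1)
        )
        final_val = model.evaluate_mse(ds.val_inputs, ds.val_targets)
        assert final_val == pytest.approx(min(history["val_loss"]), rel=1e-6)

    def test_empty_partition_rejected(self, rng):
        ds = self._toy_dataset(rng)
        empty = _ArrayDataset(ds.train_inputs[:0], ds.train_targets[:0],
                              ds.val_inputs, ds.val_targets)
        model = build_model(ConvLSTMModelSpec(layers=1, filters=2))
        with pytest.raises(ValidationError):
            train(model, empty, TrainingProtocol(max_epochs=2, patience=1))
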