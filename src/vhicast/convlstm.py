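"""ConvLSTM cells, networks and training, implemented in NumPy.

The cell follows the peephole formulation of convolutional LSTMs:

    i_t = sigmoid(W_xi * x_t + W_hi * h_{t-1} + W_ci o c_{t-1} + b_i)
    f_t = sigmoid(W_xf * x_t + W_hf * h_{t-1} + W_cf o c_{t-1} + b_f)
    c_t = f_t o c_{t-1} + i_t o tanh(W_xc * x_t + W_hc * h_{t-1} + b_c)
    o_t = sigmoid(W_xo * x_t + W_ho * h_{t-1} + W_co o c_t + b_o)
    h_t = o_t o tanh(c_t)

where ``*`` is a same-padded convolution and ``o`` the Hadamard product.
Peephole terms (W_c.) are elementwise weights of the same shape as the cell
state; they default to off, matching mainstream ConvLSTM layers, and can be
enabled for the exact formulation above.

Convolutions are evaluated as im2col matrix products, with hand-derived
backpropagation through time; the optimizer is Adam and early stopping
monitors validation MSE. Everything is float32 and bitwise reproducible
given a seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import ValidationError

__all__ = [
    "CellParams",
    "CellState",
    "ConvLSTMModelSpec",
    "TrainingProtocol",
    "ConvLSTMModel",
    "cell_step",
    "build_model",
    "train",
    "epochs_without_improvement",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# im2col convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches under same-padding."""
    B, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, H * W, C * k * k)


def _col2im(dcols: np.ndarray, B: int, C: int, H: int, W: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (B, C, H, W)."""
    p = k // 2
    dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dcols.dtype)
    cols6 = dcols.reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for u in range(k):
        for v in range(k):
            dxp[:, :, u : u + H, v : v + W] += cols6[:, :, :, :, u, v]
    return dxp[:, :, p : p + H, p : p + W]


def _hw_to_img(a: np.ndarray, H: int, W: int) -> np.ndarray:
    """(B, H*W, F) -> (B, F, H, W)."""
    B, _, F = a.shape
    return np.ascontiguousarray(a.transpose(0, 2, 1)).reshape(B, F, H, W)


def _img_to_hw(a: np.ndarray) -> np.ndarray:
    """(B, F, H, W) -> (B, H*W, F)."""
    B, F, H, W = a.shape
    return np.ascontiguousarray(a.reshape(B, F, H * W).transpose(0, 2, 1))


# ---------------------------------------------------------------------------
# functional single cell step
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CellState:
    """Hidden and cell-memory grids, each of shape (filters, H, W)."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float32)
        self.c = np.asarray(self.c, dtype=np.float32)
        if self.h.shape != self.c.shape:
            raise ValidationError("h and c must have the same shape")


@dataclasses.dataclass
class CellParams:
    """Explicit per-gate kernels and biases of one ConvLSTM cell.

    Input-to-gate kernels have shape (filters, in_channels, k, k) and
    hidden-to-gate kernels (filters, filters, k, k); peephole weights, when
    present, have the shape of the cell state (filters, H, W).
    """

    W_xi: np.ndarray
    W_xf: np.ndarray
    W_xc: np.ndarray
    W_xo: np.ndarray
    W_hi: np.ndarray
    W_hf: np.ndarray
    W_hc: np.ndarray
    W_ho: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    W_ci: np.ndarray | None = None
    W_cf: np.ndarray | None = None
    W_co: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = self.W_xi.shape[-1]
        if k % 2 != 1:
            raise ValidationError("kernel spatial size must be odd")
        for name in ("W_xi", "W_xf", "W_xc", "W_xo", "W_hi", "W_hf", "W_hc", "W_ho",
                     "b_i", "b_f", "b_c", "b_o"):
            arr = np.asarray(getattr(self, name), dtype=np.float32)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite entries in {name}")
            setattr(self, name, arr)

    def fused(self) -> tuple[np.ndarray, np.ndarray]:
        """Pack per-gate kernels into one (C_z*k*k, 4F) matrix, gate order i,f,c,o.

        Column layout matches :func:`_im2col` patches of the concatenated
        (input, hidden) channels.
        """
        F = self.W_xi.shape[0]
        blocks = []
        for wx, wh in ((self.W_xi, self.W_hi), (self.W_xf, self.W_hf),
                       (self.W_xc, self.W_hc), (self.W_xo, self.W_ho)):
            # (F, C_z*k*k): per filter, x-channel taps then h-channel taps
            blocks.append(np.concatenate([wx.reshape(F, -1), wh.reshape(F, -1)], axis=1))
        Wz = np.concatenate(blocks, axis=0).T.astype(np.float32)  # (C_z k^2, 4F)
        b = np.concatenate([self.b_i, self.b_f, self.b_c, self.b_o]).astype(np.float32)
        return Wz, b


def _gate_forward(
    z_cols: np.ndarray,
    c_prev: np.ndarray,
    Wz: np.ndarray,
    b: np.ndarray,
    peep: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
):
    """Shared gate math on flattened (B, H*W, .) tensors. Returns state + cache."""
    F = Wz.shape[1] // 4
    a = z_cols @ Wz + b
    ai, af, ag, ao = (a[..., i * F : (i + 1) * F] for i in range(4))
    if peep is not None:
        ai = ai + peep[0] * c_prev
        af = af + peep[1] * c_prev
    i = _sigmoid(ai)
    f = _sigmoid(af)
    g = np.tanh(ag)
    c = f * c_prev + i * g
    if peep is not None:
        ao = ao + peep[2] * c
    o = _sigmoid(ao)
    tanh_c = np.tanh(c)
    h = o * tanh_c
    return h, c, (i, f, g, o, tanh_c, c_prev, c)


def cell_step(x: np.ndarray, state: CellState, params: CellParams) -> CellState:
    """One ConvLSTM step on an unbatched input grid (in_channels, H, W)."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValidationError("x must be (in_channels, H, W)")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(state.h)):
        raise FloatingPointError("non-finite values in cell inputs")
    F, H, W = state.h.shape
    k = params.W_xi.shape[-1]
    Wz, b = params.fused()
    z = np.concatenate([x[None], state.h[None]], axis=1)
    peep = None
    if params.W_ci is not None:
        peep = tuple(
            np.asarray(w, dtype=np.float32).reshape(F, H * W).T[None]
            for w in (params.W_ci, params.W_cf, params.W_co)
        )
    h, c, _ = _gate_forward(_im2col(z, k), _img_to_hw(state.c[None]), Wz, b, peep)
    return CellState(h=_hw_to_img(h, H, W)[0], c=_hw_to_img(c, H, W)[0])


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConvLSTMModelSpec:
    """Architecture of a VHI forecasting network.

    1-3 stacked ConvLSTM cells (intermediate layers emit their full hidden
    sequences) followed by a 1x1 convolution head mapping the final hidden
    state to one output frame; ``horizon`` records the step the model is
    trained to predict.
    """

    layers: int = 1
    filters: int = 16
    kernel_size: int = 3
    peepholes: bool = False
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.layers not in (1, 2, 3):
            raise ValidationError("layers must be 1, 2 or 3")
        if self.filters < 1:
            raise ValidationError("filters must be positive")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValidationError("kernel_size must be odd and positive")
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1")


@dataclasses.dataclass
class TrainingProtocol:
    """Optimization settings: Adam on pixelwise MSE with early stopping."""

    max_epochs: int = 100
    patience: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.patience < self.max_epochs:
            raise ValidationError("require 0 < patience < max_epochs")


class ConvLSTMModel:
    """Stacked ConvLSTM network with fused gate weights and a 1x1 conv head."""

    def __init__(self, spec: ConvLSTMModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        F, k = spec.filters, spec.kernel_size
        for layer in range(spec.layers):
            c_in = 1 if layer == 0 else F
            cz = c_in + F
            s = np.sqrt(1.0 / (cz * k * k))
            self.params[f"W{layer}"] = rng.uniform(-s, s, size=(cz * k * k, 4 * F)).astype(
                np.float32
            )
            b = np.zeros(4 * F, dtype=np.float32)
            b[F : 2 * F] = 1.0  # forget-gate bias starts open
            self.params[f"b{layer}"] = b
        s = np.sqrt(1.0 / F)
        self.params["W_head"] = rng.uniform(-s, s, size=(F, 1)).astype(np.float32)
        self.params["b_head"] = np.zeros(1, dtype=np.float32)
        self._peep_grid: tuple[int, int] | None = None

    # -- peephole weights are state-shaped, so allocated per grid size ------
    def _ensure_peepholes(self, H: int, W: int) -> None:
        if not self.spec.peepholes:
            return
        if self._peep_grid == (H, W):
            return
        if self._peep_grid is not None:
            raise ValidationError("peephole model already bound to a different grid size")
        F = self.spec.filters
        for layer in range(self.spec.layers):
            for gate in ("ci", "cf", "co"):
                self.params[f"W_{gate}{layer}"] = np.zeros((1, H * W, F), dtype=np.float32)
        self._peep_grid = (H, W)

    def num_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _peep(self, layer: int):
        if not self.spec.peepholes:
            return None
        return tuple(self.params[f"W_{g}{layer}"] for g in ("ci", "cf", "co"))

    # -- forward ------------------------------------------------------------
    def _forward(self, windows: np.ndarray, keep_cache: bool):
        B, L, H, W = windows.shape
        self._ensure_peepholes(H, W)
        F, k = self.spec.filters, self.spec.kernel_size
        HW = H * W
        h = [np.zeros((B, HW, F), dtype=np.float32) for _ in range(self.spec.layers)]
        c = [np.zeros((B, HW, F), dtype=np.float32) for _ in range(self.spec.layers)]
        caches = []
        for t in range(L):
            x = windows[:, t][:, None]  # (B, 1, H, W)
            step_cache = []
            for layer in range(self.spec.layers):
                z = np.concatenate([x, _hw_to_img(h[layer], H, W)], axis=1)
                cols = _im2col(z, k)
                h[layer], c[layer], cache = _gate_forward(
                    cols, c[layer], self.params[f"W{layer}"], self.params[f"b{layer}"],
                    self._peep(layer),
                )
                if keep_cache:
                    step_cache.append((cols, cache))
                x = _hw_to_img(h[layer], H, W)
            if keep_cache:
                caches.append(step_cache)
        out = h[-1] @ self.params["W_head"] + self.params["b_head"]  # (B, HW, 1)
        pred = out[..., 0].reshape(B, H, W)
        if keep_cache:
            return pred, (caches, h[-1], (B, L, H, W))
        return pred

    def predict(self, windows: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Forecast one frame per window; output clipped to [0, 1]."""
        windows = np.asarray(windows, dtype=np.float32)
        single = windows.ndim == 3
        if single:
            windows = windows[None]
        outs = [
            self._forward(windows[i : i + batch_size], keep_cache=False)
            for i in range(0, len(windows), batch_size)
        ]
        pred = np.clip(np.concatenate(outs), 0.0, 1.0).astype(np.float32)
        return pred[0] if single else pred

    # -- loss and gradients -------------------------------------------------
    def loss_and_grads(self, windows: np.ndarray, targets: np.ndarray):
        pred, (caches, h_last, (B, L, H, W)) = self._forward(windows, keep_cache=True)
        F, k = self.spec.filters, self.spec.kernel_size
        HW = H * W
        resid = (pred - targets).astype(np.float32)
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        grads = {name: np.zeros_like(p) for name, p in self.params.items()}

        dout = (2.0 / resid.size) * resid  # d loss / d pred
        dout = dout.reshape(B, HW, 1)
        grads["W_head"] += np.einsum("bpf,bpo->fo", h_last, dout).astype(np.float32)
        grads["b_head"] += dout.sum(axis=(0, 1))
        dh_top = dout @ self.params["W_head"].T  # (B, HW, F)

        dh = [np.zeros((B, HW, F), dtype=np.float32) for _ in range(self.spec.layers)]
        dc = [np.zeros((B, HW, F), dtype=np.float32) for _ in range(self.spec.layers)]
        dh[-1] += dh_top
        for t in range(L - 1, -1, -1):
            dx_from_above = None
            for layer in range(self.spec.layers - 1, -1, -1):
                if dx_from_above is not None:
                    dh[layer] += dx_from_above
                cols, (i, f, g, o, tanh_c, c_prev, c_now) = caches[t][layer]
                peep = self._peep(layer)
                do = dh[layer] * tanh_c
                dcc = dc[layer] + dh[layer] * o * (1.0 - tanh_c**2)
                dao = do * o * (1.0 - o)
                if peep is not None:
                    dcc = dcc + dao * peep[2]
                    grads[f"W_co{layer}"] += (dao * c_now).sum(axis=0, keepdims=True)
                di = dcc * g
                df = dcc * c_prev
                dg = dcc * i
                dc_prev = dcc * f
                dai = di * i * (1.0 - i)
                daf = df * f * (1.0 - f)
                dag = dg * (1.0 - g**2)
                if peep is not None:
                    dc_prev = dc_prev + dai * peep[0] + daf * peep[1]
                    grads[f"W_ci{layer}"] += (dai * c_prev).sum(axis=0, keepdims=True)
                    grads[f"W_cf{layer}"] += (daf * c_prev).sum(axis=0, keepdims=True)
                da = np.concatenate([dai, daf, dag, dao], axis=-1)  # (B, HW, 4F)
                czk2 = self.params[f"W{layer}"].shape[0]
                grads[f"W{layer}"] += (
                    cols.reshape(B * HW, czk2).T @ da.reshape(B * HW, 4 * F)
                ).astype(np.float32)
                grads[f"b{layer}"] += da.sum(axis=(0, 1))
                dcols = da @ self.params[f"W{layer}"].T
                c_in = czk2 // (k * k) - F
                dz = _col2im(dcols, B, c_in + F, H, W, k)
                dh[layer] = _img_to_hw(dz[:, c_in:])
                dc[layer] = dc_prev
                dx_from_above = dz[:, :c_in]  # (B, c_in, H, W)
                if layer > 0:
                    dx_from_above = _img_to_hw(dx_from_above)
                else:
                    dx_from_above = None  # gradient w.r.t. the data is discarded
        return loss, grads

    def evaluate_mse(self, windows: np.ndarray, targets: np.ndarray, batch_size: int = 64) -> float:
        total, n = 0.0, 0
        for i in range(0, len(windows), batch_size):
            pred = self._forward(windows[i : i + batch_size].astype(np.float32), keep_cache=False)
            r = pred.astype(np.float64) - targets[i : i + batch_size]
            total += float((r**2).sum())
            n += r.size
        return total / n

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in weights.items()}


def build_model(spec: ConvLSTMModelSpec, seed: int = 0) -> ConvLSTMModel:
    """Instantiate a network from an architecture spec with seeded init."""
    return ConvLSTMModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def epochs_without_improvement(val_losses: list[float]) -> int:
    """Epochs elapsed since the best (minimum) validation loss so far.

    "Improvement" means strictly lower than the best so far, by any amount.
    """
    best = int(np.argmin(val_losses))
    return len(val_losses) - 1 - best


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, p in params.items():
            if key not in self.m:  # lazily created peephole weights
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            g = grads[key]
            self.m[key] = self.beta1 * self.m[key] + (1.0 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1.0 - self.beta2) * g * g
            p -= (self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)).astype(
                np.float32
            )


def train(model: ConvLSTMModel, dataset, protocol: TrainingProtocol):
    """Train on MSE with early stopping; returns (model, history).

    ``dataset`` must expose ``train_inputs``/``train_targets`` and
    ``val_inputs``/``val_targets`` arrays (see forecasting.WindowedDataset).
    Validation loss is evaluated after every epoch; training stops when it
    has not improved for ``patience`` consecutive epochs, and the
    best-validation weights are restored.
    """
    tx = np.asarray(dataset.train_inputs, dtype=np.float32)
    ty = np.asarray(dataset.train_targets, dtype=np.float32)
    vx = np.asarray(dataset.val_inputs, dtype=np.float32)
    vy = np.asarray(dataset.val_targets, dtype=np.float32)
    if len(tx) == 0 or len(vx) == 0:
        raise ValidationError("train and validation partitions must be nonempty")

    rng = np.random.default_rng(protocol.seed)
    opt = _Adam(model.params, protocol.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_weights = model.get_weights()
    best_val = np.inf
    for _epoch in range(protocol.max_epochs):
        order = rng.permutation(len(tx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(tx), protocol.batch_size):
            idx = order[start : start + protocol.batch_size]
            loss, grads = model.loss_and_grads(tx[idx], ty[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("training loss diverged (NaN/inf)")
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val_loss = model.evaluate_mse(vx, vy)
        history["train_loss"].append(epoch_loss / n_batches)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
        if epochs_without_improvement(history["val_loss"]) >= protocol.patience:
            break
    model.set_weights(best_weights)
    return model, history
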