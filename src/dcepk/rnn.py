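"""Stacked LSTM/GRU regressors with Monte Carlo dropout, in pure NumPy.

Architecture: a stack of recurrent layers (default 4) over the two-channel
concentration sequence.  All layers but the last return full sequences and
are followed by batch normalization; the last layer returns its final hidden
state.  A dropout stage follows each recurrent block (after the batch norm),
with one mask shared across time steps within a forward pass, and a final
dense layer maps the last hidden state to the four kinetic parameters
(kep, ve, vp, tau_BAT), each affinely scaled to [0, 1] by its sampling range
for the MSE loss.

Monte Carlo dropout: at inference the dropout masks are kept active and
resampled over ``n_mc`` repeated passes (batch-norm layers use their stored
running statistics).  The per-parameter mean over passes is the prediction
and the standard deviation its uncertainty; Ktrans = kep * ve is derived per
pass before averaging.

Training uses Adam with an inverse-time learning-rate schedule
lr = lr0 / (1 + decay * epoch) and mean-squared error on the scaled targets.
Forward and backward passes are hand-derived; the per-time-step recurrences
run as batched matrix products so training a small model is practical on a
single CPU.
"""
from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from io import BytesIO

import numpy as np

from .simulator import OUTPUT_PARAMS, SimDataset, train_val_split

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "McdPrediction",
    "RnnRegressor",
    "build_model",
    "train_model",
    "mcd_predict",
    "scale_targets",
    "unscale_targets",
    "save_model",
    "load_model",
    "EVAL_PARAMS",
]

#: Parameter order of evaluated predictions (Ktrans derived per MC pass).
EVAL_PARAMS = ("kep", "ve", "vp", "ktrans", "tau_bat")


@dataclass(frozen=True)
class ModelConfig:
    cell_type: str = "gru"
    n_layers: int = 4
    hidden_units: int = 256
    dropout_rate: float = 0.25
    n_outputs: int = 4
    input_channels: int = 2
    seq_len: int = 65

    def __post_init__(self) -> None:
        if self.cell_type not in ("lstm", "gru"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    epochs: int = 50
    initial_lr: float = 1e-3
    lr_decay: float = 0.1
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.initial_lr <= 0:
            raise ValueError("batch_size, epochs and initial_lr must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class McdPrediction:
    """Monte-Carlo-dropout ensemble summary.

    ``mean`` and ``sd`` have shape (n_samples, 5) in the order
    (kep, ve, vp, ktrans, tau_bat); with a single pass (or dropout 0) the SD
    is exactly zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_mc: int
    param_names: tuple[str, ...] = EVAL_PARAMS


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _orthogonal(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[: shape[0], : shape[1]]


class _LstmLayer:
    """One LSTM layer; gate order (i, f, g, o), forget bias initialised to 1."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        h = hidden
        limit = np.sqrt(6.0 / (in_dim + 4 * h))
        self.Wx = rng.uniform(-limit, limit, (in_dim, 4 * h))
        self.Wh = np.concatenate(
            [_orthogonal((h, h), rng) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0
        self.hidden = h

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray, keep_cache: bool):
        B, T, _ = x.shape
        h = self.hidden
        xw = x.reshape(B * T, -1) @ self.Wx
        xw = xw.reshape(B, T, 4 * h) + self.b
        hs = np.zeros((B, T, h))
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        gates = np.empty((B, T, 4 * h)) if keep_cache else None
        cs = np.empty((B, T, h)) if keep_cache else None
        tanh_cs = np.empty((B, T, h)) if keep_cache else None
        for t in range(T):
            pre = xw[:, t, :] + h_t @ self.Wh
            i = _sigmoid(pre[:, :h])
            f = _sigmoid(pre[:, h : 2 * h])
            g = np.tanh(pre[:, 2 * h : 3 * h])
            o = _sigmoid(pre[:, 3 * h :])
            c_t = f * c_t + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            hs[:, t, :] = h_t
            if keep_cache:
                gates[:, t, :h] = i
                gates[:, t, h : 2 * h] = f
                gates[:, t, 2 * h : 3 * h] = g
                gates[:, t, 3 * h :] = o
                cs[:, t, :] = c_t
                tanh_cs[:, t, :] = tc
        cache = (x, hs, gates, cs, tanh_cs) if keep_cache else None
        return hs, cache

    def backward(self, d_hs: np.ndarray, cache):
        x, hs, gates, cs, tanh_cs = cache
        B, T, _ = x.shape
        h = self.hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        dpre_all = np.empty((B, T, 4 * h))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h : 2 * h]
            g = gates[:, t, 2 * h : 3 * h]
            o = gates[:, t, 3 * h :]
            tc = tanh_cs[:, t, :]
            c_prev = cs[:, t - 1, :] if t > 0 else np.zeros((B, h))
            dh = d_hs[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dpre = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            dpre_all[:, t, :] = dpre
            if t > 0:
                dWh += hs[:, t - 1, :].T @ dpre
            dh_next = dpre @ self.Wh.T
        flat = dpre_all.reshape(B * T, 4 * h)
        dWx += x.reshape(B * T, -1).T @ flat
        db += flat.sum(axis=0)
        dx = (flat @ self.Wx.T).reshape(x.shape)
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class _GruLayer:
    """One GRU layer; gates (r, z) and candidate n = tanh(x Wxn + (r*h) Whn + bn)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        h = hidden
        limit = np.sqrt(6.0 / (in_dim + 3 * h))
        self.Wx = rng.uniform(-limit, limit, (in_dim, 3 * h))
        self.Whrz = np.concatenate(
            [_orthogonal((h, h), rng) for _ in range(2)], axis=1
        )
        self.Whn = _orthogonal((h, h), rng)
        self.b = np.zeros(3 * h)
        self.hidden = h

    def params(self):
        return {"Wx": self.Wx, "Whrz": self.Whrz, "Whn": self.Whn, "b": self.b}

    def forward(self, x: np.ndarray, keep_cache: bool):
        B, T, _ = x.shape
        h = self.hidden
        xw = x.reshape(B * T, -1) @ self.Wx
        xw = xw.reshape(B, T, 3 * h) + self.b
        hs = np.zeros((B, T, h))
        h_t = np.zeros((B, h))
        gates = np.empty((B, T, 3 * h)) if keep_cache else None
        rhs = np.empty((B, T, h)) if keep_cache else None
        for t in range(T):
            rz = _sigmoid(xw[:, t, : 2 * h] + h_t @ self.Whrz)
            r = rz[:, :h]
            z = rz[:, h:]
            rh = r * h_t
            n = np.tanh(xw[:, t, 2 * h :] + rh @ self.Whn)
            if keep_cache:
                gates[:, t, :h] = r
                gates[:, t, h : 2 * h] = z
                gates[:, t, 2 * h :] = n
                rhs[:, t, :] = rh
            h_t = (1.0 - z) * n + z * h_t
            hs[:, t, :] = h_t
        cache = (x, hs, gates, rhs) if keep_cache else None
        return hs, cache

    def backward(self, d_hs: np.ndarray, cache):
        x, hs, gates, rhs = cache
        B, T, _ = x.shape
        h = self.hidden
        dWx = np.zeros_like(self.Wx)
        dWhrz = np.zeros_like(self.Whrz)
        dWhn = np.zeros_like(self.Whn)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, h))
        dpre_all = np.empty((B, T, 3 * h))
        for t in range(T - 1, -1, -1):
            r = gates[:, t, :h]
            z = gates[:, t, h : 2 * h]
            n = gates[:, t, 2 * h :]
            h_prev = hs[:, t - 1, :] if t > 0 else np.zeros((B, h))
            dh = d_hs[:, t, :] + dh_next
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dpre_n = dn * (1.0 - n * n)
            d_rh = dpre_n @ self.Whn.T
            dr = d_rh * h_prev
            dh_prev += d_rh * r
            dpre_r = dr * r * (1 - r)
            dpre_z = dz * z * (1 - z)
            dpre_rz = np.concatenate([dpre_r, dpre_z], axis=1)
            if t > 0:
                dWhrz += h_prev.T @ dpre_rz
                dWhn += rhs[:, t, :].T @ dpre_n
            else:
                dWhn += rhs[:, t, :].T @ dpre_n  # rh at t=0 is zero anyway
            dh_next = dh_prev + dpre_rz @ self.Whrz.T
            dpre_all[:, t, : 2 * h] = dpre_rz
            dpre_all[:, t, 2 * h :] = dpre_n
        flat = dpre_all.reshape(B * T, 3 * h)
        dWx += x.reshape(B * T, -1).T @ flat
        db += flat.sum(axis=0)
        dx = (flat @ self.Wx.T).reshape(x.shape)
        return dx, {"Wx": dWx, "Whrz": dWhrz, "Whn": dWhn, "b": db}


class _BatchNorm:
    """Feature-wise batch normalization over all leading axes."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, training: bool, keep_cache: bool):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        out = self.gamma * x_hat + self.beta
        cache = (x_hat, inv_std, x.shape, training) if keep_cache else None
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        x_hat, inv_std, shape, training = cache
        axes = tuple(range(dout.ndim - 1))
        m = np.prod([shape[a] for a in axes])
        dgamma = (dout * x_hat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        if training:
            dx_hat = dout * self.gamma
            dx = inv_std / m * (
                m * dx_hat - dx_hat.sum(axis=axes)
                - x_hat * (dx_hat * x_hat).sum(axis=axes)
            )
        else:
            dx = dout * self.gamma * inv_std
        return dx, {"gamma": dgamma, "beta": dbeta}


class RnnRegressor:
    """Stacked recurrent regressor; see the module docstring for the layout."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layer_cls = _LstmLayer if cfg.cell_type == "lstm" else _GruLayer
        self.layers = []
        in_dim = cfg.input_channels
        for _ in range(cfg.n_layers):
            self.layers.append(layer_cls(in_dim, cfg.hidden_units, rng))
            in_dim = cfg.hidden_units
        self.bns = [_BatchNorm(cfg.hidden_units) for _ in range(cfg.n_layers - 1)]
        limit = np.sqrt(6.0 / (cfg.hidden_units + cfg.n_outputs))
        self.W_out = rng.uniform(-limit, limit, (cfg.hidden_units, cfg.n_outputs))
        self.b_out = np.zeros(cfg.n_outputs)
        self.target_ranges: dict[str, tuple[float, float]] | None = None

    # -- parameter registry -------------------------------------------------
    def named_params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"layer{i}.{k}"] = v
        for i, bn in enumerate(self.bns):
            for k, v in bn.params().items():
                out[f"bn{i}.{k}"] = v
        out["dense.W"] = self.W_out
        out["dense.b"] = self.b_out
        return out

    def n_params(self) -> int:
        return sum(v.size for v in self.named_params().values())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None,
                mc_dropout: bool = False, keep_cache: bool = False):
        """Run the network on inputs of shape (batch, seq_len, channels).

        Dropout is active when ``training`` or ``mc_dropout`` is true and the
        configured rate is positive; batch statistics are only used (and
        running statistics updated) when ``training`` is true.
        """
        cfg = self.cfg
        p = cfg.dropout_rate
        use_dropout = p > 0 and (training or mc_dropout)
        if use_dropout and dropout_rng is None:
            raise ValueError("dropout is active but no dropout_rng supplied")
        caches = []
        out = x
        for i, layer in enumerate(self.layers):
            hs, rnn_cache = layer.forward(out, keep_cache)
            last = i == len(self.layers) - 1
            if last:
                out = hs[:, -1, :]
                bn_cache = None
            else:
                out, bn_cache = self.bns[i].forward(hs, training, keep_cache)
            mask = None
            if use_dropout:
                if out.ndim == 3:
                    # one mask per sample/feature, shared across time steps
                    mask = (dropout_rng.random((out.shape[0], 1, out.shape[2])) >= p)
                else:
                    mask = dropout_rng.random(out.shape) >= p
                out = out * mask / (1.0 - p)
            caches.append((rnn_cache, bn_cache, mask, last))
        y = out @ self.W_out + self.b_out
        if keep_cache:
            return y, (caches, out)
        return y

    def backward(self, dy: np.ndarray, cache):
        caches, last_hidden = cache
        p = self.cfg.dropout_rate
        grads = {"dense.W": last_hidden.T @ dy, "dense.b": dy.sum(axis=0)}
        dout = dy @ self.W_out.T
        for i in range(len(self.layers) - 1, -1, -1):
            rnn_cache, bn_cache, mask, last = caches[i]
            if mask is not None:
                dout = dout * mask / (1.0 - p)
            if last:
                d_hs = np.zeros((dout.shape[0], rnn_cache[1].shape[1],
                                 self.cfg.hidden_units))
                d_hs[:, -1, :] = dout
            else:
                d_hs, bn_grads = self.bns[i].backward(dout, bn_cache)
                for k, v in bn_grads.items():
                    grads[f"bn{i}.{k}"] = v
            dout, layer_grads = self.layers[i].backward(d_hs, rnn_cache)
            for k, v in layer_grads.items():
                grads[f"layer{i}.{k}"] = v
        return grads


def build_model(cfg: ModelConfig, seed: int = 0) -> RnnRegressor:
    """Construct an untrained network with seeded weight initialisation."""
    return RnnRegressor(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Target scaling
# ---------------------------------------------------------------------------

def scale_targets(targets: np.ndarray,
                  ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    """Affine map of each output parameter to [0, 1] by its sampling range.

    A zero-width range (e.g. tau_BAT pinned to 0 in a no-delay design) maps
    identically to 0 rather than dividing by zero.
    """
    targets = np.asarray(targets, dtype=float)
    out = np.empty_like(targets)
    for j, name in enumerate(OUTPUT_PARAMS):
        lo, hi = ranges[name]
        if hi == lo:
            if np.any(targets[:, j] != lo):
                raise ValueError(f"zero-width range for {name} with varying values")
            out[:, j] = 0.0
        else:
            out[:, j] = (targets[:, j] - lo) / (hi - lo)
    return out


def unscale_targets(scaled: np.ndarray,
                    ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    """Exact inverse of :func:`scale_targets`."""
    scaled = np.asarray(scaled, dtype=float)
    out = np.empty_like(scaled)
    for j, name in enumerate(OUTPUT_PARAMS):
        lo, hi = ranges[name]
        out[:, j] = scaled[:, j] * (hi - lo) + lo
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


@dataclass
class LossHistory:
    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)


def train_model(model: RnnRegressor, dataset: SimDataset,
                tcfg: TrainConfig) -> LossHistory:
    """Train in place by MSE on range-scaled targets; returns the loss history.

    Adam with lr = lr0/(1 + decay*epoch); 0.9/0.1 train/validation split;
    dropout active during training; validation losses are computed with
    dropout off and batch norm on running statistics.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    ranges = dataset.config.target_ranges()
    model.target_ranges = ranges
    X = dataset.inputs
    Y = scale_targets(dataset.targets, ranges)

    ss = np.random.SeedSequence(tcfg.seed)
    split_rng, shuffle_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    train_idx, val_idx = train_val_split(len(dataset), tcfg.val_fraction, split_rng)
    Xtr, Ytr = X[train_idx], Y[train_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    params = model.named_params()
    opt = _Adam(params)
    history = LossHistory()
    bs = tcfg.batch_size
    for epoch in range(tcfg.epochs):
        lr = tcfg.initial_lr / (1.0 + tcfg.lr_decay * epoch)
        order = shuffle_rng.permutation(len(Xtr))
        epoch_losses = []
        for start in range(0, len(Xtr), bs):
            sel = order[start : start + bs]
            xb, yb = Xtr[sel], Ytr[sel]
            pred, cache = model.forward(xb, training=True, dropout_rng=drop_rng,
                                        keep_cache=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, step {start // bs}; "
                    "reduce the learning rate or check the data"
                )
            epoch_losses.append(loss)
            dy = 2.0 * err / err.size
            grads = model.backward(dy, cache)
            opt.step(params, grads, lr)
        val_pred = _forward_in_chunks(model, Xval)
        val_loss = float(np.mean((val_pred - Yval) ** 2))
        history.train.append(float(np.mean(epoch_losses)))
        history.val.append(val_loss)
    return history


def _forward_in_chunks(model: RnnRegressor, X: np.ndarray, chunk: int = 512,
                       mc_dropout: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    outs = []
    for start in range(0, len(X), chunk):
        outs.append(model.forward(X[start : start + chunk], training=False,
                                  mc_dropout=mc_dropout, dropout_rng=rng))
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# Monte Carlo dropout inference
# ---------------------------------------------------------------------------

def mcd_predict(model: RnnRegressor, inputs: np.ndarray, n_mc: int = 100,
                seed: int = 0,
                ranges: dict[str, tuple[float, float]] | None = None) -> McdPrediction:
    """Repeated stochastic forward passes with dropout active.

    Returns per-sample, per-parameter mean and SD in original units, with
    Ktrans = kep * ve derived within each pass.  With dropout rate 0 every
    pass is identical and the SD is exactly zero; n_mc = 1 likewise reports
    zero SD (with a warning, since no spread can be estimated).
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if ranges is None:
        ranges = model.target_ranges
    if ranges is None:
        raise ValueError("model has no stored target ranges; pass `ranges`")
    if n_mc == 1:
        import warnings

        warnings.warn("n_mc = 1: uncertainty reported as 0")
    rng = np.random.default_rng(seed)
    use_mc = model.cfg.dropout_rate > 0
    passes = np.empty((n_mc, len(inputs), 5))
    for k in range(n_mc):
        scaled = _forward_in_chunks(model, inputs, mc_dropout=use_mc, rng=rng)
        raw = unscale_targets(scaled, ranges)
        passes[k, :, 0:3] = raw[:, 0:3]
        passes[k, :, 3] = raw[:, 0] * raw[:, 1]  # Ktrans per pass
        passes[k, :, 4] = raw[:, 3]
        if not use_mc:
            # deterministic network: every pass is identical by construction
            mean = passes[k]
            return McdPrediction(mean=mean, sd=np.zeros_like(mean), n_mc=n_mc)
    mean = passes.mean(axis=0)
    sd = passes.std(axis=0) if n_mc > 1 else np.zeros_like(mean)
    return McdPrediction(mean=mean, sd=sd, n_mc=n_mc)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: RnnRegressor, path: str) -> None:
    """Single archive: weights + running stats + a JSON manifest."""
    arrays = dict(model.named_params())
    for i, bn in enumerate(model.bns):
        arrays[f"bn{i}.running_mean"] = bn.running_mean
        arrays[f"bn{i}.running_var"] = bn.running_var
    manifest = {"model_config": asdict(model.cfg),
                "target_ranges": model.target_ranges}
    buf = BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))


def load_model(path: str) -> RnnRegressor:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        weights = np.load(BytesIO(zf.read("weights.npz")))
        cfg = ModelConfig(**manifest["model_config"])
        model = RnnRegressor(cfg)
        params = model.named_params()
        for k in params:
            params[k][...] = weights[k]
        for i, bn in enumerate(model.bns):
            bn.running_mean = weights[f"bn{i}.running_mean"]
            bn.running_var = weights[f"bn{i}.running_var"]
        tr = manifest["target_ranges"]
        if tr is not None:
            model.target_ranges = {k: tuple(v) for k, v in tr.items()}
        return model
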