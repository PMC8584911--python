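"""Concrete autoencoder (CAE) for unsupervised selection of actual features.

The encoder is a *concrete selection layer*: ``k`` nodes, each holding a vector
of logits over the ``n`` input features. During training each node draws a
relaxed one-hot weight vector from the concrete (Gumbel-softmax) distribution

    w = softmax((logits + g) / T),   g ~ Gumbel(0, 1) i.i.d.,

and the encoding is the weighted input ``z_j = w_j . x``. The temperature ``T``
is annealed from a high value (near-uniform, exploratory) to a low value
(near-one-hot, committed) on an exponential schedule, so that by the end of
training each node has effectively selected one concrete input feature. A
feedforward decoder (two hidden layers, leaky ReLU, dropout, linear output)
reconstructs all ``n`` inputs from the ``k`` selections; the training loss is
the mean squared reconstruction error.

Everything is NumPy with hand-written backpropagation and Adam (a few numba
kernels cover the elementwise hot paths), which keeps runs bit-reproducible
for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

from .data_io import ExpressionMatrix, LabelVector, ValidationError, stratified_split


class ConfigError(ValueError):
    """A CAE configuration violates its invariants."""


@dataclass
class CAEConfig:
    """Hyperparameters of a single CAE run.

    Defaults follow the tuned operating point for expression data: a decoder
    with two 300-node hidden layers, leaky ReLU slope 0.1, 10% dropout,
    300 epochs at learning rate 0.002 (Adam), temperature annealed 10.0 -> 0.1.
    """

    k: int = 10
    hidden_sizes: tuple[int, ...] = (300, 300)
    leaky_relu_slope: float = 0.1
    dropout_rate: float = 0.1
    epochs: int = 300
    learning_rate: float = 0.002
    t_start: float = 10.0
    t_end: float = 0.1
    batch_size: int = 32
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if n_features is not None and self.k >= n_features:
            raise ConfigError(f"k={self.k} must be < n_features={n_features}")
        if not 0 < self.t_end < self.t_start:
            raise ConfigError("temperatures must satisfy 0 < t_end < t_start")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


@dataclass
class SelectorState:
    """Parameters of the concrete selection layer: k x n logits and T."""

    logits: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=float)
        if self.logits.ndim != 2:
            raise ValueError("logits must be a k x n matrix")
        if not np.isfinite(self.logits).all():
            raise ValueError("logits must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def probabilities(self) -> np.ndarray:
        """Per-node selection probabilities softmax(logits / T)."""
        scaled = self.logits / self.temperature
        scaled = scaled - scaled.max(axis=1, keepdims=True)
        e = np.exp(scaled)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class CharacteristicTrace:
    """Per-epoch convergence diagnostics of one CAE run.

    Mirrors the four curves of the characteristic plot: annealed temperature,
    mean-max selection probability, training loss and validation loss.
    """

    temperature: np.ndarray
    mean_max_prob: np.ndarray
    train_loss: np.ndarray
    val_loss: np.ndarray

    def __len__(self) -> int:
        return len(self.temperature)

    def to_dict(self) -> dict:
        return {
            "temperature": [float(v) for v in self.temperature],
            "mean_max_prob": [float(v) for v in self.mean_max_prob],
            "train_loss": [float(v) for v in self.train_loss],
            "val_loss": [float(v) for v in self.val_loss],
        }


@dataclass
class DecoderParams:
    """Trained decoder weights plus the feature ordering they were fit to."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    leaky_relu_slope: float
    feature_ids: list[str]

    def forward(self, z: np.ndarray) -> np.ndarray:
        h = z
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = h @ W + b
            h = np.where(h >= 0, h, self.leaky_relu_slope * h)
        return h @ self.weights[-1] + self.biases[-1]


@dataclass
class RunResult:
    """Outcome of one CAE run.

    ``per_node_pick`` is the argmax feature of each selector node (duplicates
    possible); ``selected_unique`` deduplicates it. ``val_mse`` is the
    reconstruction MSE on the held-out split with hard one-hot selection.
    """

    selected_unique: set[str]
    per_node_pick: list[str]
    trace: CharacteristicTrace
    val_mse: float
    config: CAEConfig
    seed: int
    decoder: DecoderParams | None = None

    def to_dict(self) -> dict:
        cfg = dict(self.config.__dict__)
        cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
        return {
            "seed": self.seed,
            "selected_unique": sorted(self.selected_unique),
            "per_node_pick": list(self.per_node_pick),
            "val_mse": float(self.val_mse),
            "config": cfg,
            "trace": self.trace.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunResult":
        cfg = dict(d["config"])
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        tr = d["trace"]
        return cls(
            selected_unique=set(d["selected_unique"]),
            per_node_pick=list(d["per_node_pick"]),
            trace=CharacteristicTrace(
                np.asarray(tr["temperature"]),
                np.asarray(tr["mean_max_prob"]),
                np.asarray(tr["train_loss"]),
                np.asarray(tr["val_loss"]),
            ),
            val_mse=float(d["val_mse"]),
            config=CAEConfig(**cfg),
            seed=int(d["seed"]),
        )


def sample_concrete_weights(
    logits: np.ndarray, temperature: float, noise: np.ndarray
) -> np.ndarray:
    """Relaxed one-hot weights softmax((logits + noise) / T) along the last axis.

    ``noise`` holds standard Gumbel draws of the same shape as ``logits``
    (pass zeros for the deterministic mean path). Weights are non-negative and
    sum to one along the feature axis; for fixed noise the map is smooth in the
    logits, which is what makes feature selection trainable by gradient
    descent.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    s = (logits + noise) / temperature
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def anneal_temperature(
    epoch: int, total_epochs: int, t_start: float = 10.0, t_end: float = 0.1
) -> float:
    """Exponential annealing: T(e) = t_start * (t_end / t_start) ** (e / E).

    Decreases monotonically from ``t_start`` at epoch 0 to exactly ``t_end``
    at ``epoch == total_epochs``.
    """
    if not 0 < t_end < t_start:
        raise ValueError("need 0 < t_end < t_start")
    if not 0 <= epoch <= total_epochs:
        raise ValueError("need 0 <= epoch <= total_epochs")
    if total_epochs == 0:
        return t_end
    return float(t_start * (t_end / t_start) ** (epoch / total_epochs))


def mean_max_probability(state: SelectorState) -> float:
    """Mean over selector nodes of each node's maximum selection probability.

    Approaches 1 as every node commits to a single feature; equals 1/n when
    every node is uniform. A convergence diagnostic for the trace.
    """
    return float(state.probabilities().max(axis=1).mean())


def _gumbel(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Standard Gumbel draws G = -log(-log U), computed in place in ``out``."""
    if out is None:
        out = np.empty(shape, dtype=np.float32)
    rng.random(out=out, dtype=np.float32)
    np.maximum(out, np.float32(1e-12), out=out)
    np.log(out, out=out)
    np.negative(out, out=out)
    np.log(out, out=out)
    np.negative(out, out=out)
    return out


@numba.njit(cache=True, fastmath=True)
def _adam_kernel(theta, grad, m, v, b1, b2, alpha, eps_hat):  # pragma: no cover
    one = np.float32(1.0)
    for i in range(theta.size):
        g = grad[i]
        m[i] = b1 * m[i] + (one - b1) * g
        v[i] = b2 * v[i] + (one - b2) * g * g
        theta[i] -= alpha * m[i] / (np.sqrt(v[i]) + eps_hat)


class _Adam:
    """Adam over one flat float32 parameter vector (single fused pass)."""

    def __init__(self, theta: np.ndarray, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = np.zeros_like(theta)
        self.v = np.zeros_like(theta)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        # p -= lr * (m/b1t) / (sqrt(v/b2t) + eps), algebraically rearranged
        alpha = np.float32(self.lr * math.sqrt(b2t) / b1t)
        eps_hat = np.float32(self.eps * math.sqrt(b2t))
        _adam_kernel(
            theta, grad, self.m, self.v,
            np.float32(self.b1), np.float32(self.b2), alpha, eps_hat,
        )


@numba.njit(cache=True, fastmath=True)
def _selector_grad_kernel(w, dz, x, z, out):  # pragma: no cover
    # dlogits[k,n] = sum_b w[b,k,n] * dz[b,k] * (x[b,n] - z[b,k])
    B, k, n = w.shape
    out[:] = np.float32(0.0)
    for b in range(B):
        for j in range(k):
            c = dz[b, j]
            zz = z[b, j]
            for i in range(n):
                out[j, i] += w[b, j, i] * c * (x[b, i] - zz)


@numba.njit(cache=True, fastmath=True)
def _leaky_dropout_fwd(pre, u, out, slope, p):  # pragma: no cover
    # out = inverted-dropout(leaky_relu(pre)); u holds U(0,1) draws
    zero = np.float32(0.0)
    scale = np.float32(1.0) / (np.float32(1.0) - p)
    pr, uu, o = pre.reshape(-1), u.reshape(-1), out.reshape(-1)
    for i in range(pr.size):
        h = pr[i]
        if h < zero:
            h *= slope
        o[i] = zero if uu[i] < p else h * scale


@numba.njit(cache=True, fastmath=True)
def _leaky_dropout_bwd(dh, pre, u, slope, p):  # pragma: no cover
    zero = np.float32(0.0)
    scale = np.float32(1.0) / (np.float32(1.0) - p)
    d, pr, uu = dh.reshape(-1), pre.reshape(-1), u.reshape(-1)
    for i in range(d.size):
        if uu[i] < p:
            d[i] = zero
        else:
            g = d[i] * scale
            if pr[i] < zero:
                g *= slope
            d[i] = g


@numba.njit(cache=True, fastmath=True)
def _leaky_fwd(pre, out, slope):  # pragma: no cover
    zero = np.float32(0.0)
    pr, o = pre.reshape(-1), out.reshape(-1)
    for i in range(pr.size):
        h = pr[i]
        if h < zero:
            h *= slope
        o[i] = h


class _Network:
    """Selector logits + decoder, with hand-written forward/backward.

    All parameters and activations are float32; the concrete selection noise
    is drawn per sample (each sample in a minibatch explores its own relaxed
    one-hot draw, which is what makes the selector rank correlated features
    reliably at small sample sizes).
    """

    def __init__(self, n: int, cfg: CAEConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.n = n
        sizes = [cfg.k, *cfg.hidden_sizes, n]
        shapes = [(cfg.k, n)]
        shapes += [(i, o) for i, o in zip(sizes[:-1], sizes[1:])]
        shapes += [(o,) for o in sizes[1:]]
        total = sum(int(np.prod(s)) for s in shapes)
        # single flat parameter/gradient buffer; per-tensor views into it
        self.theta = np.empty(total, dtype=np.float32)
        self.grad = np.zeros(total, dtype=np.float32)

        def carve(buf):
            views, off = [], 0
            for s in shapes:
                size = int(np.prod(s))
                views.append(buf[off : off + size].reshape(s))
                off += size
            return views

        pviews = carve(self.theta)
        gviews = carve(self.grad)
        n_layers = len(sizes) - 1
        self.logits = pviews[0]
        self.W = pviews[1 : 1 + n_layers]
        self.b = pviews[1 + n_layers :]
        self._g_logits = gviews[0]
        self._gW = gviews[1 : 1 + n_layers]
        self._gb = gviews[1 + n_layers :]

        # symmetric (zero) start: nodes differentiate only through their
        # stochastic concrete draws, which reduces early lock-in
        self.logits[:] = 0.0
        for W, (fan_in, _) in zip(self.W, zip(sizes[:-1], sizes[1:])):
            W[:] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=W.shape)
        for b in self.b:
            b[:] = 0.0
        self.opt = _Adam(self.theta, cfg.learning_rate)

    # -- decoder -----------------------------------------------------------
    def _decode(self, z: np.ndarray, rng: np.random.Generator | None):
        """Forward through the decoder; rng enables (inverted) dropout."""
        slope = np.float32(self.cfg.leaky_relu_slope)
        p = np.float32(self.cfg.dropout_rate)
        cache = {"h": [z], "pre": [], "u": []}
        h = z
        for W, b in zip(self.W[:-1], self.b[:-1]):
            pre = h @ W
            pre += b
            h = np.empty_like(pre)
            if rng is not None and p > 0:
                u = rng.random(pre.shape, dtype=np.float32)
                _leaky_dropout_fwd(pre, u, h, slope, p)
            else:
                u = None
                _leaky_fwd(pre, h, slope)
            cache["pre"].append(pre)
            cache["u"].append(u)
            cache["h"].append(h)
        out = h @ self.W[-1]
        out += self.b[-1]
        return out, cache

    def _decode_backward(self, d_out: np.ndarray, cache) -> np.ndarray:
        """Backprop through the decoder, writing into the flat grad views."""
        slope = np.float32(self.cfg.leaky_relu_slope)
        p = np.float32(self.cfg.dropout_rate)
        np.matmul(cache["h"][-1].T, d_out, out=self._gW[-1])
        d_out.sum(axis=0, out=self._gb[-1])
        dh = d_out @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            u = cache["u"][i]
            if u is not None:
                _leaky_dropout_bwd(dh, cache["pre"][i], u, slope, p)
            else:
                dh *= np.where(cache["pre"][i] >= 0, np.float32(1.0), slope)
            np.matmul(cache["h"][i].T, dh, out=self._gW[i])
            dh.sum(axis=0, out=self._gb[i])
            dh = dh @ self.W[i].T
        return dh  # gradient w.r.t. z

    # -- full training step ------------------------------------------------
    def train_step(self, x: np.ndarray, gumbel: np.ndarray, temperature: float,
                   rng: np.random.Generator):
        """One minibatch update with per-sample concrete selection. Returns loss.

        ``gumbel`` holds standard Gumbel draws of shape (batch, k, n); it is
        consumed (overwritten) as scratch space.
        """
        inv_t = np.float32(1.0 / temperature)
        g = gumbel
        g += self.logits[None, :, :]
        g *= inv_t
        g -= g.max(axis=-1, keepdims=True)
        w = np.exp(g, out=g)
        w /= w.sum(axis=-1, keepdims=True)
        z = np.einsum("bkn,bn->bk", w, x)
        out, cache = self._decode(z, rng)
        err = out - x
        loss = float(np.mean(err**2))

        err *= np.float32(2.0 / err.size)
        dz = self._decode_backward(err, cache)
        # z = sum_n w_bkn x_bn through the per-row softmax jacobian:
        # dlogits = (1/T) sum_b w .* dz (x - z)
        _selector_grad_kernel(w, dz * inv_t, x, z, self._g_logits)

        self.opt.step(self.theta, self.grad)
        return loss

    def stochastic_loss(
        self, x: np.ndarray, temperature: float, rng: np.random.Generator
    ) -> float:
        """MSE with sampled concrete selection, no dropout (validation curve).

        One concrete draw per selector node, shared across the validation
        samples; enough stochasticity for the convergence curve at a fraction
        of the per-sample cost.
        """
        g = _gumbel(rng, (self.cfg.k, self.n))
        w = sample_concrete_weights(self.logits, temperature, g).astype(np.float32)
        z = x @ w.T
        out, _ = self._decode(z, None)
        return float(np.mean((out - x) ** 2))

    def hard_loss(self, x: np.ndarray) -> float:
        """MSE with hard argmax selection, no dropout (final evaluation)."""
        picks = self.logits.argmax(axis=1)
        out, _ = self._decode(x[:, picks], None)
        return float(np.mean((out - x) ** 2))


def _split_indices(
    m: ExpressionMatrix,
    labels: LabelVector | None,
    seed: int,
    test_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    if labels is not None:
        return stratified_split(m, labels, test_fraction, seed)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(m.n_samples)
    n_test = max(1, int(round(test_fraction * m.n_samples)))
    return np.sort(idx[n_test:]), np.sort(idx[:n_test])


def train_cae(
    m: ExpressionMatrix,
    cfg: CAEConfig,
    labels: LabelVector | None = None,
) -> RunResult:
    """Train one concrete autoencoder and extract its selected features.

    The cohort is split 80/20 (stratified by class when ``labels`` is given);
    the selector logits and decoder are trained by Adam on minibatch
    reconstruction MSE with the temperature annealed once per epoch. The trace
    records temperature, mean-max probability, training loss and
    validation loss (stochastic selection at the current temperature) at every
    epoch. After the last epoch each node's argmax feature is extracted and
    the held-out MSE is recomputed with hard one-hot selection.

    Fully deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate(m.n_features)
    if not m.normalized:
        raise ValidationError("train_cae expects a min-max normalized matrix")
    if m.n_samples < 2:
        raise ValidationError("need at least 2 samples")

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _split_indices(m, labels, cfg.seed)
    x_train = np.ascontiguousarray(m.values[train_idx], dtype=np.float32)
    x_val = np.ascontiguousarray(m.values[val_idx], dtype=np.float32)

    net = _Network(m.n_features, cfg, rng)

    temps = np.empty(cfg.epochs)
    mmp = np.empty(cfg.epochs)
    tr_loss = np.empty(cfg.epochs)
    va_loss = np.empty(cfg.epochs)

    n_train = x_train.shape[0]
    g_pool = np.empty((n_train, cfg.k, m.n_features), dtype=np.float32)
    for epoch in range(cfg.epochs):
        # last epoch runs at exactly t_end
        temperature = anneal_temperature(
            epoch, max(cfg.epochs - 1, 1), cfg.t_start, cfg.t_end
        ) if cfg.epochs > 1 else cfg.t_end
        order = rng.permutation(n_train)
        g_epoch = _gumbel(rng, g_pool.shape, out=g_pool)
        losses = []
        for start in range(0, n_train, cfg.batch_size):
            batch = x_train[order[start : start + cfg.batch_size]]
            g = g_epoch[start : start + cfg.batch_size]
            losses.append(net.train_step(batch, g, temperature, rng))
        temps[epoch] = temperature
        tr_loss[epoch] = float(np.mean(losses))
        va_loss[epoch] = net.stochastic_loss(x_val, temperature, rng)
        mmp[epoch] = mean_max_probability(SelectorState(net.logits, temperature))

    picks_idx = net.logits.argmax(axis=1)
    per_node_pick = [m.feature_ids[i] for i in picks_idx]
    decoder = DecoderParams(
        weights=[W.copy() for W in net.W],
        biases=[b.copy() for b in net.b],
        leaky_relu_slope=cfg.leaky_relu_slope,
        feature_ids=list(m.feature_ids),
    )
    return RunResult(
        selected_unique=set(per_node_pick),
        per_node_pick=per_node_pick,
        trace=CharacteristicTrace(temps, mmp, tr_loss, va_loss),
        val_mse=net.hard_loss(x_val),
        config=cfg,
        seed=cfg.seed,
        decoder=decoder,
    )


def reconstruction_mse(result: RunResult, m: ExpressionMatrix) -> float:
    """Reconstruction MSE of a trained run on a (held-out) matrix.

    Feeds only the run's hard-selected features to the decoder and averages
    the squared error over all samples of ``m`` and all features the decoder
    was trained to reconstruct.
    """
    if result.decoder is None:
        raise ValueError("run result carries no trained decoder")
    x = m.values[:, m.feature_index(result.decoder.feature_ids)]
    z = x[:, [result.decoder.feature_ids.index(f) for f in result.per_node_pick]]
    out = result.decoder.forward(z)
    return float(np.mean((out - x) ** 2))
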