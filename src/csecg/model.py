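"""Multi-kernel 1-D CNN for heartbeat classification.

The network ingests a 400-sample beat segment (single channel) and emits a
softmax probability vector over the five AAMI classes. Its building blocks:

* **convolution block** — 1-D convolution (same padding) -> batch
  normalisation -> ReLU -> dropout;
* **temporal transition module** — three parallel convolutions with kernel
  sizes 1, 3 and 11 (each conv -> batch-norm -> ReLU) whose outputs are
  concatenated along the channel axis, so short- and long-range beat
  morphology is captured at the same depth;
* max pooling after the first block, a global average pool, and a fully
  connected head with heavy dropout (0.75) before the softmax.

Default architecture:
conv(16,k5) -> maxpool(2,2) -> transition(8,8,16) -> conv(32,k5) ->
transition(16,16,32) -> conv(64,k5) -> global-average-pool -> FC(64,
dropout 0.75) -> softmax(5).

Everything — forward pass, backpropagation, SGD with L2 weight decay on the
convolution layers — is implemented directly on NumPy arrays, so training
is deterministic given a seed and runs on any CPU. Removing the transition
modules (``transition_filters=()``) degrades to the plain-CNN ablation
baseline.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .cs_loss import compute_batch_cost, total_loss
from .segment import SEGMENT_LENGTH, SegmentDataset

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    ``conv_blocks`` lists (filters, kernel_size, dropout_rate) for the
    stacked convolution blocks; ``transition_filters`` lists the per-branch
    filter counts of the transition module placed after each of the first
    ``len(transition_filters)`` blocks. The third transition kernel (11 by
    default) was chosen over 15 and 21; all three remain configurable.
    """

    n_classes: int = 5
    conv_blocks: tuple[tuple[int, int, float], ...] = (
        (16, 5, 0.2), (32, 5, 0.2), (64, 5, 0.2),
    )
    transition_kernels: tuple[int, ...] = (1, 3, 11)
    transition_filters: tuple[tuple[int, ...], ...] = ((8, 8, 16), (16, 16, 32))
    pool_size: int = 2
    pool_stride: int = 2
    fc_units: int = 64
    fc_dropout: float = 0.75
    l2: float = 0.003
    activation: str = "relu"
    seed: int = 0
    input_length: int = SEGMENT_LENGTH
    dtype: str = "float32"

    def validate(self) -> None:
        for filters, kernel, rate in self.conv_blocks:
            if kernel <= 0 or kernel % 2 == 0:
                raise ValueError(f"kernel sizes must be odd positive, got {kernel}")
            if not 0 <= rate <= 0.75:
                raise ValueError(f"dropout rate {rate} outside [0, 0.75]")
            if filters <= 0:
                raise ValueError("filter counts must be positive")
        for kernel in self.transition_kernels:
            if kernel <= 0 or kernel % 2 == 0:
                raise ValueError(f"kernel sizes must be odd positive, got {kernel}")
        for branch in self.transition_filters:
            if len(branch) != len(self.transition_kernels):
                raise ValueError(
                    "each transition entry needs one filter count per branch"
                )
        if not 0 <= self.fc_dropout <= 0.75:
            raise ValueError(f"fc_dropout {self.fc_dropout} outside [0, 0.75]")
        if self.l2 < 0:
            raise ValueError("l2 must be nonnegative")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if len(self.transition_filters) > len(self.conv_blocks):
            raise ValueError("more transition modules than convolution blocks")

    @staticmethod
    def small(seed: int = 0) -> "ModelConfig":
        """A slimmer configuration for desk-scale benchmarks."""
        return ModelConfig(
            conv_blocks=((8, 5, 0.1), (16, 5, 0.1), (32, 5, 0.1)),
            transition_filters=((4, 4, 8), (8, 8, 16)),
            pool_size=4, pool_stride=4,
            fc_units=32,
            seed=seed,
        )


@dataclass
class TrainConfig:
    """SGD schedule (defaults: LR 0.01, L2 from the model config)."""

    epochs: int = 10
    batch_size: int = 128
    lr: float = 0.01
    loss: str = "cs"            # "cs" (cost-sensitive) or "ce"
    phi_max: float | None = None
    verbose: bool = False


# ---------------------------------------------------------------------------
# Layers (forward + manual backward)
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward, backward, parameter list."""

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator
                ) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray, bool]]:
        """(value, gradient, apply_l2) triples."""
        return []


class Conv1D(_Layer):
    """Same-padding 1-D convolution on (batch, length, channels) maps.

    Weights are stored as (in_channels, kernel, filters) so the im2col
    window view reshapes into the matmul without reordering.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float64):
        if kernel % 2 == 0 or kernel <= 0:
            raise ValueError("kernel size must be odd positive")
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = (rng.standard_normal((in_channels, kernel, filters)) * scale
                  ).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.kernel = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        if self.kernel > x.shape[1]:
            raise ValueError(
                f"kernel {self.kernel} exceeds feature length {x.shape[1]}"
            )
        B, L, Cin = x.shape
        k = self.kernel
        pad = (k - 1) // 2
        x_pad = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (B, L, Cin, k) window view -> one (B*L, Cin*k) gemm operand
        wins = np.lib.stride_tricks.sliding_window_view(x_pad, k, axis=1)
        self._cols = np.ascontiguousarray(wins).reshape(B * L, Cin * k)
        self._shape = (B, L, Cin)
        out = self._cols @ self.W.reshape(Cin * k, -1) + self.b
        return out.reshape(B, L, -1)

    def backward(self, grad):
        B, L, Cin = self._shape
        k = self.kernel
        pad = (k - 1) // 2
        g = grad.reshape(B * L, -1)
        self.dW = (self._cols.T @ g).reshape(self.W.shape)
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.reshape(Cin * k, -1).T).reshape(B, L, Cin, k)
        dx_pad = np.zeros((B, L + 2 * pad, Cin), dtype=grad.dtype)
        for j in range(k):
            dx_pad[:, j: j + L, :] += dcols[:, :, :, j]
        return dx_pad[:, pad: pad + L, :]

    def params(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]


class BatchNorm(_Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, dtype=np.float64):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (_BN_MOMENTUM * self.running_mean
                                 + (1 - _BN_MOMENTUM) * mean)
            self.running_var = (_BN_MOMENTUM * self.running_var
                                + (1 - _BN_MOMENTUM) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + _BN_EPS)
        xhat = (x - mean) / std
        self._cache = (xhat, std, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, std, n = self._cache
        self.dgamma = (grad * xhat).sum(axis=(0, 1))
        self.dbeta = grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma
        return (dxhat - dxhat.mean(axis=(0, 1))
                - xhat * (dxhat * xhat).mean(axis=(0, 1))) / std

    def params(self):
        return [(self.gamma, self.dgamma, False), (self.beta, self.dbeta, False)]


class ReLU(_Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(_Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32
                       else np.float64)
        self._mask = (u < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool(_Layer):
    """Max pooling with pool size R and stride T; out = floor((L-R)/T)+1."""

    def __init__(self, pool_size: int, stride: int):
        if pool_size < 1 or stride < 1:
            raise ValueError("pool size and stride must be >= 1")
        self.R, self.T = pool_size, stride

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        if self.R > L:
            raise ValueError(f"pool size {self.R} exceeds feature length {L}")
        n_out = (L - self.R) // self.T + 1
        starts = np.arange(n_out) * self.T
        wins = np.stack([x[:, starts + r, :] for r in range(self.R)], axis=2)
        self._arg = wins.argmax(axis=2)
        self._in_shape = x.shape
        self._starts = starts
        return wins.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        n_out = self._arg.shape[1]
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        pos = self._starts[None, :, None] + self._arg         # (B, n_out, C)
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(dx, (np.broadcast_to(b_idx, pos.shape), pos,
                       np.broadcast_to(c_idx, pos.shape)), grad)
        return dx


class GlobalAveragePool(_Layer):
    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._L, axis=1) / self._L


class Dense(_Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 dtype=np.float64):
        scale = np.sqrt(2.0 / in_features)
        self.W = (rng.standard_normal((in_features, units)) * scale).astype(dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW, False), (self.b, self.db, False)]


class ConvBlock(_Layer):
    """Convolution -> batch normalisation -> ReLU -> dropout."""

    def __init__(self, in_channels, filters, kernel, dropout_rate,
                 rng, dtype=np.float64):
        self.conv = Conv1D(in_channels, filters, kernel, rng, dtype)
        self.bn = BatchNorm(filters, dtype)
        self.act = ReLU()
        self.drop = Dropout(dropout_rate)
        self.out_channels = filters

    def forward(self, x, train=False, rng=None):
        x = self.conv.forward(x, train, rng)
        x = self.bn.forward(x, train, rng)
        x = self.act.forward(x, train, rng)
        return self.drop.forward(x, train, rng)

    def backward(self, grad):
        grad = self.drop.backward(grad)
        grad = self.act.backward(grad)
        grad = self.bn.backward(grad)
        return self.conv.backward(grad)

    def params(self):
        return self.conv.params() + self.bn.params()


class TemporalTransition(_Layer):
    """Parallel convolutions (kernels 1/3/11) concatenated channelwise.

    Each branch is conv -> batch-norm -> ReLU; the output channel count is
    the sum of the branch filter counts.
    """

    def __init__(self, in_channels, branch_filters, kernels=(1, 3, 11),
                 rng=None, dtype=np.float64):
        if len(branch_filters) != len(kernels):
            raise ValueError("one filter count per branch kernel required")
        rng = rng or np.random.default_rng()
        self.branches = []
        for filters, kernel in zip(branch_filters, kernels):
            self.branches.append((
                Conv1D(in_channels, filters, kernel, rng, dtype),
                BatchNorm(filters, dtype),
                ReLU(),
            ))
        self.out_channels = int(sum(branch_filters))
        self._splits = np.cumsum(branch_filters)[:-1]

    def forward(self, x, train=False, rng=None):
        outs = []
        for conv, bn, act in self.branches:
            h = conv.forward(x, train, rng)
            h = bn.forward(h, train, rng)
            outs.append(act.forward(h, train, rng))
        return np.concatenate(outs, axis=2)

    def backward(self, grad):
        dx = None
        for (conv, bn, act), g in zip(self.branches,
                                      np.split(grad, self._splits, axis=2)):
            g = act.backward(g)
            g = bn.backward(g)
            g = conv.backward(g)
            dx = g if dx is None else dx + g
        return dx

    def params(self):
        out = []
        for conv, bn, _ in self.branches:
            out += conv.params() + bn.params()
        return out


# ---------------------------------------------------------------------------
# Functional wrappers (single-shot application with fresh weights)
# ---------------------------------------------------------------------------

def conv_block(features: np.ndarray, filters: int, kernel: int,
               seed: int = 0, train: bool = False) -> np.ndarray:
    """Apply a freshly initialised convolution block to a feature map."""
    rng = np.random.default_rng(seed)
    block = ConvBlock(features.shape[2], filters, kernel, 0.0, rng,
                      dtype=features.dtype)
    return block.forward(np.asarray(features), train, rng)


def max_pool(features: np.ndarray, pool_size: int, stride: int) -> np.ndarray:
    """Max pooling over the length axis of a (batch, length, channels) map."""
    return MaxPool(pool_size, stride).forward(np.asarray(features))


def temporal_transition(features: np.ndarray,
                        branch_filters: tuple[int, ...] = (8, 8, 16),
                        kernels: tuple[int, ...] = (1, 3, 11),
                        seed: int = 0, train: bool = False) -> np.ndarray:
    """Apply a freshly initialised temporal transition module."""
    rng = np.random.default_rng(seed)
    module = TemporalTransition(features.shape[2], branch_filters, kernels,
                                rng, dtype=features.dtype)
    return module.forward(np.asarray(features), train, rng)


# ---------------------------------------------------------------------------
# The classifier
# ---------------------------------------------------------------------------

class BeatClassifier:
    """The full network with SGD training and softmax probabilities."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.config.validate()
        dtype = np.dtype(self.config.dtype).type
        self._dtype = dtype
        rng = np.random.default_rng(self.config.seed)

        cfg = self.config
        layers: list[_Layer] = []
        channels = 1
        for i, (filters, kernel, rate) in enumerate(cfg.conv_blocks):
            layers.append(ConvBlock(channels, filters, kernel, rate, rng, dtype))
            channels = filters
            if i == 0 and cfg.pool_size > 1:
                layers.append(MaxPool(cfg.pool_size, cfg.pool_stride))
            if i < len(cfg.transition_filters):
                module = TemporalTransition(
                    channels, cfg.transition_filters[i],
                    cfg.transition_kernels, rng, dtype,
                )
                layers.append(module)
                channels = module.out_channels
        layers.append(GlobalAveragePool())
        layers.append(Dense(channels, cfg.fc_units, rng, dtype))
        layers.append(ReLU())
        layers.append(Dropout(cfg.fc_dropout))
        layers.append(Dense(cfg.fc_units, cfg.n_classes, rng, dtype))
        self.layers = layers

    # -- inference ---------------------------------------------------------

    #: Evaluation-mode forward passes are chunked to keep the convolution
    #: workspaces cache-resident; results are unaffected.
    _EVAL_CHUNK = 256

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities for a (batch, 400) or (batch, 400, 1) input."""
        x = np.asarray(X, dtype=self._dtype)
        if x.ndim == 2:
            x = x[:, :, None]
        if not train and x.shape[0] > self._EVAL_CHUNK:
            return np.concatenate([
                self.forward(x[i: i + self._EVAL_CHUNK])
                for i in range(0, x.shape[0], self._EVAL_CHUNK)
            ])
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return _softmax(x)

    predict_proba = forward

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X), axis=1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for layer in self.layers
                       for p, _, _ in layer.params()))

    # -- training ----------------------------------------------------------

    def fit(
        self,
        dataset: SegmentDataset,
        train_config: TrainConfig | None = None,
        log_hook: Callable[[dict], None] | None = None,
    ) -> list[dict]:
        """Train with SGD; returns per-epoch log dictionaries.

        With ``loss='cs'`` the per-class misclassification cost phi is
        recomputed for every batch from the batch's composition and the
        model's own arg-max predictions on it (no gradient through phi);
        ``loss='ce'`` is the plain cross-entropy arm. L2 weight decay
        applies to convolution kernels only.
        """
        tc = train_config or TrainConfig()
        if tc.loss not in ("cs", "ce"):
            raise ValueError(f"unknown loss {tc.loss!r}; expected 'cs' or 'ce'")
        rng = np.random.default_rng(self.config.seed + 1)
        X = np.asarray(dataset.X, dtype=self._dtype)[:, :, None]
        y = dataset.y
        n = len(y)
        C = self.config.n_classes
        dataset_counts = np.bincount(y, minlength=C)
        history: list[dict] = []
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            t0 = time.perf_counter()
            for start in range(0, n, tc.batch_size):
                idx = order[start: start + tc.batch_size]
                xb, yb = X[idx], y[idx]
                probs = self._forward_train(xb, rng)
                preds = np.argmax(probs, axis=1)
                if tc.loss == "cs":
                    state = compute_batch_cost(yb, preds, dataset_counts, C)
                    phi = state.phi
                    if tc.phi_max is not None:
                        phi = np.minimum(phi, tc.phi_max)
                else:
                    phi = np.ones(C)
                epoch_loss += total_loss(probs, yb, phi) * len(yb)
                self._backward_sgd(probs, yb, phi.astype(self._dtype), tc.lr)
            entry = {
                "epoch": epoch,
                "loss": epoch_loss / n,
                "seconds": time.perf_counter() - t0,
            }
            history.append(entry)
            if log_hook is not None:
                log_hook(entry)
            if tc.verbose:
                print(f"epoch {epoch}: loss={entry['loss']:.4f} "
                      f"({entry['seconds']:.1f}s)")
        return history

    def _forward_train(self, xb, rng):
        x = xb
        for layer in self.layers:
            x = layer.forward(x, True, rng)
        return _softmax(x)

    def _backward_sgd(self, probs, yb, phi, lr):
        M = len(yb)
        grad = probs.copy()
        grad[np.arange(M), yb] -= 1.0
        grad *= (phi[yb] / M)[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        l2 = self.config.l2
        for layer in self.layers:
            for value, g, decay in layer.params():
                value -= lr * (g + (l2 * value if decay else 0.0))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.json`` (architecture) and ``<path>.npz`` (weights)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, (value, _, _) in enumerate(layer.params()):
                arrays[f"layer{i}_param{j}"] = value
            if isinstance(layer, (ConvBlock,)):
                arrays[f"layer{i}_rmean"] = layer.bn.running_mean
                arrays[f"layer{i}_rvar"] = layer.bn.running_var
            if isinstance(layer, BatchNorm):
                arrays[f"layer{i}_rmean"] = layer.running_mean
                arrays[f"layer{i}_rvar"] = layer.running_var
            if isinstance(layer, TemporalTransition):
                for k, (_, bn, _) in enumerate(layer.branches):
                    arrays[f"layer{i}_branch{k}_rmean"] = bn.running_mean
                    arrays[f"layer{i}_branch{k}_rvar"] = bn.running_var
        np.savez(path.with_suffix(".npz"), **arrays)

    @staticmethod
    def load(path: str | Path) -> "BeatClassifier":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            raw = json.load(fh)
        raw["conv_blocks"] = tuple(tuple(b) for b in raw["conv_blocks"])
        raw["transition_kernels"] = tuple(raw["transition_kernels"])
        raw["transition_filters"] = tuple(
            tuple(b) for b in raw["transition_filters"]
        )
        clf = BeatClassifier(ModelConfig(**raw))
        data = np.load(path.with_suffix(".npz"))
        for i, layer in enumerate(clf.layers):
            for j, (value, _, _) in enumerate(layer.params()):
                value[...] = data[f"layer{i}_param{j}"]
            if isinstance(layer, ConvBlock):
                layer.bn.running_mean = data[f"layer{i}_rmean"]
                layer.bn.running_var = data[f"layer{i}_rvar"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = data[f"layer{i}_rmean"]
                layer.running_var = data[f"layer{i}_rvar"]
            if isinstance(layer, TemporalTransition):
                for k, (_, bn, _) in enumerate(layer.branches):
                    bn.running_mean = data[f"layer{i}_branch{k}_rmean"]
                    bn.running_var = data[f"layer{i}_branch{k}_rvar"]
        return clf


def build_model(config: ModelConfig | None = None) -> BeatClassifier:
    """Validate the configuration and construct the classifier."""
    return BeatClassifier(config)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
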