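"""The lightweight multiscale CNN: layers, forward/backward pass, training.

The network classifies a single second of e-nose data (one 10-sensor G/G0
vector) with a local-global-local pipeline:

1. parallel bias-free 1x3 and 1x5 convolutions along the sensor axis
   (short- and medium-range cross-sensor patterns),
2. fusion of the two branches (elementwise superimposition or
   concatenation), ReLU,
3. a small stack of bias-free fully connected layers (global context),
4. reshape of the last hidden vector into a 2D feature map and a second
   bias-free convolution over it (local re-extraction),
5. a linear projection to a 4-unit discriminative space and a bias-free
   linear classifier producing raw class scores.

There are no pooling layers and no bias terms anywhere; with ~10 input
features pooling would discard information, and dropping biases roughly
halves the parameter count at negligible accuracy cost.  ReLU follows the
branch fusion, each hidden FC layer, and the second-stage convolution.  The
4-unit projection is linear: it factorizes the classifier through a
low-dimensional discriminative space, and (being bias-free on nonnegative
inputs) a rectified unit this narrow could die irrecoverably during SGD,
collapsing classes.  Softmax is folded into the cross-entropy loss.

Everything is plain vectorized numpy.  The backward pass is written by hand
and checked against central finite differences in the test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .data_model import N_SENSORS, InstanceTable

KERNEL_SHORT = 3
KERNEL_MID = 5


class ConfigError(ValueError):
    """Inconsistent architecture configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Parametric architecture template.

    ``fc_widths`` must end in a width equal to ``reshape_shape[0] *
    reshape_shape[1]``; with no FC layers the fused branch vector itself is
    reshaped.  ``stage2_kernel`` is a (rows, cols) kernel applied 'valid'
    over the reshaped map with ``f3`` filters.  The projection width is
    fixed at 4: the penultimate discriminative space shared by every task
    head, so switching the class count C changes exactly 4*C weights.
    """

    n_classes: int
    f1: int = 1                      # filters on the 1x3 branch
    f2: int = 1                      # filters on the 1x5 branch
    padding3: str = "same"           # {"valid", "same"}
    padding5: str = "same"
    fusion: str = "sum"              # {"concat", "sum"}
    fc_widths: tuple[int, ...] = (16,)
    reshape_shape: tuple[int, int] = (2, 8)
    stage2_kernel: tuple[int, int] = (1, 8)
    f3: int = 3
    projection_width: int = 4
    input_len: int = N_SENSORS
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.f1 < 1 or self.f2 < 1 or self.f3 < 1:
            raise ConfigError("filter counts must be >= 1")
        for pad in (self.padding3, self.padding5):
            if pad not in ("valid", "same"):
                raise ConfigError(f"unknown padding mode {pad!r}")
        if self.fusion not in ("concat", "sum"):
            raise ConfigError(f"unknown fusion mode {self.fusion!r}")
        if self.activation != "relu":
            raise ConfigError("only the ReLU hidden activation is supported")
        if self.projection_width != 4:
            raise ConfigError("projection width is fixed at 4")
        if self.fusion == "sum":
            if self.f1 != self.f2 or self.branch_len(3) != self.branch_len(5):
                raise ConfigError(
                    "sum fusion needs equal filter counts and branch lengths"
                )
        r, c = self.reshape_shape
        if r * c != self.hidden_width:
            raise ConfigError(
                f"reshape {self.reshape_shape} incompatible with hidden "
                f"width {self.hidden_width}"
            )
        kr, kc = self.stage2_kernel
        if not (1 <= kr <= r and 1 <= kc <= c):
            raise ConfigError("stage-2 kernel does not fit in the feature map")

    def branch_len(self, kernel: int) -> int:
        pad = self.padding3 if kernel == KERNEL_SHORT else self.padding5
        return self.input_len if pad == "same" else self.input_len - kernel + 1

    @property
    def fused_len(self) -> int:
        if self.fusion == "sum":
            return self.f1 * self.branch_len(KERNEL_SHORT)
        return self.f1 * self.branch_len(KERNEL_SHORT) + self.f2 * self.branch_len(
            KERNEL_MID
        )

    @property
    def hidden_width(self) -> int:
        """Width of the vector that gets reshaped into the 2D map."""
        return self.fc_widths[-1] if self.fc_widths else self.fused_len

    @property
    def stage2_positions(self) -> tuple[int, int]:
        r, c = self.reshape_shape
        kr, kc = self.stage2_kernel
        return (r - kr + 1, c - kc + 1)

    @property
    def flat_len(self) -> int:
        pr, pc = self.stage2_positions
        return self.f3 * pr * pc

    def layer_shapes(self) -> dict[str, tuple[int, ...]]:
        """Weight tensor shapes in forward order (bias-free throughout)."""
        shapes: dict[str, tuple[int, ...]] = {
            "conv3": (self.f1, KERNEL_SHORT),
            "conv5": (self.f2, KERNEL_MID),
        }
        prev = self.fused_len
        for i, w in enumerate(self.fc_widths):
            shapes[f"fc{i}"] = (w, prev)
            prev = w
        shapes["stage2"] = (self.f3, *self.stage2_kernel)
        shapes["proj"] = (self.projection_width, self.flat_len)
        shapes["classifier"] = (self.n_classes, self.projection_width)
        return shapes


@dataclass
class ParameterSet:
    """Named weight tensors in forward order (float path)."""

    tensors: dict[str, np.ndarray]
    dtype_tag: str = "float32"

    @property
    def n_elements(self) -> int:
        return int(sum(t.size for t in self.tensors.values()))

    def to_flat_bytes(self) -> bytes:
        """Flat little-endian 32-bit float serialization, forward order."""
        buf = io.BytesIO()
        for t in self.tensors.values():
            buf.write(np.ascontiguousarray(t, dtype="<f4").tobytes())
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.tensors)

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        with np.load(path) as archive:
            return cls(tensors={k: archive[k] for k in archive.files})

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            tensors={k: v.copy() for k, v in self.tensors.items()},
            dtype_tag=self.dtype_tag,
        )


def init_params(config: ModelConfig, seed: int = 0) -> ParameterSet:
    """Uniform +-sqrt(1/fan_in) initialization, seeded."""
    rng = np.random.default_rng(seed)
    tensors = {}
    for name, shape in config.layer_shapes().items():
        fan_in = int(np.prod(shape[1:]))
        bound = np.sqrt(1.0 / fan_in)
        tensors[name] = rng.uniform(-bound, bound, size=shape)
    return ParameterSet(tensors=tensors)


# ---------------------------------------------------------------------------
# layer primitives

def conv1d_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Bias-free 'valid' cross-correlation of a vector with a kernel.

    out[i] = sum_j x[i + j] * w[j], output length len(x) - len(w) + 1.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.ndim != 1 or w.ndim != 1:
        raise ConfigError("conv1d_valid expects 1-D input and kernel")
    if len(w) > len(x):
        raise ConfigError("kernel longer than input")
    windows = np.lib.stride_tricks.sliding_window_view(x, len(w))
    return windows @ w


def dense(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bias-free linear map: out = W @ x."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or x.shape[-1] != W.shape[1]:
        raise ConfigError(f"dense shape mismatch: W {W.shape} vs x {x.shape}")
    return x @ W.T


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _pad_same(X: np.ndarray, kernel: int) -> np.ndarray:
    """Zero-pad the sensor axis so a 'valid' conv keeps the input length."""
    left = (kernel - 1) // 2
    right = kernel - 1 - left
    return np.pad(X, ((0, 0), (left, right)))


def _branch(X: np.ndarray, w: np.ndarray, padding: str) -> np.ndarray:
    """Batched multi-filter 1D conv: (B, L) x (f, k) -> (B, f, L_out)."""
    k = w.shape[1]
    Xp = _pad_same(X, k) if padding == "same" else X
    windows = np.lib.stride_tricks.sliding_window_view(Xp, k, axis=1)
    return np.einsum("bpk,fk->bfp", windows, w)


# ---------------------------------------------------------------------------
# forward / backward

def forward_batch(
    config: ModelConfig, params: ParameterSet, X: np.ndarray, want_cache: bool = False
):
    """Raw class scores for a batch of 10-sensor vectors.

    Returns ``scores`` of shape (B, n_classes); with ``want_cache`` also the
    intermediate activations needed by :func:`backward_batch`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != config.input_len:
        raise ConfigError(
            f"input length {X.shape[1]} != configured {config.input_len}"
        )
    t = params.tensors
    B = X.shape[0]

    z3 = _branch(X, t["conv3"], config.padding3)   # (B, f1, L3)
    z5 = _branch(X, t["conv5"], config.padding5)   # (B, f2, L5)
    if config.fusion == "sum":
        fused = (z3 + z5).reshape(B, -1)
    else:
        fused = np.concatenate([z3.reshape(B, -1), z5.reshape(B, -1)], axis=1)
    h = relu(fused)

    fc_pre: list[np.ndarray] = []
    fc_post: list[np.ndarray] = [h]
    for i in range(len(config.fc_widths)):
        z = h @ t[f"fc{i}"].T
        fc_pre.append(z)
        h = relu(z)
        fc_post.append(h)

    r, c = config.reshape_shape
    M = h.reshape(B, r, c)
    kr, kc = config.stage2_kernel
    win = np.lib.stride_tricks.sliding_window_view(M, (kr, kc), axis=(1, 2))
    z2 = np.einsum("bijuv,fuv->bfij", win, t["stage2"])   # (B, f3, pr, pc)
    h2 = relu(z2)
    flat = h2.reshape(B, -1)

    zp = flat @ t["proj"].T   # linear projection: no activation
    hp = zp
    scores = hp @ t["classifier"].T

    if not want_cache:
        return scores
    cache = dict(
        X=X, z3=z3, z5=z5, fused=fused, fc_pre=fc_pre, fc_post=fc_post,
        M=M, win=win, z2=z2, h2=h2, flat=flat, zp=zp, hp=hp,
    )
    return scores, cache


def forward(config: ModelConfig, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """Raw class scores for a single 10-sensor vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigError("forward expects a single feature vector")
    return forward_batch(config, params, x[None, :])[0]


def predict(config: ModelConfig, params: ParameterSet, x: np.ndarray) -> int:
    """Argmax class; ties broken toward the lowest index."""
    return int(np.argmax(forward(config, params, x)))


def predict_batch(
    config: ModelConfig, params: ParameterSet, X: np.ndarray
) -> np.ndarray:
    return np.argmax(forward_batch(config, params, X), axis=1)


def backward_batch(
    config: ModelConfig,
    params: ParameterSet,
    cache: dict,
    dscores: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every weight tensor.

    ``dscores`` is d(loss)/d(raw scores), shape (B, n_classes).
    """
    t = params.tensors
    grads: dict[str, np.ndarray] = {}
    B = dscores.shape[0]

    grads["classifier"] = dscores.T @ cache["hp"]
    dhp = dscores @ t["classifier"]
    dzp = dhp   # projection is linear
    grads["proj"] = dzp.T @ cache["flat"]
    dflat = dzp @ t["proj"]

    dh2 = dflat.reshape(cache["h2"].shape)
    dz2 = dh2 * (cache["z2"] > 0)
    grads["stage2"] = np.einsum("bfij,bijuv->fuv", dz2, cache["win"])
    # scatter dz2 back through the stage-2 conv onto the feature map
    r, c = config.reshape_shape
    kr, kc = config.stage2_kernel
    dM = np.zeros((B, r, c))
    pr, pc = config.stage2_positions
    for u in range(kr):
        for v in range(kc):
            # contribution of kernel tap (u, v) to map cell (i+u, j+v)
            dM[:, u : u + pr, v : v + pc] += np.einsum(
                "bfij,f->bij", dz2, t["stage2"][:, u, v]
            )
    dh = dM.reshape(B, -1)

    for i in reversed(range(len(config.fc_widths))):
        dz = dh * (cache["fc_pre"][i] > 0)
        grads[f"fc{i}"] = dz.T @ cache["fc_post"][i]
        dh = dz @ t[f"fc{i}"]

    dfused = dh * (cache["fused"] > 0)
    f1, f2 = config.f1, config.f2
    L3 = config.branch_len(KERNEL_SHORT)
    L5 = config.branch_len(KERNEL_MID)
    if config.fusion == "sum":
        dz3 = dfused.reshape(B, f1, L3)
        dz5 = dz3
    else:
        dz3 = dfused[:, : f1 * L3].reshape(B, f1, L3)
        dz5 = dfused[:, f1 * L3 :].reshape(B, f2, L5)

    grads["conv3"] = _branch_weight_grad(cache["X"], dz3, KERNEL_SHORT, config.padding3)
    grads["conv5"] = _branch_weight_grad(cache["X"], dz5, KERNEL_MID, config.padding5)
    return grads


def _branch_weight_grad(
    X: np.ndarray, dz: np.ndarray, kernel: int, padding: str
) -> np.ndarray:
    Xp = _pad_same(X, kernel) if padding == "same" else X
    windows = np.lib.stride_tricks.sliding_window_view(Xp, kernel, axis=1)
    return np.einsum("bfp,bpk->fk", dz, windows)


# ---------------------------------------------------------------------------
# loss and training

def softmax_cross_entropy(
    scores: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and d(loss)/d(scores)."""
    shifted = scores - scores.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    B = scores.shape[0]
    loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-300))
    dscores = probs.copy()
    dscores[np.arange(B), y] -= 1.0
    dscores /= B
    return float(loss), dscores


@dataclass(frozen=True)
class TrainingConfig:
    """Mini-batch SGD schedule: lr(e) = lr0 * decay^floor(e / decay_every).

    ``n_restarts > 1`` trains that many independently initialized runs
    (restart seeds derived from ``seed``) and keeps the one with the lowest
    final training loss — the standard guard against the occasional bad
    basin when fitting a tiny bias-free ReLU network with plain SGD.
    """

    batch_size: int = 32
    lr0: float = 0.01
    lr_decay: float = 0.95
    decay_every: int = 10
    epochs: int = 500
    train_fraction: float = 0.7
    seed: int = 0
    standardize: bool = True
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        return self.lr0 * self.lr_decay ** (epoch // self.decay_every)


@dataclass
class Standardizer:
    """Per-sensor z-scoring with statistics from the training split only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        return cls(mean=mean, std=std)

    @classmethod
    def identity(cls, n_features: int = N_SENSORS) -> "Standardizer":
        return cls(mean=np.zeros(n_features), std=np.ones(n_features))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def train(
    config: ModelConfig,
    data: InstanceTable,
    tc: TrainingConfig,
    X: np.ndarray | None = None,
) -> tuple[ParameterSet, TrainingHistory]:
    """Mini-batch SGD with the stepped learning-rate schedule.

    ``data`` supplies labels (and features unless a pre-standardized ``X``
    is passed).  Reproducible given ``tc.seed``: the same seed drives the
    weight initialization and the per-epoch shuffles.  With
    ``tc.n_restarts > 1`` the best of several independently seeded runs
    (by final training loss) is returned.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    y = data.y
    if y.min() < 0 or y.max() >= config.n_classes:
        raise ValueError(
            f"label out of range [0, {config.n_classes}): "
            f"saw {y.min()}..{y.max()}"
        )
    features = data.X if X is None else np.asarray(X, dtype=float)
    best: tuple[ParameterSet, TrainingHistory] | None = None
    for k in range(tc.n_restarts):
        restart_seed = tc.seed if k == 0 else [tc.seed, k]
        result = _sgd_run(config, features, y, tc, restart_seed)
        if best is None or result[1].loss[-1] < best[1].loss[-1]:
            best = result
    return best


def _sgd_run(
    config: ModelConfig,
    features: np.ndarray,
    y: np.ndarray,
    tc: TrainingConfig,
    seed,
) -> tuple[ParameterSet, TrainingHistory]:
    params = init_params(config, seed=seed)
    rng = np.random.default_rng([*np.atleast_1d(seed), 0x5D])
    n = len(y)
    history = TrainingHistory()

    for epoch in range(tc.epochs):
        lr = tc.learning_rate(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            scores, cache = forward_batch(
                config, params, features[idx], want_cache=True
            )
            loss, dscores = softmax_cross_entropy(scores, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}"
                )
            grads = backward_batch(config, params, cache, dscores)
            for name, g in grads.items():
                params.tensors[name] -= lr * g
            epoch_loss += loss * len(idx)
        history.loss.append(epoch_loss / n)
        history.lr.append(lr)
    return params, history
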