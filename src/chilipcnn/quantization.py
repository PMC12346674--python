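"""Fixed-point (Q-format) conversion and the quantized inference path.

Floating-point arithmetic is expensive on an FPGA; the deployed circuit
instead computes in two's-complement fixed point.  A real x is mapped to an
integer by

    X_fixed = floor(x * 2^b + 0.5)            (quantize, round-half-up)
    x       = X_fixed / 2^b                    (dequantize)

where ``b`` is the number of fractional bits.  The deployed configuration
is Q(16, 12): 16-bit words with 12 fractional bits, i.e. real range
[-8, 8 - 2^-12] at 2^-12 resolution.  Out-of-range values saturate to the
range endpoints (never wrap), matching hardware saturation logic.

The quantized forward path mirrors the float network layer by layer:
weights and inputs are stored in Q(W, b); each layer runs integer
multiply-accumulates in a wide (64-bit) accumulator and rescales the
result by b fractional bits with the +2^(b-1) rounding offset.  Two
inter-layer schemes are provided:

* ``"wide"`` (default): intermediate activations stay in a wide register
  between layers, as an HLS accumulator pipeline would keep them; only
  weights and network inputs are confined to the W-bit storage format.
* ``"narrow"``: every inter-layer value is saturated back to the W-bit
  range, modelling W-bit inter-layer buffers.  With a single shared
  format this clips any activation beyond +-2^(W-1-b) (+-8 at Q(16,12)),
  which on data with large responses can dominate the quantization error.

ReLU on integers is exact.  Accumulation order is fixed, so both paths are
bit-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import InstanceTable
from .model import (
    ConfigError,
    ModelConfig,
    ParameterSet,
    Standardizer,
    _pad_same,
    forward_batch,
)


@dataclass(frozen=True)
class FixedPointFormat:
    """Two's-complement Q(W, b): W total bits, b fractional bits."""

    word_length: int = 16
    frac_bits: int = 12

    def __post_init__(self) -> None:
        if not (0 < self.frac_bits < self.word_length):
            raise ValueError("need 0 < frac_bits < word_length")

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def int_min(self) -> int:
        return -(1 << (self.word_length - 1))

    @property
    def int_max(self) -> int:
        return (1 << (self.word_length - 1)) - 1

    @property
    def real_min(self) -> float:
        return self.int_min / self.scale

    @property
    def real_max(self) -> float:
        return self.int_max / self.scale


Q16_12 = FixedPointFormat(16, 12)


def float_to_fixed(x, fmt: FixedPointFormat = Q16_12) -> np.ndarray:
    """Quantize: floor(x * 2^b + 0.5), saturated to the integer range.

    Round-half-up applies to negatives too (floor(-1023.5) = -1024).
    Accepts scalars or arrays; returns int64.
    """
    scaled = np.floor(np.asarray(x, dtype=float) * fmt.scale + 0.5)
    return np.clip(scaled, fmt.int_min, fmt.int_max).astype(np.int64)


def fixed_to_float(x_fixed, fmt: FixedPointFormat = Q16_12) -> np.ndarray:
    """Dequantize: X_fixed / 2^b.  Rejects out-of-range integers."""
    xi = np.asarray(x_fixed, dtype=np.int64)
    if xi.size and (xi.min() < fmt.int_min or xi.max() > fmt.int_max):
        raise ValueError(
            f"integer outside Q({fmt.word_length},{fmt.frac_bits}) range"
        )
    return xi / fmt.scale


@dataclass
class QuantizedParameterSet:
    """Integer weight tensors mirroring a float ParameterSet."""

    tensors: dict[str, np.ndarray]
    fmt: FixedPointFormat
    n_saturated: int = 0

    @property
    def n_elements(self) -> int:
        return int(sum(t.size for t in self.tensors.values()))

    def to_flat_bytes(self) -> bytes:
        """Flat little-endian 16-bit integer serialization (W <= 16)."""
        if self.fmt.word_length > 16:
            raise ValueError("flat 16-bit serialization needs W <= 16")
        return b"".join(
            np.ascontiguousarray(t, dtype="<i2").tobytes()
            for t in self.tensors.values()
        )


def quantize_model(
    params: ParameterSet, fmt: FixedPointFormat = Q16_12
) -> QuantizedParameterSet:
    """Quantize every weight tensor; counts saturated weights."""
    tensors = {}
    n_sat = 0
    for name, t in params.tensors.items():
        if not np.all(np.isfinite(t)):
            raise ValueError(f"non-finite weight in tensor {name!r}")
        raw = np.floor(np.asarray(t, dtype=float) * fmt.scale + 0.5)
        n_sat += int(np.count_nonzero((raw < fmt.int_min) | (raw > fmt.int_max)))
        tensors[name] = np.clip(raw, fmt.int_min, fmt.int_max).astype(np.int64)
    return QuantizedParameterSet(tensors=tensors, fmt=fmt, n_saturated=n_sat)


def _requantize(
    acc: np.ndarray, fmt: FixedPointFormat, saturate: bool
) -> np.ndarray:
    """Rescale a wide product/accumulator back to b fractional bits.

    Products of two b-fraction integers carry 2b fractional bits; dividing
    by 2^b with the +2^(b-1) offset is the integer round-half-up of the
    real product.  With ``saturate`` the result is clipped to the W-bit
    storage range (narrow inter-layer buffers); otherwise it stays wide.
    """
    half = 1 << (fmt.frac_bits - 1)
    shifted = np.floor_divide(acc + half, fmt.scale)
    if saturate:
        return np.clip(shifted, fmt.int_min, fmt.int_max)
    return shifted


def forward_fixed_batch(
    config: ModelConfig,
    qparams: QuantizedParameterSet,
    X: np.ndarray,
    fmt: FixedPointFormat | None = None,
    intermediate: str = "wide",
) -> np.ndarray:
    """Fixed-point forward pass; returns dequantized (real) class scores.

    Inputs are quantized to ``fmt``; each layer runs integer MACs in int64
    (wide accumulator), rescales once per layer output, and applies
    integer ReLU.  ``intermediate`` selects the inter-layer scheme: "wide"
    keeps activations in the wide register, "narrow" saturates them to the
    W-bit storage range between layers.  Left-to-right accumulation via
    integer matmul keeps the result independent of threading or summation
    reassociation.
    """
    fmt = fmt or qparams.fmt
    if intermediate not in ("wide", "narrow"):
        raise ValueError("intermediate must be 'wide' or 'narrow'")
    saturate = intermediate == "narrow"
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != config.input_len:
        raise ConfigError(
            f"input length {X.shape[1]} != configured {config.input_len}"
        )
    t = qparams.tensors
    B = X.shape[0]
    xq = float_to_fixed(X, fmt)

    def branch(xq: np.ndarray, w: np.ndarray, padding: str) -> np.ndarray:
        k = w.shape[1]
        xp = _pad_same(xq, k) if padding == "same" else xq
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        acc = np.einsum("bpk,fk->bfp", win, w, dtype=np.int64)
        return _requantize(acc, fmt, saturate)

    z3 = branch(xq, t["conv3"], config.padding3)
    z5 = branch(xq, t["conv5"], config.padding5)
    if config.fusion == "sum":
        fused = z3 + z5
        if saturate:
            fused = np.clip(fused, fmt.int_min, fmt.int_max)
        fused = fused.reshape(B, -1)
    else:
        fused = np.concatenate([z3.reshape(B, -1), z5.reshape(B, -1)], axis=1)
    h = np.maximum(fused, 0)

    for i in range(len(config.fc_widths)):
        acc = h @ t[f"fc{i}"].T
        h = np.maximum(_requantize(acc, fmt, saturate), 0)

    r, c = config.reshape_shape
    M = h.reshape(B, r, c)
    kr, kc = config.stage2_kernel
    win = np.lib.stride_tricks.sliding_window_view(M, (kr, kc), axis=(1, 2))
    acc = np.einsum("bijuv,fuv->bfij", win, t["stage2"], dtype=np.int64)
    h2 = np.maximum(_requantize(acc, fmt, saturate), 0)
    flat = h2.reshape(B, -1)

    hp = _requantize(flat @ t["proj"].T, fmt, saturate)   # linear projection
    scores_q = _requantize(hp @ t["classifier"].T, fmt, saturate)
    return scores_q / fmt.scale


def forward_fixed(
    config: ModelConfig,
    qparams: QuantizedParameterSet,
    x: np.ndarray,
    fmt: FixedPointFormat | None = None,
    intermediate: str = "wide",
) -> np.ndarray:
    """Fixed-point scores for a single feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ConfigError("forward_fixed expects a single feature vector")
    return forward_fixed_batch(config, qparams, x[None, :], fmt, intermediate)[0]


def predict_fixed_batch(
    config: ModelConfig,
    qparams: QuantizedParameterSet,
    X: np.ndarray,
    fmt: FixedPointFormat | None = None,
    intermediate: str = "wide",
) -> np.ndarray:
    return np.argmax(
        forward_fixed_batch(config, qparams, X, fmt, intermediate), axis=1
    )


def accuracy_delta(
    config: ModelConfig,
    params: ParameterSet,
    qfmt: FixedPointFormat,
    test: InstanceTable,
    standardizer: Standardizer | None = None,
    intermediate: str = "wide",
) -> float:
    """Float-path accuracy minus fixed-path accuracy, in percentage points.

    Both paths consume the same (optionally standardized) features, as on
    the deployed system where preprocessing happens host-side.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    X = standardizer.transform(test.X) if standardizer is not None else test.X
    float_pred = np.argmax(forward_batch(config, params, X), axis=1)
    qparams = quantize_model(params, qfmt)
    fixed_pred = predict_fixed_batch(config, qparams, X, qfmt, intermediate)
    acc_float = float(np.mean(float_pred == test.y))
    acc_fixed = float(np.mean(fixed_pred == test.y))
    return 100.0 * (acc_float - acc_fixed)
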