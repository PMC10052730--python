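"""Compact 1-D convolutional network for tabular feature vectors.

Architecture (fixed stage order): valid 1-D cross-correlation with
``n_filters`` kernels of width ``kernel_size`` and per-filter bias ->
batch normalization (per-filter mean/variance plus learnable affine
scale/shift) -> ReLU -> non-overlapping max-pool of width 2 -> fully
connected hidden layer with ReLU -> linear output layer -> softmax over
``n_classes``.

All trainable parameters live in one flat vector (see
:func:`parameter_count` for the layout), because the network is trained
gradient-free: a population optimizer searches the parameter box
directly, with the full-training-set cross-entropy as the objective.
Batch-normalization statistics are therefore not running averages; for a
given parameter vector they are the deterministic full-batch statistics
of the conv outputs, and the statistics of the winning parameters are
frozen into the trained model for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkSpec",
    "parameter_count",
    "unflatten",
    "flatten",
    "forward",
    "cross_entropy_loss",
]

_BN_EPS = 1e-5
_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes of the tabular conv net."""

    n_filters: int = 4
    kernel_size: int = 3
    hidden_units: int = 8
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("invalid spec: n_filters must be >= 1")
        if self.kernel_size < 1:
            raise ValueError("invalid spec: kernel_size must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("invalid spec: hidden_units must be >= 1")
        if self.n_classes < 2:
            raise ValueError("invalid spec: n_classes must be >= 2")

    def conv_length(self, input_len: int) -> int:
        if self.kernel_size > input_len:
            raise ValueError(
                f"invalid spec: kernel_size {self.kernel_size} exceeds "
                f"input length {input_len}"
            )
        return input_len - self.kernel_size + 1

    def pooled_length(self, input_len: int) -> int:
        # width-2 non-overlapping pool, guarded so a length-1 conv output
        # (kernel spanning the whole input) passes through unpooled
        length = self.conv_length(input_len)
        return max(1, length // 2)


def parameter_count(spec: NetworkSpec, input_len: int) -> int:
    """Total trainable parameters for ``input_len`` features.

    Layout order: conv weights (F x J), conv biases (F), batch-norm
    scales (F), batch-norm shifts (F), hidden weights (H x F*pooled),
    hidden biases (H), output weights (C x H), output biases (C).
    """
    f, j = spec.n_filters, spec.kernel_size
    h, c = spec.hidden_units, spec.n_classes
    pooled = spec.pooled_length(input_len)
    return f * j + f + 2 * f + h * (f * pooled) + h + c * h + c


def unflatten(params: np.ndarray, spec: NetworkSpec, input_len: int) -> dict:
    """Split a flat parameter vector into named arrays."""
    params = np.asarray(params, dtype=float).ravel()
    expected = parameter_count(spec, input_len)
    if params.size != expected:
        raise ValueError(
            f"parameter vector has length {params.size}, expected {expected}"
        )
    f, j = spec.n_filters, spec.kernel_size
    h, c = spec.hidden_units, spec.n_classes
    pooled = spec.pooled_length(input_len)
    sizes = {
        "conv_w": (f, j),
        "conv_b": (f,),
        "bn_scale": (f,),
        "bn_shift": (f,),
        "hidden_w": (h, f * pooled),
        "hidden_b": (h,),
        "out_w": (c, h),
        "out_b": (c,),
    }
    out = {}
    offset = 0
    for name, shape in sizes.items():
        size = int(np.prod(shape))
        out[name] = params[offset : offset + size].reshape(shape)
        offset += size
    return out


def flatten(arrays: dict) -> np.ndarray:
    """Inverse of :func:`unflatten` (same fixed layout order)."""
    order = (
        "conv_w",
        "conv_b",
        "bn_scale",
        "bn_shift",
        "hidden_w",
        "hidden_b",
        "out_w",
        "out_b",
    )
    return np.concatenate([np.asarray(arrays[k], dtype=float).ravel() for k in order])


def _conv1d(X: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of each row of X with each filter.

    Returns an (n, length, F) activation tensor.
    """
    n, d = X.shape
    f, j = w.shape
    length = d - j + 1
    windows = np.lib.stride_tricks.sliding_window_view(X, j, axis=1)  # (n, length, j)
    return windows @ w.T + b  # (n, length, f)


def forward(
    params: np.ndarray,
    spec: NetworkSpec,
    X: np.ndarray,
    norm_stats: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Class probabilities for each row of ``X``.

    ``norm_stats`` is ``{"mean": (F,), "var": (F,)}`` for the batch-norm
    stage; when ``None`` the full-batch statistics of the conv outputs
    are computed (and returned, so a trainer can freeze them).  Returns
    ``(probs, norm_stats_used)`` with probs rows summing to 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = unflatten(params, spec, X.shape[1])

    conv = _conv1d(X, p["conv_w"], p["conv_b"])  # (n, L, F)
    if norm_stats is None:
        mean = conv.mean(axis=(0, 1))
        var = conv.var(axis=(0, 1))
        norm_stats = {"mean": mean, "var": var}
    normed = (conv - norm_stats["mean"]) / np.sqrt(norm_stats["var"] + _BN_EPS)
    act = np.maximum(normed * p["bn_scale"] + p["bn_shift"], 0.0)

    n, length, f = act.shape
    if length >= 2:
        pooled_len = length // 2
        pooled = act[:, : 2 * pooled_len].reshape(n, pooled_len, 2, f).max(axis=2)
    else:
        pooled = act
    flat = pooled.reshape(n, -1)  # (n, F * pooled_len), position-major

    hidden = np.maximum(flat @ p["hidden_w"].T + p["hidden_b"], 0.0)
    logits = hidden @ p["out_w"].T + p["out_b"]
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return probs, norm_stats


def cross_entropy_loss(
    params: np.ndarray,
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    norm_stats: dict | None = None,
) -> float:
    """Mean negative log-probability of the true classes.

    ``y`` holds integer class indices in ``[0, n_classes)``; predicted
    probabilities are floored at 1e-12 before the log.
    """
    y = np.asarray(y)
    if y.ndim != 1 or y.size != np.atleast_2d(X).shape[0]:
        raise ValueError("labels must be a vector matching the rows of X")
    if y.min() < 0 or y.max() >= spec.n_classes:
        raise ValueError("label outside [0, n_classes)")
    probs, _ = forward(params, spec, X, norm_stats)
    p_true = np.maximum(probs[np.arange(y.size), y], _PROB_FLOOR)
    return float(-np.mean(np.log(p_true)))
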