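"""Pooling, pair aggregation, and the two classification heads.

Per-residue embeddings are mean-pooled along sequence length into a single
d-dimensional vector; for protein-pair tasks the two pooled embeddings are
averaged. Two heads are provided:

* ``paper_head`` — dropout -> dense(d -> 128) -> tanh -> dropout ->
  dense(128 -> C), the transformer-style sequence-classification head.
  Binary tasks use a single logit (C = 1) with a sigmoid.
* ``mlp_baseline`` — dense(d -> 64) -> ReLU -> dense(64 -> 64) -> ReLU ->
  dense(64 -> C), the frozen-embedding baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .plm_core import ConfigurationError, EmbeddingMatrix, InputError

__all__ = [
    "PooledEmbedding",
    "HeadSpec",
    "ClassificationHead",
    "build_head",
    "mean_pool",
    "pool_batch",
    "first_token_pool",
    "pair_aggregate",
    "head_forward",
    "head_param_count",
]


@dataclass
class PooledEmbedding:
    """A fixed-length (d-dim) protein embedding and the length pooled over."""

    values: np.ndarray
    source_length: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.source_length < 1:
            raise InputError("source_length must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise InputError("pooled embedding contains non-finite values")


def _default_hidden(variant: str) -> tuple:
    return (128,) if variant == "paper_head" else (64, 64)


@dataclass(frozen=True)
class HeadSpec:
    """Shape and variant of a classification head."""

    variant: str = "paper_head"
    input_dim: int = 1280
    n_outputs: int = 1
    hidden: tuple | None = None
    dropout_p: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("paper_head", "mlp_baseline"):
            raise ConfigurationError("variant must be 'paper_head' or 'mlp_baseline'")
        hidden = tuple(self.hidden) if self.hidden is not None else _default_hidden(self.variant)
        if any(w < 1 for w in hidden) or self.input_dim < 1 or self.n_outputs < 1:
            raise ConfigurationError("all head widths must be positive")
        object.__setattr__(self, "hidden", hidden)

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = (self.input_dim, *self.hidden, self.n_outputs)
        return list(zip(dims[:-1], dims[1:]))


def head_param_count(spec: HeadSpec) -> int:
    """Dense-layer parameter total: sum of (in*out + out) over layers."""
    return sum(i * o + o for i, o in spec.layer_dims)


class ClassificationHead:
    """Trainable dense head mapping a pooled embedding to task logits."""

    def __init__(self, spec: HeadSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, Tensor] = {}
        for li, (fan_in, fan_out) in enumerate(spec.layer_dims):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.params[f"W{li}"] = Tensor(
                rng.uniform(-bound, bound, size=(fan_out, fan_in)), requires_grad=True
            )
            self.params[f"b{li}"] = Tensor(np.zeros(fan_out), requires_grad=True)

    def forward(self, e: Tensor | np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x = ag.as_tensor(e)
        if x.shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {x.shape[-1]} != head input_dim {self.spec.input_dim}"
            )
        n_layers = len(self.spec.layer_dims)
        if self.spec.variant == "paper_head":
            x = ag.dropout(x, self.spec.dropout_p, rng, train)
            for li in range(n_layers):
                x = x @ self.params[f"W{li}"].transpose() + self.params[f"b{li}"]
                if li < n_layers - 1:
                    x = x.tanh()
                    x = ag.dropout(x, self.spec.dropout_p, rng, train)
        else:
            for li in range(n_layers):
                x = x @ self.params[f"W{li}"].transpose() + self.params[f"b{li}"]
                if li < n_layers - 1:
                    x = ag.relu(x)
        return x

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for n, arr in state.items():
            self.params[n].data = arr.copy()


def build_head(spec: HeadSpec) -> ClassificationHead:
    return ClassificationHead(spec)


def head_forward(head: ClassificationHead, e, train: bool = False, rng=None) -> np.ndarray:
    """Inference-mode logits as a plain ndarray."""
    return head.forward(e, train=train, rng=rng).data


def mean_pool(E: EmbeddingMatrix | np.ndarray, mask: np.ndarray | None = None) -> PooledEmbedding:
    """Average per-residue embeddings (d x n columns) over valid positions."""
    values = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        values = values[:, mask]
    if values.shape[1] == 0:
        raise InputError("mean_pool requires at least one valid position")
    return PooledEmbedding(values=values.mean(axis=1), source_length=values.shape[1])


def first_token_pool(E: EmbeddingMatrix | np.ndarray) -> PooledEmbedding:
    """Alternative pooling: take the first residue position's embedding."""
    values = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=np.float64)
    if values.shape[1] == 0:
        raise InputError("empty embedding matrix")
    return PooledEmbedding(values=values[:, 0], source_length=values.shape[1])


def pool_batch(x: Tensor, mask: np.ndarray) -> Tensor:
    """Differentiable masked mean over sequence length: (B, n, d) -> (B, d)."""
    mask = np.asarray(mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    if np.any(counts < 1):
        raise InputError("every sequence in the batch needs a valid position")
    summed = (x * mask[:, :, None]).sum(axis=1)
    return summed * (1.0 / counts)[:, None]


def pair_aggregate(ea, eb):
    """Order-invariant pair embedding: the elementwise average (ea + eb) / 2."""
    a = ea.values if isinstance(ea, PooledEmbedding) else ea
    b = eb.values if isinstance(eb, PooledEmbedding) else eb
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        if a.shape != b.shape:
            raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
        return (a + b) * 0.5
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0
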