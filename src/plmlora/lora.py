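"""Low-rank adaptation (LoRA) of the transformer attention projections.

A frozen projection ``h = Wx`` is augmented with a trainable low-rank
bypass, ``h = Wx + (alpha/r) * B A x`` with ``A`` an r x k Gaussian-initialized
matrix and ``B`` a d x r zero matrix, so the first forward pass equals the
unadapted model. Adapters are injected into the last ``n_adapted_layers``
blocks, targeting any subset of the Q/K/V projections. This module also
owns exact trainable-parameter accounting for the three tuning modes
(head-only, PEFT, full fine-tuning of the last n blocks).
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .plm_core import (
    ArchConfig,
    ConfigurationError,
    TransformerEncoder,
    per_block_params,
)
from . import heads as _heads

__all__ = [
    "TARGET_NAMES",
    "LoraConfig",
    "AdapterPair",
    "AdaptedModel",
    "TuningMode",
    "RECOMMENDED_LORA",
    "inject_adapters",
    "lora_forward",
    "merge_adapters",
    "adapter_param_count",
    "count_trainable",
    "param_breakdown",
    "save_adapters",
    "load_adapters",
    "estimate_memory_bytes",
]

TARGET_NAMES = ("Q", "K", "V")


@dataclass(frozen=True)
class LoraConfig:
    """Adapter placement and shape.

    Defaults follow the recommended protein-language setting: adapt the key
    and value matrices with rank >= 4, alpha = 32, adapter dropout 0.1.
    """

    target_matrices: tuple = ("K", "V")
    rank: int = 8
    alpha: float = 32.0
    dropout_p: float = 0.1
    n_adapted_layers: int = 5
    seed: int = 0

    def __post_init__(self):
        targets = tuple(dict.fromkeys(t.upper() for t in self.target_matrices))
        object.__setattr__(self, "target_matrices", targets)
        if not targets:
            raise ConfigurationError("target_matrices must be a nonempty subset of {Q, K, V}")
        bad = [t for t in targets if t not in TARGET_NAMES]
        if bad:
            raise ConfigurationError(f"unknown target matrices: {bad}; valid: {TARGET_NAMES}")
        if not isinstance(self.rank, (int, np.integer)) or self.rank < 1:
            raise ConfigurationError(f"rank must be a positive integer, got {self.rank!r}")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.n_adapted_layers < 1:
            raise ConfigurationError("n_adapted_layers must be >= 1")

    @property
    def scale(self) -> float:
        return self.alpha / self.rank


#: Recommended preset: rank >= 4 adapters on the key and value matrices.
RECOMMENDED_LORA = LoraConfig(target_matrices=("K", "V"), rank=8, alpha=32.0)


@dataclass
class AdapterPair:
    """One low-rank bypass: A (r x k), B (d x r), applied as scale * B A x."""

    A: Tensor
    B: Tensor
    scale: float
    dropout_p: float = 0.0

    @property
    def rank(self) -> int:
        return self.A.data.shape[0]

    def delta(self) -> np.ndarray:
        """The merged weight increment scale * B @ A (rank <= r)."""
        return self.scale * (self.B.data @ self.A.data)


@dataclass(frozen=True)
class TuningMode:
    """Which parameters receive gradients: 'mlp' (head only), 'peft', or 'ft'."""

    kind: str
    n_layers: int = 0
    lora: LoraConfig | None = None

    def __post_init__(self):
        if self.kind not in ("mlp", "peft", "ft"):
            raise ConfigurationError("kind must be one of 'mlp', 'peft', 'ft'")
        if self.kind == "mlp" and self.n_layers != 0:
            raise ConfigurationError("mlp mode trains no transformer layers")
        if self.kind == "peft" and self.lora is None:
            raise ConfigurationError("peft mode requires a LoraConfig")
        if self.kind == "ft" and self.n_layers < 1:
            raise ConfigurationError("ft mode requires n_layers >= 1")


class AdaptedModel:
    """A frozen base encoder plus trainable adapter pairs.

    ``adapters`` maps (layer index, projection letter) -> AdapterPair. The
    base model's parameters are never updated; only A and B matrices (and
    an externally managed head) are trainable.
    """

    def __init__(self, base: TransformerEncoder, cfg: LoraConfig):
        self.base = base
        self.cfg = cfg
        self.adapters: dict[tuple[int, str], AdapterPair] = {}
        d = base.config.d_model
        rng = np.random.default_rng(cfg.seed)
        first = base.config.n_layers - cfg.n_adapted_layers
        for layer in range(first, base.config.n_layers):
            for t in cfg.target_matrices:
                A = Tensor(rng.normal(0.0, 0.02, size=(cfg.rank, d)), requires_grad=True)
                B = Tensor(np.zeros((d, cfg.rank)), requires_grad=True)
                self.adapters[(layer, t.lower())] = AdapterPair(
                    A=A, B=B, scale=cfg.scale, dropout_p=cfg.dropout_p
                )

    @property
    def config(self) -> ArchConfig:
        return self.base.config

    def forward(self, ids, mask, train: bool = False, rng=None, collect_attention: bool = False):
        return self.base.forward(ids, mask, adapters=self.adapters,
                                 train=train, rng=rng, collect_attention=collect_attention)

    def trainable_params(self) -> dict[str, Tensor]:
        out = {}
        for (layer, t), pair in self.adapters.items():
            out[f"adapter.{layer}.{t}.A"] = pair.A
            out[f"adapter.{layer}.{t}.B"] = pair.B
        return out

    def n_new_params(self) -> int:
        return sum(p.data.size for p in self.trainable_params().values())


def inject_adapters(model: TransformerEncoder, cfg: LoraConfig) -> AdaptedModel:
    """Attach zero-initialized low-rank adapters to the last n blocks."""
    if cfg.n_adapted_layers > model.config.n_layers:
        raise ConfigurationError(
            f"cannot adapt {cfg.n_adapted_layers} layers of a "
            f"{model.config.n_layers}-layer model"
        )
    return AdaptedModel(model, cfg)


def lora_forward(W: np.ndarray, pair: AdapterPair, x: np.ndarray,
                 train: bool = False, rng: np.random.Generator | None = None,
                 dropout_p: float | None = None) -> np.ndarray:
    """Adapted projection of a single input: Wx + scale * B (A dropout(x)).

    Plain-ndarray reference form of the bypass the encoder applies inside
    its attention projections; dropout on the adapter input only applies in
    training mode.
    """
    W = np.asarray(W, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if W.shape[1] != x.shape[0] or pair.A.data.shape[1] != x.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape}, A {pair.A.data.shape}, x {x.shape}")
    p = pair.dropout_p if dropout_p is None else dropout_p
    xin = x
    if train and p > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        xin = x * ((rng.random(x.shape) >= p) / (1.0 - p))
    return W @ x + pair.scale * (pair.B.data @ (pair.A.data @ xin))


def merge_adapters(model) -> TransformerEncoder:
    """Fold adapters into the base weights: W' = W + (alpha/r) B A."""
    if not isinstance(model, AdaptedModel) or not model.adapters:
        warnings.warn("model carries no adapters; returning an unmerged copy")
        base = model.base if isinstance(model, AdaptedModel) else model
        merged = TransformerEncoder(base.config)
        merged.load_weights({n: t.data.copy() for n, t in base.params.items()})
        return merged
    merged = TransformerEncoder(model.base.config)
    merged.load_weights({n: t.data.copy() for n, t in model.base.params.items()})
    for (layer, t), pair in model.adapters.items():
        name = f"blocks.{layer}.attn.{t}.W"
        merged.params[name].data = merged.params[name].data + pair.delta()
    return merged


# ----------------------------------------------------------------------
# Parameter accounting
# ----------------------------------------------------------------------

def adapter_param_count(cfg: LoraConfig, d: int, k: int | None = None) -> int:
    """New trainable parameters: n_layers * |targets| * r * (d + k)."""
    k = d if k is None else k
    return cfg.n_adapted_layers * len(cfg.target_matrices) * cfg.rank * (d + k)


def count_trainable(arch: ArchConfig, mode: TuningMode, head_spec) -> int:
    """Exact count of parameters receiving gradient updates.

    head-only: head; PEFT: adapters + head; FT: last-n full blocks + head.
    The token embedding table and the model-final LayerNorm are excluded
    from last-n-layers counts.
    """
    head = _heads.head_param_count(head_spec)
    if mode.kind == "mlp":
        return head
    if mode.kind == "peft":
        if mode.lora.n_adapted_layers > arch.n_layers:
            raise ConfigurationError("more adapted layers than model layers")
        return adapter_param_count(mode.lora, arch.d_model) + head
    if mode.n_layers > arch.n_layers:
        raise ConfigurationError("more fine-tuned layers than model layers")
    return mode.n_layers * per_block_params(arch.d_model, arch.ffn_dim) + head


def param_breakdown(arch: ArchConfig, mode: TuningMode, head_spec) -> dict[str, int]:
    """Per-component breakdown of the trainable-parameter total."""
    head = _heads.head_param_count(head_spec)
    out = {"head": head}
    if mode.kind == "peft":
        per_adapter = mode.lora.rank * 2 * arch.d_model
        out["per_adapter"] = per_adapter
        out["n_adapters"] = mode.lora.n_adapted_layers * len(mode.lora.target_matrices)
        out["adapters"] = adapter_param_count(mode.lora, arch.d_model)
    elif mode.kind == "ft":
        out["per_block"] = per_block_params(arch.d_model, arch.ffn_dim)
        out["n_blocks"] = mode.n_layers
        out["blocks"] = mode.n_layers * out["per_block"]
    out["total"] = count_trainable(arch, mode, head_spec)
    return out


def estimate_memory_bytes(arch: ArchConfig, mode: TuningMode, head_spec,
                          batch: int = 4, seq_len: int = 1024,
                          bytes_per_value: int = 4) -> dict[str, int]:
    """Analytic training-memory estimate (weights, optimizer state, activations).

    Adam keeps two moments per trainable parameter; activations are
    estimated per block as the residual stream, Q/K/V/context, attention
    logits, and the FFN inner width. A coarse planning tool, not a
    measurement.
    """
    d, f, h = arch.d_model, arch.ffn_dim, arch.n_heads
    total_weights = (arch.vocab_size * d + arch.n_layers * per_block_params(d, f) + 2 * d)
    trainable = count_trainable(arch, mode, head_spec)
    per_block_act = batch * seq_len * (4 * d + f + 2 * d) + batch * h * seq_len * seq_len
    n_stored = arch.n_layers if mode.kind != "mlp" else 1
    return {
        "weights": total_weights * bytes_per_value,
        "gradients": trainable * bytes_per_value,
        "adam_state": 2 * trainable * bytes_per_value,
        "activations": n_stored * per_block_act * bytes_per_value,
    }


# ----------------------------------------------------------------------
# Adapter-only checkpointing (base + delta distribution)
# ----------------------------------------------------------------------

def save_adapters(model: AdaptedModel, path) -> None:
    """Export adapters (A, B, scale, placement) as a portable zip archive."""
    path = Path(path)
    meta = {
        "config": {
            "target_matrices": list(model.cfg.target_matrices),
            "rank": model.cfg.rank,
            "alpha": model.cfg.alpha,
            "dropout_p": model.cfg.dropout_p,
            "n_adapted_layers": model.cfg.n_adapted_layers,
            "seed": model.cfg.seed,
        },
        "placements": [[layer, t] for (layer, t) in model.adapters],
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for (layer, t), pair in model.adapters.items():
            with zf.open(f"{layer}.{t}.A.npy", "w") as fh:
                np.save(fh, pair.A.data)
            with zf.open(f"{layer}.{t}.B.npy", "w") as fh:
                np.save(fh, pair.B.data)


def load_adapters(base: TransformerEncoder, path) -> AdaptedModel:
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        cfg = LoraConfig(**{**meta["config"],
                            "target_matrices": tuple(meta["config"]["target_matrices"])})
        model = AdaptedModel(base, cfg)
        for layer, t in meta["placements"]:
            pair = model.adapters[(layer, t)]
            with zf.open(f"{layer}.{t}.A.npy") as fh:
                pair.A.data = np.load(fh)
            with zf.open(f"{layer}.{t}.B.npy") as fh:
                pair.B.data = np.load(fh)
    return model
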