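"""A minimal protein-language-model-style transformer encoder.

The encoder is a pre-layer-norm transformer over the 20-letter amino-acid
alphabet (plus pad and mask tokens) with rotary position mixing on the
query/key projections, biased Q/K/V/O projections, a biased two-layer GELU
feed-forward block, and two LayerNorms per block plus a final LayerNorm.
Initialization is fully deterministic under ``ArchConfig.seed``, and the
parameter layout is the reference for all trainable-parameter accounting:

    per block: 4(d^2 + d) + (d*f + f) + (f*d + d) + 4d

with embedding dimension ``d`` and feed-forward width ``f``. The token
embedding table and the final LayerNorm are deliberately outside the
per-block count (they are never unfrozen in "last-n-layers" tuning).

Weights here are randomly initialized stand-ins for a pretrained protein
language model; ``load_weights`` exists as a hook for external weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "AMINO_ACIDS",
    "PAD_TOKEN",
    "MASK_TOKEN",
    "ConfigurationError",
    "InputError",
    "ArchConfig",
    "TokenSequence",
    "EmbeddingMatrix",
    "AttentionMap",
    "TransformerEncoder",
    "build_model",
    "forward_embed",
    "attention_maps",
    "per_block_params",
    "save_model",
    "load_model",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_TOKEN = len(AMINO_ACIDS)        # 20
MASK_TOKEN = len(AMINO_ACIDS) + 1   # 21; also used for ambiguous residue 'X'
_AA_TO_ID = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ConfigurationError(ValueError):
    """Invalid architecture or adapter configuration."""


class InputError(ValueError):
    """Invalid model input (bad token, empty sequence, too long)."""


@dataclass(frozen=True)
class ArchConfig:
    """Dimensions and layout of the reference transformer.

    Defaults mirror a 650M-parameter encoder geometry (d=1280, 33 blocks,
    20 heads, FFN width 4d) so that parameter accounting reproduces the
    published trainable-parameter totals; tests use much smaller values.
    """

    d_model: int = 1280
    n_layers: int = 33
    n_heads: int = 20
    ffn_dim: int = 5120
    vocab_size: int = 22
    max_len: int = 1024
    seed: int = 0
    positional: str = "rotary"  # "rotary" | "none"

    def __post_init__(self):
        for name in ("d_model", "n_layers", "n_heads", "ffn_dim", "vocab_size", "max_len"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.ffn_dim < self.d_model:
            raise ConfigurationError("ffn_dim must be at least d_model")
        if self.positional not in ("rotary", "none"):
            raise ConfigurationError("positional must be 'rotary' or 'none'")
        if self.positional == "rotary" and (self.d_model // self.n_heads) % 2 != 0:
            raise ConfigurationError("rotary positions require an even head dimension")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ArchConfig":
        return cls(**json.loads(s))


@dataclass
class TokenSequence:
    """Integer-encoded amino-acid sequence with per-position validity flags."""

    ids: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ids.shape != self.mask.shape or self.ids.ndim != 1:
            raise InputError("ids and mask must be 1-D arrays of equal length")
        if np.any(self.ids[~self.mask] != PAD_TOKEN):
            raise InputError("masked-out positions must carry the pad token")

    @classmethod
    def from_string(cls, seq: str) -> "TokenSequence":
        ids = []
        for i, ch in enumerate(seq.upper()):
            if ch in _AA_TO_ID:
                ids.append(_AA_TO_ID[ch])
            elif ch == "X":
                ids.append(MASK_TOKEN)
            else:
                raise InputError(f"invalid residue {ch!r} at position {i}")
        if not ids:
            raise InputError("empty sequence")
        ids = np.asarray(ids, dtype=np.int64)
        return cls(ids=ids, mask=np.ones(len(ids), dtype=bool))

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def padded(self, n_pad: int) -> "TokenSequence":
        """Return a copy with `n_pad` pad positions appended."""
        ids = np.concatenate([self.ids, np.full(n_pad, PAD_TOKEN, dtype=np.int64)])
        mask = np.concatenate([self.mask, np.zeros(n_pad, dtype=bool)])
        return TokenSequence(ids=ids, mask=mask)


@dataclass
class EmbeddingMatrix:
    """d_model x n_valid per-residue embeddings for one sequence."""

    values: np.ndarray
    n_valid: int

    def __post_init__(self):
        if self.values.shape[1] != self.n_valid:
            raise ValueError("column count must equal the number of valid positions")


@dataclass
class AttentionMap:
    """Row-stochastic attention, indexed (layer, head, query i, key j)."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 4 or self.values.shape[2] != self.values.shape[3]:
            raise ValueError("attention maps must be (layer, head, n, n)")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_heads(self) -> int:
        return self.values.shape[1]


def per_block_params(d: int, f: int) -> int:
    """Trainable parameters in one transformer block: 4(d²+d)+(df+f)+(fd+d)+4d."""
    return 4 * (d * d + d) + (d * f + f) + (f * d + d) + 4 * d


def _trunc_normal(rng: np.random.Generator, shape, sigma: float = 0.02) -> np.ndarray:
    """Normal(0, sigma²) resampled into ±2 sigma."""
    x = rng.normal(0.0, sigma, size=shape)
    bad = np.abs(x) > 2 * sigma
    while np.any(bad):
        x[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        bad = np.abs(x) > 2 * sigma
    return x


class TransformerEncoder:
    """Pre-LN transformer encoder with per-layer attention capture.

    Parameters live in ``self.params`` (name -> Tensor). Weight matrices use
    the (out, in) convention, applied as ``x @ W.T + b``.
    """

    def __init__(self, config: ArchConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params()
        if config.positional == "rotary":
            self._rot_cos, self._rot_sin = self._rotary_tables(config.max_len, config.head_dim)

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d, f = cfg.d_model, cfg.ffn_dim

        def p(name, arr):
            self.params[name] = Tensor(arr, requires_grad=True)

        p("embed.W", _trunc_normal(rng, (cfg.vocab_size, d)))
        for i in range(cfg.n_layers):
            pre = f"blocks.{i}."
            for proj in ("q", "k", "v", "o"):
                p(pre + f"attn.{proj}.W", _trunc_normal(rng, (d, d)))
                p(pre + f"attn.{proj}.b", np.zeros(d))
            p(pre + "ln1.g", np.ones(d))
            p(pre + "ln1.b", np.zeros(d))
            p(pre + "ln2.g", np.ones(d))
            p(pre + "ln2.b", np.zeros(d))
            p(pre + "ffn.W1", _trunc_normal(rng, (f, d)))
            p(pre + "ffn.b1", np.zeros(f))
            p(pre + "ffn.W2", _trunc_normal(rng, (d, f)))
            p(pre + "ffn.b2", np.zeros(d))
        p("final_ln.g", np.ones(d))
        p("final_ln.b", np.zeros(d))

    @staticmethod
    def _rotary_tables(max_len: int, head_dim: int):
        half = head_dim // 2
        inv_freq = 1.0 / (10000.0 ** (np.arange(half) / half))
        angles = np.outer(np.arange(max_len), inv_freq)
        return np.cos(angles), np.sin(angles)

    # ------------------------------------------------------------------
    def block_param_names(self, layer: int) -> list[str]:
        pre = f"blocks.{layer}."
        return [n for n in self.params if n.startswith(pre)]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def set_trainable(self, names) -> None:
        self.trainable_names = set(names)

    def _project(self, x: Tensor, which: str, layer: int, adapters=None,
                 train: bool = False, rng=None) -> Tensor:
        W = self.params[f"blocks.{layer}.attn.{which}.W"]
        b = self.params[f"blocks.{layer}.attn.{which}.b"]
        out = x @ W.transpose() + b
        if adapters is not None and (layer, which) in adapters:
            pair = adapters[(layer, which)]
            xin = ag.dropout(x, pair.dropout_p, rng, train)
            out = out + (xin @ pair.A.transpose()) @ pair.B.transpose() * pair.scale
        return out

    def forward(self, ids: np.ndarray, mask: np.ndarray, adapters=None,
                train: bool = False, rng: np.random.Generator | None = None,
                collect_attention: bool = False):
        """Run the encoder on a (B, n) batch of token ids.

        Returns (embeddings Tensor (B, n, d), list of per-layer attention
        arrays (B, heads, n, n) when requested).
        """
        cfg = self.config
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        mask = np.atleast_2d(np.asarray(mask, dtype=bool))
        B, n = ids.shape
        if n > cfg.max_len:
            raise InputError(f"sequence length {n} exceeds max_len {cfg.max_len}")
        if ids.min() < 0 or ids.max() >= cfg.vocab_size:
            raise InputError("token id outside the vocabulary")

        H, hd = cfg.n_heads, cfg.head_dim
        x = ag.embedding(self.params["embed.W"], ids)
        # keys at invalid positions are excluded from every softmax row
        key_bias = np.where(mask, 0.0, -1e9)[:, None, None, :]
        attn_out: list[np.ndarray] = []

        for layer in range(cfg.n_layers):
            pre = f"blocks.{layer}."
            h = ag.layer_norm(x, self.params[pre + "ln1.g"], self.params[pre + "ln1.b"])
            q = self._project(h, "q", layer, adapters, train, rng)
            k = self._project(h, "k", layer, adapters, train, rng)
            v = self._project(h, "v", layer, adapters, train, rng)
            # (B, n, d) -> (B, H, n, hd)
            q = q.reshape(B, n, H, hd).swapaxes(1, 2)
            k = k.reshape(B, n, H, hd).swapaxes(1, 2)
            v = v.reshape(B, n, H, hd).swapaxes(1, 2)
            if cfg.positional == "rotary":
                cos, sin = self._rot_cos[:n], self._rot_sin[:n]
                q = ag.rotary(q, cos, sin)
                k = ag.rotary(k, cos, sin)
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd)) + key_bias
            attn = ag.softmax(scores, axis=-1)
            if collect_attention:
                attn_out.append(attn.data.copy())
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, n, cfg.d_model)
            Wo = self.params[pre + "attn.o.W"]
            x = x + (ctx @ Wo.transpose() + self.params[pre + "attn.o.b"])
            h2 = ag.layer_norm(x, self.params[pre + "ln2.g"], self.params[pre + "ln2.b"])
            W1, b1 = self.params[pre + "ffn.W1"], self.params[pre + "ffn.b1"]
            W2, b2 = self.params[pre + "ffn.W2"], self.params[pre + "ffn.b2"]
            x = x + (ag.gelu(h2 @ W1.transpose() + b1) @ W2.transpose() + b2)

        x = ag.layer_norm(x, self.params["final_ln.g"], self.params["final_ln.b"])
        return x, attn_out

    def load_weights(self, arrays: dict[str, np.ndarray]) -> None:
        """Hook for loading externally trained weights by parameter name."""
        for name, arr in arrays.items():
            if name not in self.params:
                raise ConfigurationError(f"unknown parameter {name!r}")
            if self.params[name].data.shape != arr.shape:
                raise ConfigurationError(f"shape mismatch for {name!r}")
            self.params[name].data = np.asarray(arr, dtype=np.float64)


def build_model(config: ArchConfig) -> TransformerEncoder:
    """Build a seeded reference encoder; identical config -> identical weights."""
    return TransformerEncoder(config)


def forward_embed(model, seq: TokenSequence) -> EmbeddingMatrix:
    """Per-residue embeddings (d x n_valid) in inference mode."""
    base, adapters = _unwrap(model)
    out, _ = base.forward(seq.ids[None, :], seq.mask[None, :], adapters=adapters)
    values = out.data[0][seq.mask].T  # (d, n_valid)
    return EmbeddingMatrix(values=values, n_valid=seq.n_valid)


def attention_maps(model, seq: TokenSequence) -> AttentionMap:
    """Row-stochastic attention for every layer and head, over valid positions."""
    base, adapters = _unwrap(model)
    _, attns = base.forward(seq.ids[None, :], seq.mask[None, :],
                            adapters=adapters, collect_attention=True)
    valid = seq.mask
    maps = np.stack([a[0][:, valid][:, :, valid] for a in attns])  # (L, H, nv, nv)
    return AttentionMap(values=maps)


def _unwrap(model):
    """Accept either a plain encoder or a LoRA-adapted wrapper."""
    adapters = getattr(model, "adapters", None)
    base = getattr(model, "base", model)
    return base, adapters


def save_model(model: TransformerEncoder, path) -> None:
    """Serialize config + weights to an .npz checkpoint."""
    path = Path(path)
    arrays = {name: t.data for name, t in model.params.items()}
    np.savez(path, __config__=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> TransformerEncoder:
    with np.load(Path(path)) as npz:
        config = ArchConfig.from_json(bytes(npz["__config__"]).decode())
        model = TransformerEncoder(config)
        model.load_weights({n: npz[n] for n in npz.files if n != "__config__"})
    return model
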