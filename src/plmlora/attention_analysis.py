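"""Attention-locality analysis: the diagonal (weighted Pearson) correlation.

Treating a head-averaged attention map's mass at coordinates (i, j) as a
sample weight over the query index i and key index j, the diagonal
correlation r_xy is the weighted Pearson correlation between i and j:
1 for strictly diagonal (local) attention, 0 for diffuse attention, and -1
for mass on a strictly decreasing line. Comparing a base model against its
adapter-tuned counterpart over a set of proteins yields per-layer
distributions of delta = r_xy(base) - r_xy(adapted); a positive delta means
attention became more global after adaptation. Per-layer significance of
median delta != 0 uses the two-sided paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plm_core import AttentionMap, TokenSequence, attention_maps

__all__ = [
    "DiagonalCorrelation",
    "DeltaResult",
    "head_average",
    "diagonal_correlation",
    "model_diagonal_correlations",
    "delta_correlation",
    "layer_significance",
]


@dataclass
class DiagonalCorrelation:
    """Per-layer r_xy for one protein under one model."""

    per_layer: np.ndarray
    protein_id: str = ""
    model_tag: str = "base"


@dataclass
class DeltaResult:
    """Per-layer distributions of delta r_xy = r(base) - r(adapted) over proteins."""

    deltas: np.ndarray  # (n_proteins, n_layers)
    r_base: np.ndarray
    r_adapted: np.ndarray
    p_values: np.ndarray = field(default=None)
    protein_ids: list = field(default_factory=list)
    adapted_layers: list = field(default_factory=list)

    @property
    def n_proteins(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_layers(self) -> int:
        return self.deltas.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi, pid in enumerate(self.protein_ids or range(self.n_proteins)):
            for layer in range(self.n_layers):
                rows.append({
                    "protein": pid, "layer": layer,
                    "r_base": self.r_base[pi, layer],
                    "r_adapted": self.r_adapted[pi, layer],
                    "delta": self.deltas[pi, layer],
                })
        return pd.DataFrame(rows)


def head_average(maps: AttentionMap, layer: int) -> np.ndarray:
    """Elementwise mean over heads for one layer; rows remain stochastic."""
    if not (0 <= layer < maps.n_layers):
        raise IndexError(f"layer {layer} out of range [0, {maps.n_layers})")
    return maps.values[layer].mean(axis=0)


def diagonal_correlation(M: np.ndarray) -> float:
    """Weighted Pearson correlation of row and column indices under weights M.

    With w_ij = M_ij / sum(M), mu_i = sum_ij w_ij * i, mu_j = sum_ij w_ij * j:

        r = sum w_ij (i - mu_i)(j - mu_j)
            / sqrt(sum w_ij (i - mu_i)^2 * sum w_ij (j - mu_j)^2)

    Invariant to positive rescaling of M and to transposition. Returns NaN
    (flagged missing) when either coordinate has zero variance under the
    weights, e.g. all mass in a single row or cell.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be a square matrix")
    n = M.shape[0]
    if n < 2:
        raise ValueError("diagonal correlation needs n >= 2")
    if np.any(M < 0):
        raise ValueError("M must be nonnegative")
    total = M.sum()
    if total <= 0:
        raise ValueError("M must have positive total mass")
    w = M / total
    i = np.arange(n, dtype=np.float64)
    wi = w.sum(axis=1)  # marginal weight of row index
    wj = w.sum(axis=0)
    mu_i = float(wi @ i)
    mu_j = float(wj @ i)
    var_i = float(wi @ (i - mu_i) ** 2)
    var_j = float(wj @ (i - mu_j) ** 2)
    if var_i <= 0 or var_j <= 0:
        return float("nan")
    cov = float((i - mu_i) @ w @ (i - mu_j))
    return cov / np.sqrt(var_i * var_j)


def model_diagonal_correlations(model, seq: TokenSequence,
                                protein_id: str = "", tag: str = "base") -> DiagonalCorrelation:
    """r_xy for every layer of one model on one sequence (heads averaged)."""
    maps = attention_maps(model, seq)
    vals = np.array([
        diagonal_correlation(head_average(maps, layer)) for layer in range(maps.n_layers)
    ])
    return DiagonalCorrelation(per_layer=vals, protein_id=protein_id, model_tag=tag)


def delta_correlation(base_model, adapted_model, seqs: dict[str, TokenSequence],
                      significance: str = "wilcoxon") -> DeltaResult:
    """Per-protein, per-layer delta r_xy = r(base) - r(adapted).

    Both models must share an architecture. ``seqs`` maps protein id to a
    TokenSequence. Positive deltas mean the adapted model's attention is
    less diagonal (more global).
    """
    if not seqs:
        raise ValueError("delta_correlation requires a nonempty sequence set")
    cb, ca = base_model.config, adapted_model.config
    if (cb.n_layers, cb.n_heads, cb.d_model) != (ca.n_layers, ca.n_heads, ca.d_model):
        raise ValueError("base and adapted models must share an architecture")
    ids = list(seqs)
    r_base = np.stack([
        model_diagonal_correlations(base_model, seqs[pid], pid, "base").per_layer
        for pid in ids
    ])
    r_adapted = np.stack([
        model_diagonal_correlations(adapted_model, seqs[pid], pid, "adapted").per_layer
        for pid in ids
    ])
    adapted_layers = sorted({layer for (layer, _) in getattr(adapted_model, "adapters", {})})
    result = DeltaResult(deltas=r_base - r_adapted, r_base=r_base, r_adapted=r_adapted,
                         protein_ids=ids, adapted_layers=adapted_layers)
    result.p_values = layer_significance(result, test=significance)
    return result


def layer_significance(result: DeltaResult, test: str = "wilcoxon") -> np.ndarray:
    """Two-sided paired test per layer of H0: median delta = 0.

    Default is the Wilcoxon signed-rank test; a paired t-test is available
    with ``test="ttest"``. Degenerate all-zero layers return p = 1.
    """
    if result.n_proteins < 2:
        raise ValueError("significance requires at least 2 proteins")
    pvals = np.ones(result.n_layers)
    for layer in range(result.n_layers):
        d = result.deltas[:, layer]
        d = d[~np.isnan(d)]
        if len(d) < 2 or np.allclose(d, 0.0):
            pvals[layer] = 1.0
            continue
        if test == "wilcoxon":
            res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
            pvals[layer] = float(res.pvalue)
        elif test == "ttest":
            pvals[layer] = float(stats.ttest_1samp(d, 0.0).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
    return pvals
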