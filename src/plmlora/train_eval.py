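"""Training protocol and the per-class / macro-averaged metric suite.

Training follows the published protocol: sigmoid cross-entropy with logits
(one-vs-rest over 18 logits for the multiclass task), Adam with L2 weight
decay 0.01 (LayerNorm parameters exempt), a cosine-decay-with-restarts
learning-rate schedule (initial 0.001 for head-only and PEFT runs, 0.0005
for full fine-tuning), an epoch of 16,384 examples with an on-device batch
of 4 accumulated over 16 micro-batches (effective batch 64), and model
selection by the best validation AUPR across epochs.

Evaluation reports accuracy, F1, MCC, AUPR (average precision), precision,
recall and specificity, per class and as an unweighted ("macro") average —
the macro average is deliberately insensitive to class support, which is
highly imbalanced on the symmetry task. For a multiclass report the
per-class accuracy is the within-class accuracy (identical to recall), so
the macro accuracy is the balanced accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, matthews_corrcoef

from . import autograd as ag
from .autograd import Tensor
from .heads import ClassificationHead, pair_aggregate, pool_batch
from .lora import AdaptedModel, TuningMode
from .plm_core import PAD_TOKEN, TokenSequence, TransformerEncoder
from .data_synth import SYMMETRY_CLASSES, TaskData

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "RunHistory",
    "compute_loss",
    "cosine_restart_lr",
    "Adam",
    "train",
    "predict_scores",
    "evaluate",
    "macro_aupr",
    "simulate_random_binary_aupr",
    "simulate_random_multiclass_macro_aupr",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol. Defaults are the published settings."""

    epoch_size: int = 16384
    device_batch: int = 4
    accum_steps: int = 16
    n_epochs: int = 40
    lr: float | None = None  # per-mode default: 0.001 mlp/peft, 0.0005 ft
    weight_decay: float = 0.01
    restart_period: int = 5  # epochs per cosine restart
    seed: int = 0

    @property
    def effective_batch(self) -> int:
        return self.device_batch * self.accum_steps

    @property
    def updates_per_epoch(self) -> int:
        return self.epoch_size // self.effective_batch

    def mode_lr(self, kind: str) -> float:
        if self.lr is not None:
            return self.lr
        return 0.0005 if kind == "ft" else 0.001


@dataclass
class MetricsReport:
    """Per-class and macro-averaged classification metrics."""

    per_class: dict
    macro: dict
    n_classes: int
    support: dict
    zero_support: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = {str(c): m for c, m in self.per_class.items()}
        rows["macro"] = self.macro
        return pd.DataFrame(rows).T


@dataclass
class RunHistory:
    """Per-epoch training record and the selected best epoch."""

    epochs: list = field(default_factory=list)  # dicts: epoch, train_loss, val_aupr, lr
    best_epoch: int = -1
    best_val_aupr: float = -np.inf
    best_state: dict = field(default_factory=dict)

    def record(self, epoch: int, train_loss: float, val_aupr: float, lr: float) -> bool:
        self.epochs.append(
            {"epoch": epoch, "train_loss": train_loss, "val_aupr": val_aupr, "lr": lr}
        )
        if val_aupr > self.best_val_aupr:  # strict: first occurrence wins ties
            self.best_val_aupr = val_aupr
            self.best_epoch = epoch
            return True
        return False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


# ----------------------------------------------------------------------
# Loss
# ----------------------------------------------------------------------

def compute_loss(logits: Tensor, labels, task: str) -> Tensor:
    """Sigmoid cross-entropy: one logit (binary) or summed one-vs-rest (18-class)."""
    if task == "ppi":
        y = np.asarray(labels, dtype=np.float64)
        z = logits.reshape(-1) if logits.ndim > 1 else logits
        if z.shape != y.shape:
            raise ValueError(f"logit shape {z.shape} incompatible with labels {y.shape}")
        if np.any((y != 0) & (y != 1)):
            raise ValueError("binary labels must be 0 or 1")
        return ag.bce_with_logits(z, y).mean()
    if task == "symmetry":
        labels = np.asarray(labels)
        n_classes = logits.shape[-1]
        if labels.min() < 0 or labels.max() >= n_classes:
            raise ValueError("label outside the class set")
        onehot = np.zeros(logits.shape)
        onehot[np.arange(len(labels)), labels] = 1.0
        return ag.bce_with_logits(logits, onehot).sum(axis=-1).mean()
    raise ValueError(f"unknown task {task!r}")


# ----------------------------------------------------------------------
# Optimizer + schedule
# ----------------------------------------------------------------------

def cosine_restart_lr(base_lr: float, progress_epochs: float, period_epochs: float) -> float:
    """Cosine decay from base_lr to 0, restarting every `period_epochs`."""
    phase = (progress_epochs % period_epochs) / period_epochs
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * phase))


class Adam:
    """Adam with (coupled) L2 weight decay; LayerNorm parameters exempt."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0,
                 decay_exempt=("ln1.", "ln2.", "final_ln.")):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.exempt = {n for n in params if any(tag in n for tag in decay_exempt)}
        self.m = {n: np.zeros_like(p.data) for n, p in params.items()}
        self.v = {n: np.zeros_like(p.data) for n, p in params.items()}
        self.t = 0

    def step(self, grad_scale: float = 1.0) -> None:
        self.t += 1
        for n, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * grad_scale
            if self.weight_decay and n not in self.exempt:
                g = g + self.weight_decay * p.data
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1 ** self.t)
            vhat = self.v[n] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ----------------------------------------------------------------------
# Batching helpers
# ----------------------------------------------------------------------

def _tokenize_all(data: TaskData) -> dict[str, TokenSequence]:
    return {pid: TokenSequence.from_string(seq) for pid, seq in data.sequences.items()}

_CLASS_INDEX = {c: i for i, c in enumerate(SYMMETRY_CLASSES)}


def _pad_batch(tokens: list[TokenSequence]):
    n = max(t.ids.shape[0] for t in tokens)
    ids = np.full((len(tokens), n), PAD_TOKEN, dtype=np.int64)
    mask = np.zeros((len(tokens), n), dtype=bool)
    for i, t in enumerate(tokens):
        ids[i, : len(t.ids)] = t.ids
        mask[i, : len(t.ids)] = t.mask
    return ids, mask


def _forward_batch(model, head: ClassificationHead, records, tokens, task: str,
                   train: bool = False, rng=None) -> Tensor:
    """Embed -> pool -> (pair average) -> head, returning logits."""
    if task == "ppi":
        seqs = [tokens[r.id_a] for r in records] + [tokens[r.id_b] for r in records]
    else:
        seqs = [tokens[r.id] for r in records]
    ids, mask = _pad_batch(seqs)
    emb, _ = model.forward(ids, mask, train=train, rng=rng)
    pooled = pool_batch(emb, mask)
    if task == "ppi":
        B = len(records)
        pooled = pair_aggregate(pooled[:B], pooled[B:])
    return head.forward(pooled, train=train, rng=rng)


def _labels_of(records, task: str) -> np.ndarray:
    if task == "ppi":
        return np.array([r.label for r in records], dtype=np.int64)
    return np.array([_CLASS_INDEX[r.label] for r in records], dtype=np.int64)


def predict_scores(model, head: ClassificationHead, data: TaskData, split: str = "val",
                   batch_size: int = 32, tokens=None) -> np.ndarray:
    """Inference-mode probabilities: (n,) for pairs, (n, 18) one-vs-rest."""
    records = data.split(split)
    tokens = tokens or _tokenize_all(data)
    chunks = []
    for start in range(0, len(records), batch_size):
        logits = _forward_batch(model, head, records[start:start + batch_size],
                                tokens, data.task)
        z = logits.data
        chunks.append(1.0 / (1.0 + np.exp(-z)))
    scores = np.concatenate(chunks, axis=0)
    return scores.reshape(-1) if data.task == "ppi" else scores


def _trainable_params(model, head: ClassificationHead, mode: TuningMode) -> dict[str, Tensor]:
    params = {f"head.{n}": p for n, p in head.params.items()}
    if mode.kind == "mlp":
        return params
    if mode.kind == "peft":
        if not isinstance(model, AdaptedModel):
            raise ValueError("peft mode requires an adapter-injected model")
        params.update(model.trainable_params())
        return params
    base: TransformerEncoder = model
    if isinstance(model, AdaptedModel):
        raise ValueError("ft mode expects a plain (unadapted) encoder")
    first = base.config.n_layers - mode.n_layers
    for layer in range(first, base.config.n_layers):
        for name in base.block_param_names(layer):
            params[name] = base.params[name]
    return params


def train(model, head: ClassificationHead, data: TaskData, cfg: TrainConfig,
          mode: TuningMode) -> RunHistory:
    """Run the full protocol and return the per-epoch history + best state.

    Gradients are accumulated over ``accum_steps`` micro-batches with loss
    averaging, so the update is invariant to how a fixed effective batch is
    split. The checkpoint stored in ``history.best_state`` is the trainable
    parameter set at the epoch with the highest validation AUPR.
    """
    if not data.train or not data.val:
        raise ValueError("training requires nonempty train and validation splits")
    tokens = _tokenize_all(data)
    params = _trainable_params(model, head, mode)
    opt = Adam(params, lr=cfg.mode_lr(mode.kind), weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    base_lr = cfg.mode_lr(mode.kind)
    history = RunHistory()
    train_recs = data.train
    updates = max(cfg.updates_per_epoch, 1)

    for epoch in range(cfg.n_epochs):
        if cfg.epoch_size <= len(train_recs):
            idx = rng.permutation(len(train_recs))[: cfg.epoch_size]
        else:
            idx = rng.integers(0, len(train_recs), size=cfg.epoch_size)
        losses = []
        pos = 0
        lr_now = base_lr
        for u in range(updates):
            lr_now = cosine_restart_lr(base_lr, epoch + u / updates, cfg.restart_period)
            opt.lr = lr_now
            opt.zero_grad()
            n_micro = 0
            for _ in range(cfg.accum_steps):
                batch_idx = idx[pos: pos + cfg.device_batch]
                pos += cfg.device_batch
                if len(batch_idx) == 0:
                    break
                batch = [train_recs[i] for i in batch_idx]
                logits = _forward_batch(model, head, batch, tokens, data.task,
                                        train=True, rng=rng)
                loss = compute_loss(logits, _labels_of(batch, data.task), data.task)
                loss.backward()
                losses.append(loss.item())
                n_micro += 1
            if n_micro:
                opt.step(grad_scale=1.0 / n_micro)  # loss averaging across micro-batches

        val_scores = predict_scores(model, head, data, "val", tokens=tokens)
        val_labels = _labels_of(data.val, data.task)
        if data.task == "ppi":
            val_aupr = float(average_precision_score(val_labels, val_scores))
        else:
            val_aupr = macro_aupr(val_labels, val_scores, n_classes=len(SYMMETRY_CLASSES))
        improved = history.record(epoch, float(np.mean(losses)), val_aupr, lr_now)
        if improved:
            history.best_state = {n: p.data.copy() for n, p in params.items()}
    return history


def load_best(model, head: ClassificationHead, history: RunHistory, mode: TuningMode) -> None:
    """Restore the best-validation-AUPR checkpoint into model + head."""
    params = _trainable_params(model, head, mode)
    for n, arr in history.best_state.items():
        params[n].data = arr.copy()


# ----------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------

def _binary_contingency(y_true: np.ndarray, y_pred: np.ndarray):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _binary_metrics(y_true, y_pred, scores) -> dict:
    tp, fp, tn, fn = _binary_contingency(y_true, y_pred)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class label vector: MCC defined as 0")
        mcc = 0.0
        aupr = 0.0
    else:
        mcc = float(matthews_corrcoef(y_true, y_pred))
        aupr = float(average_precision_score(y_true, scores))
    return {
        "accuracy": _safe_div(tp + tn, tp + fp + tn + fn),
        "f1": _safe_div(2 * precision * recall, precision + recall),
        "mcc": mcc,
        "aupr": aupr,
        "precision": precision,
        "recall": recall,
        "specificity": _safe_div(tn, tn + fp),
    }


def evaluate(scores: np.ndarray, labels, task: str, threshold: float = 0.5,
             classes=None) -> MetricsReport:
    """Score a prediction set.

    Binary: probabilities thresholded at ``threshold`` plus AUPR over the
    ranking. Multiclass: argmax class prediction, one-vs-rest per-class
    metrics (per-class accuracy = within-class accuracy = recall), and an
    unweighted macro average; zero-support classes contribute 0 and are
    flagged in ``zero_support``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if task == "ppi":
        y = np.asarray(labels, dtype=np.int64)
        y_pred = (scores >= threshold).astype(np.int64)
        metrics = _binary_metrics(y, y_pred, scores)
        return MetricsReport(per_class={1: metrics}, macro=dict(metrics), n_classes=2,
                             support={1: int(y.sum()), 0: int((1 - y).sum())})
    if task != "symmetry":
        raise ValueError(f"unknown task {task!r}")

    classes = list(classes) if classes is not None else list(SYMMETRY_CLASSES)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = np.array([classes.index(l) for l in labels])
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError(f"scores must be (n, {len(classes)})")
    preds = scores.argmax(axis=1)
    per_class: dict = {}
    support: dict = {}
    zero_support = []
    for ci, cname in enumerate(classes):
        y_c = (labels == ci).astype(np.int64)
        support[cname] = int(y_c.sum())
        if support[cname] == 0:
            zero_support.append(cname)
            per_class[cname] = {m: 0.0 for m in
                                ("accuracy", "f1", "mcc", "aupr",
                                 "precision", "recall", "specificity")}
            continue
        p_c = (preds == ci).astype(np.int64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = _binary_metrics(y_c, p_c, scores[:, ci])
        m["accuracy"] = m["recall"]  # within-class accuracy
        per_class[cname] = m
    macro = {
        key: float(np.mean([per_class[c][key] for c in classes]))
        for key in next(iter(per_class.values()))
    }
    return MetricsReport(per_class=per_class, macro=macro, n_classes=len(classes),
                         support=support, zero_support=zero_support)


def macro_aupr(labels: np.ndarray, scores: np.ndarray, n_classes: int) -> float:
    """Unweighted mean of one-vs-rest average precision over nonempty classes
    (empty classes contribute 0)."""
    vals = []
    for ci in range(n_classes):
        y = (np.asarray(labels) == ci).astype(int)
        vals.append(float(average_precision_score(y, scores[:, ci])) if y.sum() else 0.0)
    return float(np.mean(vals))


# ----------------------------------------------------------------------
# Random-classifier baselines (by simulation)
# ----------------------------------------------------------------------

def simulate_random_binary_aupr(n: int = 10_000, reps: int = 50, seed: int = 0) -> float:
    """Mean AUPR of Uniform(0,1) scores on balanced binary labels."""
    rng = np.random.default_rng(seed)
    vals = [
        average_precision_score(rng.integers(0, 2, size=n), rng.random(n))
        for _ in range(reps)
    ]
    return float(np.mean(vals))


def simulate_random_multiclass_macro_aupr(n: int = 18_000, n_classes: int = 18,
                                          reps: int = 50, seed: int = 0) -> float:
    """Mean macro AUPR of uniform scores over equiprobable classes."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        labels = rng.integers(0, n_classes, size=n)
        scores = rng.random((n, n_classes))
        vals.append(macro_aupr(labels, scores, n_classes))
    return float(np.mean(vals))
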