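"""Loss closed forms, optimizer/schedule arithmetic, metric oracles, and
training-loop invariants (reproducibility, accumulation, freezing, selection)."""

import numpy as np
import pytest

from plmlora import (
    ArchConfig,
    HeadSpec,
    LoraConfig,
    RunHistory,
    SyntheticTaskSpec,
    TrainConfig,
    TuningMode,
    build_head,
    build_model,
    compute_loss,
    cosine_restart_lr,
    evaluate,
    inject_adapters,
    macro_aupr,
    predict_scores,
    simulate_ppi_task,
    train,
)
from plmlora.autograd import Tensor
from plmlora.train_eval import Adam, load_best

LN2 = np.log(2.0)


# ----------------------------------------------------------------------
# Loss closed forms
# ----------------------------------------------------------------------

class TestLoss:
    def test_binary_zero_logits_is_ln2(self):
        loss = compute_loss(Tensor(np.zeros(8)), np.array([0, 1] * 4), "ppi")
        assert abs(loss.item() - LN2) < 1e-12

    def test_binary_confident_correct_vanishes(self):
        z = np.array([30.0, -30.0])
        loss = compute_loss(Tensor(z), np.array([1, 0]), "ppi")
        assert loss.item() < 1e-10

    def test_binary_elementwise_oracle(self, rng):
        z = rng.normal(size=20) * 2
        y = rng.integers(0, 2, size=20)
        loss = compute_loss(Tensor(z), y, "ppi").item()
        p = 1 / (1 + np.exp(-z))
        naive = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert abs(loss - naive) < 1e-10

    def test_multiclass_zero_logits(self):
        """18 sigmoid terms per example, each ln 2 at logit 0."""
        loss = compute_loss(Tensor(np.zeros((5, 18))), np.arange(5), "symmetry")
        assert abs(loss.item() - 18 * LN2) < 1e-10

    def test_multiclass_one_vs_rest_oracle(self, rng):
        z = rng.normal(size=(6, 18))
        labels = rng.integers(0, 18, size=6)
        onehot = np.eye(18)[labels]
        naive = (np.maximum(z, 0) - z * onehot + np.log1p(np.exp(-np.abs(z)))).sum(1).mean()
        assert abs(compute_loss(Tensor(z), labels, "symmetry").item() - naive) < 1e-10

    def test_label_validation(self):
        with pytest.raises(ValueError):
            compute_loss(Tensor(np.zeros(2)), np.array([0, 2]), "ppi")
        with pytest.raises(ValueError):
            compute_loss(Tensor(np.zeros((2, 18))), np.array([0, 18]), "symmetry")
        with pytest.raises(ValueError):
            compute_loss(Tensor(np.zeros(2)), np.array([0, 1]), "nope")


# ----------------------------------------------------------------------
# Protocol arithmetic + optimizer
# ----------------------------------------------------------------------

class TestProtocol:
    def test_published_defaults(self):
        cfg = TrainConfig()
        assert cfg.effective_batch == 64
        assert cfg.updates_per_epoch == 16384 // 64 == 256
        assert cfg.n_epochs == 40
        assert cfg.weight_decay == 0.01

    def test_mode_learning_rates(self):
        cfg = TrainConfig()
        assert cfg.mode_lr("mlp") == cfg.mode_lr("peft") == 0.001
        assert cfg.mode_lr("ft") == 0.0005
        assert TrainConfig(lr=0.1).mode_lr("ft") == 0.1

    def test_cosine_restart_schedule(self):
        assert cosine_restart_lr(1.0, 0.0, 5.0) == 1.0
        assert abs(cosine_restart_lr(1.0, 2.5, 5.0) - 0.5) < 1e-12
        # restart: progress == period returns to the peak
        assert abs(cosine_restart_lr(1.0, 5.0, 5.0) - 1.0) < 1e-12
        # monotone decrease within one period
        vals = [cosine_restart_lr(1.0, t, 5.0) for t in np.linspace(0, 4.999, 50)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_adam_first_step_is_signed(self):
        p = Tensor(np.array([1.0, -2.0]), requires_grad=True)
        p.grad = np.array([0.5, -3.0])
        opt = Adam({"w": p}, lr=0.1)
        opt.step()
        # bias-corrected first step: lr * g/(|g| + eps) ~ lr * sign(g)
        np.testing.assert_allclose(p.data, [1.0 - 0.1, -2.0 + 0.1], atol=1e-6)

    def test_adam_converges_on_quadratic(self):
        p = Tensor(np.array([5.0]), requires_grad=True)
        opt = Adam({"w": p}, lr=0.3)
        for _ in range(200):
            p.grad = 2 * p.data  # d/dx x^2
            opt.step()
            opt.zero_grad()
        assert abs(p.data[0]) < 1e-2

    def test_layernorm_exempt_from_decay(self):
        g = Tensor(np.ones(4), requires_grad=True)
        w = Tensor(np.ones(4), requires_grad=True)
        opt = Adam({"blocks.0.ln1.g": g, "blocks.0.attn.q.W": w},
                   lr=0.0, weight_decay=0.5)
        assert "blocks.0.ln1.g" in opt.exempt
        assert "blocks.0.attn.q.W" not in opt.exempt

    def test_history_best_epoch_strict_improvement(self):
        h = RunHistory()
        assert h.record(0, 1.0, 0.5, 0.1) is True
        assert h.record(1, 1.0, 0.7, 0.1) is True
        assert h.record(2, 1.0, 0.7, 0.1) is False  # tie: first wins
        assert h.record(3, 1.0, 0.6, 0.1) is False
        assert h.best_epoch == 1 and h.best_val_aupr == 0.7


# ----------------------------------------------------------------------
# Metrics against hand-computed contingency tables
# ----------------------------------------------------------------------

def _naive_average_precision(y, scores):
    """AP for unique scores: mean precision at each positive, ranked desc."""
    order = np.argsort(-scores)
    y = np.asarray(y)[order]
    cum = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    return float(np.sum((cum / ranks) * y) / y.sum())


class TestMetrics:
    def test_binary_hand_contingency(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        scores = np.array([0.9, 0.2, 0.3, 0.8, 0.7, 0.1])
        rep = evaluate(scores, y, "ppi", threshold=0.5)
        m = rep.macro  # tp=2 fn=1 fp=1 tn=2
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["mcc"] == pytest.approx(1 / 3)  # (4-1)/sqrt(81)
        assert rep.support == {1: 3, 0: 3}

    def test_binary_aupr_matches_naive_oracle(self, rng):
        y = rng.integers(0, 2, size=200)
        scores = rng.random(200)  # unique w.p. 1
        rep = evaluate(scores, y, "ppi")
        assert rep.macro["aupr"] == pytest.approx(_naive_average_precision(y, scores))

    def test_perfect_ranking_aupr_one(self):
        y = np.array([0, 0, 1, 1])
        rep = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), y, "ppi")
        assert rep.macro["aupr"] == 1.0

    def test_single_class_mcc_zero_with_warning(self):
        with pytest.warns(UserWarning):
            rep = evaluate(np.array([0.9, 0.8]), np.array([1, 1]), "ppi")
        assert rep.macro["mcc"] == 0.0

    def test_multiclass_macro_is_unweighted_mean(self, rng):
        labels = rng.integers(0, 4, size=100)
        scores = rng.random((100, 4))
        rep = evaluate(scores, labels, "symmetry", classes=["a", "b", "c", "d"])
        for key in ("f1", "recall", "aupr", "mcc"):
            assert rep.macro[key] == pytest.approx(
                np.mean([rep.per_class[c][key] for c in "abcd"]))

    def test_multiclass_accuracy_equals_recall(self, rng):
        labels = rng.integers(0, 3, size=60)
        scores = rng.random((60, 3))
        rep = evaluate(scores, labels, "symmetry", classes=["x", "y", "z"])
        for c in "xyz":
            assert rep.per_class[c]["accuracy"] == rep.per_class[c]["recall"]

    def test_multiclass_hand_example(self):
        # 2 present classes of 3; predictions argmax over columns
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.05, 0.05],
                           [0.1, 0.8, 0.1],
                           [0.2, 0.7, 0.1],
                           [0.3, 0.6, 0.1]])
        rep = evaluate(scores, labels, "symmetry", classes=["a", "b", "c"])
        assert rep.per_class["a"]["recall"] == pytest.approx(0.5)  # 1 of 2
        assert rep.per_class["b"]["recall"] == pytest.approx(1.0)
        assert rep.zero_support == ["c"]
        assert rep.per_class["c"]["f1"] == 0.0  # zero-support contributes 0

    def test_multiclass_string_labels(self):
        labels = np.array(["a", "b"])
        scores = np.array([[0.9, 0.1], [0.2, 0.8]])
        rep = evaluate(scores, labels, "symmetry", classes=["a", "b"])
        assert rep.per_class["a"]["recall"] == 1.0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros((4, 3)), np.zeros(4, dtype=int), "symmetry",
                     classes=["a", "b"])

    def test_macro_aupr_perfect_and_empty_class(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.zeros((4, 3))
        scores[np.arange(4), labels] = 1.0
        # classes 0,1 perfectly ranked (AP 1), class 2 empty contributes 0
        assert macro_aupr(labels, scores, 3) == pytest.approx(2 / 3)


# ----------------------------------------------------------------------
# Training-loop invariants on a tiny fixture
# ----------------------------------------------------------------------

TINY = ArchConfig(d_model=16, n_layers=2, n_heads=2, ffn_dim=32, max_len=64, seed=0)
SPEC = SyntheticTaskSpec(n_proteins=60, n_pairs=120, seed=5)
FAST = TrainConfig(epoch_size=16, device_batch=4, accum_steps=2, n_epochs=2, seed=1)


def _fresh(mode_kind: str, dropout_p: float = 0.1, head_seed: int = 2):
    model = build_model(TINY)
    head = build_head(HeadSpec(input_dim=16, n_outputs=1, dropout_p=dropout_p,
                               seed=head_seed))
    if mode_kind == "peft":
        cfg = LoraConfig(("K", "V"), rank=2, n_adapted_layers=2, seed=3)
        return inject_adapters(model, cfg), head, TuningMode("peft", lora=cfg)
    if mode_kind == "ft":
        return model, head, TuningMode("ft", n_layers=1)
    return model, head, TuningMode("mlp")


class TestTrainingLoop:
    def test_reproducible_under_identical_seeds(self):
        data = simulate_ppi_task(SPEC)
        m1, head1, mode1 = _fresh("mlp")
        m2, head2, mode2 = _fresh("mlp")
        h1 = train(m1, head1, data, FAST, mode1)
        h2 = train(m2, head2, data, FAST, mode2)
        assert [e["val_aupr"] for e in h1.epochs] == [e["val_aupr"] for e in h2.epochs]
        assert [e["train_loss"] for e in h1.epochs] == [e["train_loss"] for e in h2.epochs]

    def test_accumulation_invariance(self):
        """One micro-batch of 8 vs two of 4: identical updates (no dropout)."""
        data = simulate_ppi_task(SPEC)
        outs = []
        for db, acc in ((8, 1), (4, 2)):
            model, head, mode = _fresh("mlp", dropout_p=0.0)
            cfg = TrainConfig(epoch_size=8, device_batch=db, accum_steps=acc,
                              n_epochs=1, seed=7)
            train(model, head, data, cfg, mode)
            outs.append({n: p.data.copy() for n, p in head.params.items()})
        for n in outs[0]:
            np.testing.assert_allclose(outs[0][n], outs[1][n], atol=1e-12)

    def test_mlp_mode_freezes_backbone(self):
        data = simulate_ppi_task(SPEC)
        model, head, mode = _fresh("mlp")
        before = {n: p.data.copy() for n, p in model.params.items()}
        train(model, head, data, FAST, mode)
        for n, arr in before.items():
            np.testing.assert_array_equal(model.params[n].data, arr)

    def test_peft_freezes_base_trains_adapters(self):
        data = simulate_ppi_task(SPEC)
        adapted, head, mode = _fresh("peft")
        base_before = {n: p.data.copy() for n, p in adapted.base.params.items()}
        head_before = {n: p.data.copy() for n, p in head.params.items()}
        train(adapted, head, data, FAST, mode)
        for n, arr in base_before.items():  # bit-frozen base weights
            np.testing.assert_array_equal(adapted.base.params[n].data, arr)
        assert any(np.any(pair.B.data != 0.0) for pair in adapted.adapters.values())
        assert any(not np.array_equal(head.params[n].data, head_before[n])
                   for n in head_before)

    def test_ft_updates_only_last_blocks(self):
        data = simulate_ppi_task(SPEC)
        model, head, mode = _fresh("ft")  # last 1 of 2 blocks
        before = {n: p.data.copy() for n, p in model.params.items()}
        train(model, head, data, FAST, mode)
        changed = {n for n, arr in before.items()
                   if not np.array_equal(model.params[n].data, arr)}
        assert changed  # something trained
        assert all(n.startswith("blocks.1.") for n in changed)

    def test_best_state_and_load_best(self):
        data = simulate_ppi_task(SPEC)
        model, head, mode = _fresh("mlp")
        history = train(model, head, data, FAST, mode)
        assert set(history.best_state) == {f"head.{n}" for n in head.params}
        # corrupt, restore, verify restoration
        for p in head.params.values():
            p.data[...] = 0.0
        load_best(model, head, history, mode)
        for n, p in head.params.items():
            np.testing.assert_array_equal(p.data, history.best_state[f"head.{n}"])

    def test_predict_scores_shape_and_range(self):
        data = simulate_ppi_task(SPEC)
        model, head, _ = _fresh("mlp")
        scores = predict_scores(model, head, data, "val")
        assert scores.shape == (len(data.val),)
        assert np.all((scores > 0) & (scores < 1))

    def test_empty_split_rejected(self):
        data = simulate_ppi_task(SPEC)
        model, head, mode = _fresh("mlp")
        data.val = []
        with pytest.raises(ValueError):
            train(model, head, data, FAST, mode)

    def test_peft_mode_requires_adapted_model(self):
        data = simulate_ppi_task(SPEC)
        model, head, _ = _fresh("mlp")
        cfg = LoraConfig(("K", "V"), rank=2, n_adapted_layers=2)
        with pytest.raises(ValueError):
            train(model, head, data, FAST, TuningMode("peft", lora=cfg))
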