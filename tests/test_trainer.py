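"""Loss terms, training-loop contracts and mixture-aware checkpoint selection."""

import numpy as np
import pytest

from sersmix.model import DualBranchModel, ModelConfig
from sersmix.trainer import (
    FeatureDataset,
    HistoryRecord,
    LossBreakdown,
    TrainConfig,
    TrainHistory,
    loss_classification,
    loss_evidence,
    loss_regularization,
    select_checkpoint,
    train,
)


# ---- classification loss ---------------------------------------------

def test_uniform_logits_give_log_K():
    loss, _ = loss_classification(np.zeros((4, 3)), np.array([0, 1, 2, 0]))
    assert loss == pytest.approx(np.log(3.0))


def test_aligned_huge_logit_drives_loss_to_zero():
    logits = np.array([[50.0, 0.0, 0.0]])
    loss, _ = loss_classification(logits, np.array([0]))
    assert loss < 1e-20


def test_cross_entropy_matches_scalar_brute_force():
    logits = np.array([[1.0, -0.5, 0.2], [0.3, 2.0, -1.0]])
    y = np.array([2, 1])
    loss, grad = loss_classification(logits, y)
    manual = 0.0
    for i in range(2):
        e = np.exp(logits[i])
        manual += -np.log(e[y[i]] / e.sum())
    assert loss == pytest.approx(manual / 2)
    # gradient equals (softmax - onehot)/B
    for i in range(2):
        sm = np.exp(logits[i]) / np.exp(logits[i]).sum()
        sm[y[i]] -= 1.0
        np.testing.assert_allclose(grad[i], sm / 2)


def test_label_out_of_range_rejected():
    with pytest.raises(ValueError):
        loss_classification(np.zeros((1, 3)), np.array([3]))


# ---- evidence loss ---------------------------------------------------

def test_evidence_loss_zero_when_probabilities_match_targets():
    z = np.array([[1.0, 0.0, 0.0]])
    p = np.clip(z, 1e-9, 1 - 1e-9)
    loss, _ = loss_evidence(p, z)
    assert loss == pytest.approx(0.0, abs=1e-7)


def test_evidence_loss_maximum_entropy_point():
    loss, _ = loss_evidence(np.full((1, 3), 0.5), np.array([[1, 0, 1]]))
    assert loss == pytest.approx(np.log(2.0))


def test_evidence_loss_direct_arithmetic():
    p = np.array([[0.9, 0.2, 0.1]])
    z = np.array([[1.0, 0.0, 0.0]])
    loss, _ = loss_evidence(p, z)
    expected = -(np.log(0.9) + np.log(0.8) + np.log(0.9)) / 3
    assert loss == pytest.approx(expected)


# ---- clipping regulariser -------------------------------------------

def test_regularizer_zero_inside_clip():
    loss, grad = loss_regularization(np.array([[0.0, 3.0, -5.0]]), 6.0)
    assert loss == 0.0 and np.all(grad == 0.0)


def test_regularizer_quadratic_excess():
    loss, _ = loss_regularization(np.array([[8.0, 0.0, 0.0]]), 6.0)
    assert loss == pytest.approx(4.0 / 3.0)


def test_regularizer_monotone_in_magnitude():
    us = [6.0, 7.0, 8.0, 10.0]
    losses = [loss_regularization(np.array([[u, 0.0, 0.0]]), 6.0)[0] for u in us]
    assert all(a <= b for a, b in zip(losses, losses[1:]))


def test_loss_breakdown_composition_identity():
    bd = LossBreakdown(0.7, 0.3, 0.1, lambda_evi=1.0, lambda_reg=0.01)
    assert bd.total == pytest.approx(0.7 + 1.0 * 0.3 + 0.01 * 0.1)


# ---- training loop ---------------------------------------------------

def _tiny_setup(n_per_class=8, L=128, seed=0):
    rng = np.random.default_rng(seed)
    X, cats = [], []
    centers = {"A": 20, "B": 60, "C": 100}
    for c, pos in centers.items():
        for _ in range(n_per_class):
            x = 0.02 * rng.random(L)
            x[pos - 3 : pos + 3] += 1.0 + 0.1 * rng.standard_normal()
            X.append(x)
            cats.append(c)
    data = FeatureDataset(np.array(X), cats)
    mc = ModelConfig(embed_dim=16, stem=(5, 2, 4), stages=((4, 1), (8, 1)),
                     input_len=L)
    return data, mc


def test_train_rejects_mixture_categories():
    data, mc = _tiny_setup()
    data.categories[0] = "AB"
    model = DualBranchModel(mc, seed=0)
    cfg = TrainConfig(total_steps=10, warmup_steps=1, eval_every=5, batch_size=6)
    with pytest.raises(ValueError, match="mixture"):
        train(data, model, cfg)


def test_short_run_is_deterministic_and_logs_composition():
    data, mc = _tiny_setup()
    cfg = TrainConfig(total_steps=60, warmup_steps=10, eval_every=20,
                      batch_size=6, seed=9)
    hists = []
    for _ in range(2):
        model = DualBranchModel(mc, seed=4)
        hists.append(train(data, model, cfg))
    for r1, r2 in zip(hists[0], hists[1]):
        assert r1.total == r2.total
    for r in hists[0]:
        assert r.total == pytest.approx(
            r.L_cls + cfg.lambda_evi * r.L_evi + cfg.lambda_reg * r.L_reg, abs=1e-9)
    steps = [r.step for r in hists[0]]
    assert steps == sorted(steps) and len(set(steps)) == len(steps)


def test_learning_rate_reaches_floor_at_final_step():
    data, mc = _tiny_setup()
    model = DualBranchModel(mc, seed=0)
    cfg = TrainConfig(total_steps=40, warmup_steps=5, eval_every=40, batch_size=6)
    hist = train(data, model, cfg)
    assert hist.records[-1].lr == pytest.approx(cfg.lr_min)


# ---- checkpoint selection -------------------------------------------

def _rec(step, pure, seven):
    return HistoryRecord(step, 0, 0, 0, 0, 0.0, pure_val_acc=pure,
                         seven_cat_val_acc=seven, state={})


def test_select_single_eligible_record():
    cfg = TrainConfig(total_steps=1000, warmup_steps=500)
    hist = TrainHistory([_rec(400, 1.0, 0.9), _rec(600, 0.99, 0.8)])
    assert select_checkpoint(hist, cfg).step == 600


def test_select_maximises_seven_category_accuracy():
    cfg = TrainConfig(total_steps=3000, warmup_steps=500)
    hist = TrainHistory([_rec(1000, 0.97, 0.90), _rec(2000, 0.98, 0.95)])
    assert select_checkpoint(hist, cfg).step == 2000


def test_select_breaks_ties_toward_latest_step():
    cfg = TrainConfig(total_steps=3000, warmup_steps=500)
    hist = TrainHistory([_rec(1000, 0.99, 0.93), _rec(2000, 0.96, 0.93)])
    assert select_checkpoint(hist, cfg).step == 2000


def test_select_respects_eligibility_floor():
    cfg = TrainConfig(total_steps=3000, warmup_steps=500)
    hist = TrainHistory([_rec(1000, 0.90, 0.99), _rec(2000, 0.96, 0.80)])
    assert select_checkpoint(hist, cfg).step == 2000


def test_select_errors_without_eligible_checkpoint():
    cfg = TrainConfig(total_steps=3000, warmup_steps=500)
    hist = TrainHistory([_rec(400, 1.0, 0.9), _rec(600, 0.5, 0.9)])
    with pytest.raises(RuntimeError, match="extend training"):
        select_checkpoint(hist, cfg)
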