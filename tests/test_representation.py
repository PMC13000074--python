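"""Encoder contracts: causality, gradients, training loop, metrics."""

import numpy as np
import pandas as pd
import pytest

from phenoguide._nn import HEADS, MultiTaskLSTM, masked_loss_and_head_grads, sigmoid
from phenoguide.preprocessing import TimeStepTensor
from phenoguide.representation import (
    EncoderConfig,
    GuidedEncoder,
    evaluate,
    multitask_loss,
    train,
)


def _tensor(pid, X, died=0, rng=None):
    T, D = X.shape
    rrt = np.zeros(T)
    mv = np.zeros(T)
    rrt[-1] = mv[-1] = np.nan
    return TimeStepTensor(
        patient_id=pid,
        feature_names=[f"f{j}" for j in range(D)],
        features=X,
        observed_mask=np.ones_like(X),
        n_windows=T,
        fluid_total=np.zeros(T),
        vaso_max=np.zeros(T),
        peep_documented=np.zeros(T, bool),
        rrt_documented=np.zeros(T, bool),
        died_90d=died,
        remaining_los_days=(T - np.arange(T)) * (4 / 24),
        rrt_next=rrt,
        mv_next=mv,
    )


def test_encoding_dim_must_be_smaller_than_input():
    with pytest.raises(ValueError, match="smaller"):
        GuidedEncoder(EncoderConfig(encoding_dim=8), input_dim=8,
                      feature_names=[f"f{j}" for j in range(8)])


def test_encoder_is_causal():
    rng = np.random.default_rng(0)
    model = GuidedEncoder(EncoderConfig(hidden_dim=8, encoding_dim=3, seed=1), 6,
                          [f"f{j}" for j in range(6)])
    X = rng.standard_normal((1, 10, 6))
    Xp = X.copy()
    Xp[0, 5:] += 10.0
    e1 = model.encode_batch(X)
    e2 = model.encode_batch(Xp)
    np.testing.assert_array_equal(e1[0, :5], e2[0, :5])
    assert not np.allclose(e1[0, 5:], e2[0, 5:])


def test_encode_deterministic_and_shaped():
    rng = np.random.default_rng(2)
    model = GuidedEncoder(EncoderConfig(hidden_dim=8, encoding_dim=3, seed=1), 5,
                          [f"f{j}" for j in range(5)])
    tensors = [_tensor(0, rng.standard_normal((7, 5))), _tensor(1, rng.standard_normal((4, 5)))]
    enc1 = model.encode(tensors)
    enc2 = model.encode(tensors)
    pd.testing.assert_frame_equal(enc1, enc2)
    assert enc1.shape == (11, 3)


def test_dimension_mismatch_rejected():
    model = GuidedEncoder(EncoderConfig(hidden_dim=8, encoding_dim=3, seed=1), 5,
                          [f"f{j}" for j in range(5)])
    bad = _tensor(0, np.zeros((3, 4)))
    with pytest.raises(ValueError, match="mismatch"):
        model.encode([bad])


def test_predictions_in_open_unit_interval_and_zeroed_head_gives_half():
    rng = np.random.default_rng(3)
    model = GuidedEncoder(EncoderConfig(hidden_dim=8, encoding_dim=3, seed=1), 5,
                          [f"f{j}" for j in range(5)])
    for h in ("mort", "rrt", "mv"):
        for suffix in ("W1", "b1", "W2", "b2"):
            model.net.params[f"{h}_{suffix}"][:] = 0.0
    preds = model.predict([_tensor(0, rng.standard_normal((6, 5)))])
    for col in ("p_mort", "p_rrt", "p_mv"):
        assert ((preds[col] > 0) & (preds[col] < 1)).all()
        np.testing.assert_allclose(preds[col], 0.5)
    assert len(preds) == 6


class TestMultitaskLoss:
    def test_weighted_aggregation_arithmetic(self):
        preds = {"p_mort": np.array([0.5]), "los_hat": np.array([1.0]),
                 "p_rrt": np.array([0.5]), "p_mv": np.array([0.5])}
        labels = {"mort": np.array([1.0]), "los": np.array([3.0]),
                  "rrt": np.array([0.0]), "mv": np.array([1.0])}
        total, comps = multitask_loss(preds, labels, dict.fromkeys(HEADS, 0.25))
        assert total == pytest.approx(0.25 * sum(comps.values()))
        assert comps["los"] == pytest.approx(4.0)

    def test_single_task_weight(self):
        preds = {"p_mort": np.array([0.9]), "los_hat": np.array([0.0]),
                 "p_rrt": np.array([0.1]), "p_mv": np.array([0.5])}
        labels = {"mort": np.array([1.0]), "los": np.array([5.0]),
                  "rrt": np.array([1.0]), "mv": np.array([0.0])}
        total, comps = multitask_loss(preds, labels, {"mort": 1.0})
        assert total == pytest.approx(comps["mort"]) == pytest.approx(-np.log(0.9))

    def test_perfect_predictions_vanish(self):
        eps = 1e-9
        preds = {"p_mort": np.array([1 - eps]), "los_hat": np.array([2.0]),
                 "p_rrt": np.array([eps]), "p_mv": np.array([1 - eps])}
        labels = {"mort": np.array([1.0]), "los": np.array([2.0]),
                  "rrt": np.array([0.0]), "mv": np.array([1.0])}
        total, _ = multitask_loss(preds, labels, dict.fromkeys(HEADS, 1.0))
        assert total < 1e-7

    def test_all_masked_with_positive_weight_raises(self):
        preds = {"p_mort": np.array([0.5]), "los_hat": np.array([0.0]),
                 "p_rrt": np.array([0.5]), "p_mv": np.array([0.5])}
        labels = {"mort": np.array([1.0]), "los": np.array([1.0]),
                  "rrt": np.array([np.nan]), "mv": np.array([1.0])}
        with pytest.raises(ValueError, match="rrt"):
            multitask_loss(preds, labels, dict.fromkeys(HEADS, 1.0))


def test_gradients_match_finite_differences():
    """Autodiff of the total loss agrees with central differences to 1e-4."""
    rng = np.random.default_rng(0)
    net = MultiTaskLSTM(5, 4, 3, 3, rng)
    X = rng.standard_normal((2, 3, 5))
    wmask = np.array([[1, 1, 1], [1, 1, 0.0]])
    labels = {
        "mort": np.array([1.0, 0.0]),
        "los": np.array([[3.0, 2, 1], [2, 1, np.nan]]),
        "rrt": np.array([[0.0, 1, np.nan], [1, np.nan, np.nan]]),
        "mv": np.array([[1.0, 0, np.nan], [0, np.nan, np.nan]]),
    }
    w = dict.fromkeys(HEADS, 1.0)

    def loss():
        enc, _ = net.forward(X)
        outs, _ = net.head_forward(enc)
        return masked_loss_and_head_grads(outs, labels, wmask, w)[0]

    enc, cache = net.forward(X)
    outs, hcache = net.head_forward(enc)
    _, _, d_outs = masked_loss_and_head_grads(outs, labels, wmask, w)
    grads = net.zero_grads()
    dE = net.head_backward(enc, hcache, d_outs, grads)
    dX = net.backward(cache, dE, grads)

    eps = 1e-6
    for k, v in net.params.items():
        it = np.nditer(v, flags=["multi_index"])
        fd = np.zeros_like(v)
        for _ in it:
            idx = it.multi_index
            old = v[idx]
            v[idx] = old + eps
            lp = loss()
            v[idx] = old - eps
            lm = loss()
            v[idx] = old
            fd[idx] = (lp - lm) / (2 * eps)
        denom = max(1e-8, np.abs(fd).max())
        assert np.abs(fd - grads[k]).max() / denom < 1e-4, k
    fdX = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = X[idx]
        X[idx] = old + eps
        lp = loss()
        X[idx] = old - eps
        lm = loss()
        X[idx] = old
        fdX[idx] = (lp - lm) / (2 * eps)
    assert np.abs(fdX - dX).max() / np.abs(fdX).max() < 1e-4


def _toy_split(n, seed, D=6, died_frac=0.4):
    rng = np.random.default_rng(seed)
    out = []
    for pid in range(n):
        T = int(rng.integers(3, 9))
        died = int(rng.random() < died_frac)
        X = rng.standard_normal((T, D)) + died  # planted signal
        t = _tensor(pid, X, died)
        t.rrt_next[:-1] = (rng.random(T - 1) < 0.3).astype(float)
        t.mv_next[:-1] = (rng.random(T - 1) < (0.7 if died else 0.2)).astype(float)
        out.append(t)
    return out


def test_zero_learning_rate_leaves_parameters_unchanged():
    tensors = _toy_split(12, 0)
    cfg = EncoderConfig(hidden_dim=8, encoding_dim=3, learning_rate=0.0,
                        max_epochs=3, input_noise_sd=0.0, weight_decay=0.0, seed=0)
    model, history = train(tensors, tensors, cfg)
    fresh = GuidedEncoder(cfg, 6, tensors[0].feature_names)
    for k in fresh.net.params:
        np.testing.assert_array_equal(model.net.params[k], fresh.net.params[k])
    assert len(history) == 3


def test_training_reduces_loss_and_stops_early():
    tr = _toy_split(50, 1)
    va = _toy_split(20, 2)
    cfg = EncoderConfig(hidden_dim=12, encoding_dim=4, max_epochs=60, patience=5,
                        input_noise_sd=0.0, weight_decay=0.0, seed=3)
    model, history = train(tr, va, cfg)
    assert history["train_total"].iloc[-1] < history["train_total"].iloc[0]
    assert len(history) < 60  # patience triggered
    # returned model is the best-validation checkpoint
    best = history["val_total"].min()
    Xv = va
    from phenoguide.representation import pack_batch
    X, wm, lab = pack_batch(Xv)
    enc, _ = model.net.forward(X)
    outs, _ = model.net.head_forward(enc)
    total, _, _ = masked_loss_and_head_grads(outs, lab, wm, cfg.loss_weights)
    assert total == pytest.approx(best, rel=1e-9)


def test_training_is_seed_reproducible():
    tr = _toy_split(20, 4)
    cfg = EncoderConfig(hidden_dim=8, encoding_dim=3, max_epochs=5, seed=7)
    _, h1 = train(tr, tr, cfg)
    _, h2 = train(tr, tr, cfg)
    pd.testing.assert_frame_equal(h1, h2)


def _pair_count_auroc(y, p):
    """Exhaustive Mann-Whitney pair counting with half credit for ties."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def _model_with_scores(self, scores, labels):
        """Report metrics for fixed per-window scores via a stub tensor set."""
        from sklearn.metrics import roc_auc_score
        return roc_auc_score(labels, scores)

    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
            ((0.2, 0.8), (1, 0), 0.0),
            ((0.6, 0.6), (1, 0), 0.5),
        ],
    )
    def test_auroc_conventions(self, scores, labels, expected):
        got = self._model_with_scores(np.array(scores), np.array(labels))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(
            _pair_count_auroc(np.array(labels), np.array(scores))
        )

    def test_tie_handling_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 5, 60) / 4.0  # heavy ties
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        assert self._model_with_scores(p, y) == pytest.approx(_pair_count_auroc(y, p))

    def test_bootstrap_report_structure(self):
        tensors = _toy_split(25, 9)
        cfg = EncoderConfig(hidden_dim=8, encoding_dim=3, max_epochs=4, seed=1)
        model, _ = train(tensors, tensors, cfg)
        rep = evaluate(model, tensors, n_bootstrap=30, seed=0)
        for task in ("mort", "rrt", "mv"):
            point, lo, hi = rep.metrics[task]["auroc"]
            assert lo <= point <= hi
            assert 0.0 <= point <= 1.0
        mse = rep.metrics["los"]["mse"]
        assert mse[1] <= mse[0] <= mse[2]

    def test_single_class_reports_missing_auroc(self):
        tensors = _toy_split(10, 3, died_frac=0.0)
        cfg = EncoderConfig(hidden_dim=8, encoding_dim=3, max_epochs=2, seed=1)
        model, _ = train(
            tensors, tensors,
            EncoderConfig(hidden_dim=8, encoding_dim=3, max_epochs=2, seed=1,
                          loss_weights={"mort": 0.0, "los": 1.0, "rrt": 1.0, "mv": 1.0}),
        )
        rep = evaluate(model, tensors, n_bootstrap=5, seed=0)
        assert rep.metrics["mort"]["auroc"] is None


def test_checkpoint_roundtrip(tmp_path):
    tensors = _toy_split(8, 5)
    cfg = EncoderConfig(hidden_dim=8, encoding_dim=3, max_epochs=2, seed=2)
    model, _ = train(tensors, tensors, cfg)
    path = tmp_path / "enc.npz"
    model.save(str(path))
    loaded = GuidedEncoder.load(str(path))
    pd.testing.assert_frame_equal(model.encode(tensors), loaded.encode(tensors))
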