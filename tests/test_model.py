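"""Metrics formulas, loss closed forms, training and cross-validation."""

import math

import numpy as np
import pytest

from idgcn.model import (
    TrainConfig,
    cross_entropy,
    cross_validate,
    evaluate,
    init_params,
    model_forward,
    train,
    _loss_and_grads,
    _flatten_grads,
    _flatten_params,
)
from tests.conftest import random_basis


def test_metrics_from_hand_counts():
    # TP=3, TN=2, FP=1, FN=2 -> accuracy 5/8, precision 3/4, recall 3/5
    labels = np.array([1, 1, 1, 1, 1, 0, 0, 0])
    probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.4])
    m = evaluate(probs, labels)
    assert (m.tp, m.tn, m.fp, m.fn) == (3, 2, 1, 2)
    assert m.n == 8
    assert m.accuracy == pytest.approx(0.625)
    assert m.precision == pytest.approx(0.75)
    assert m.recall == pytest.approx(0.6)
    assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)


def test_metrics_perfect_predictions():
    labels = np.array([0, 1, 0, 1])
    m = evaluate(np.array([0.1, 0.9, 0.2, 0.8]), labels)
    for name in ("accuracy", "precision", "recall", "f1", "auc"):
        assert getattr(m, name) == 1.0


def test_auc_matches_sklearn_and_chance_level():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    labels = rng.integers(0, 2, 200)
    labels[:2] = [0, 1]
    probs = rng.random(200)
    m = evaluate(probs, labels)
    assert m.auc == pytest.approx(roc_auc_score(labels, probs), abs=1e-12)
    aucs = []
    for _ in range(50):
        p = rng.random(200)
        aucs.append(evaluate(p, labels).auc)
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_auc_single_class_is_nan_with_warning():
    with pytest.warns(RuntimeWarning, match="single-class"):
        m = evaluate(np.array([0.2, 0.7]), np.array([1, 1]))
    assert math.isnan(m.auc)


def test_cross_entropy_closed_forms():
    assert cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-11)
    assert cross_entropy(1, 0.5) == pytest.approx(math.log(2), abs=1e-12)
    for p in (0.1, 0.35, 0.9):
        assert cross_entropy(1, p) == pytest.approx(cross_entropy(0, 1 - p), abs=1e-12)


def test_forward_zero_fc_gives_uniform_probabilities(rng):
    params = init_params(5, 3, 2, K=2, seed=0)
    params.fc_weights[:] = 0.0
    params.fc_bias[:] = 0.0
    basis = random_basis(rng, 5, 2)
    p = model_forward(rng.normal(size=(5, 3)), basis, basis, params, np.array([1.0, 0.0]))
    assert np.allclose(p, [0.5, 0.5], atol=1e-12)


def test_forward_probabilities_normalized_and_logit_identity(rng):
    params = init_params(5, 3, 2, K=2, seed=1)
    basis = random_basis(rng, 5, 2)
    X = rng.normal(size=(5, 3))
    site = np.array([0.0, 1.0])
    p = model_forward(X, basis, basis, params, site)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    # logit difference equals FC column-difference dotted with the pre-FC vector
    from idgcn.invertible import stack_forward

    z1, z2 = stack_forward(X, params.blocks, basis, basis)
    h = np.concatenate([z1.ravel(), z2.ravel(), site])
    diff = h @ (params.fc_weights[:, 1] - params.fc_weights[:, 0]) + (
        params.fc_bias[1] - params.fc_bias[0]
    )
    assert np.log(p[1] / p[0]) == pytest.approx(diff, abs=1e-9)


def test_full_model_gradients_pass_central_difference(rng):
    B, N, F, K, S = 3, 5, 4, 3, 2
    Tsp = np.stack([random_basis(rng, N, K) for _ in range(B)])
    Tfn = np.stack([random_basis(rng, N, K) for _ in range(B)])
    X = rng.normal(size=(B, N, F))
    sites = np.eye(S)[rng.integers(0, S, B)]
    labels = np.array([0, 1, 1])
    params = init_params(N, F, S, K=K, seed=0, init_scale=0.5)
    _, grads = _loss_and_grads(X, Tsp, Tfn, sites, labels, params)
    arrs = _flatten_params(params)
    garrs = _flatten_grads(grads, 3)
    h = 1e-6
    check_rng = np.random.default_rng(1)
    for a, g in zip(arrs, garrs):
        flat = a.ravel()
        for i in check_rng.choice(flat.size, min(10, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp, _ = _loss_and_grads(X, Tsp, Tfn, sites, labels, params)
            flat[i] = orig - h
            lm, _ = _loss_and_grads(X, Tsp, Tfn, sites, labels, params)
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            ana = g.ravel()[i]
            assert abs(num - ana) / max(1e-8, abs(num) + abs(ana)) < 1e-4


def _tiny_dataset(rng, B=12):
    N, F, K, S = 4, 3, 2, 2
    Tsp = np.stack([random_basis(rng, N, K) for _ in range(B)])
    Tfn = np.stack([random_basis(rng, N, K) for _ in range(B)])
    labels = np.array([0, 1] * (B // 2))
    X = rng.normal(size=(B, N, F)) + labels[:, None, None] * 0.8
    sites = np.eye(S)[np.arange(B) % S]
    return dict(features=X, spatial_basis=Tsp, functional_basis=Tfn, sites=sites, labels=labels)


def test_training_decreases_loss_and_is_deterministic(rng):
    ds = _tiny_dataset(rng)
    cfg = TrainConfig(epochs=60, learning_rate=0.01, seed=3)
    p1, losses1 = train(ds, cfg, K=2)
    p2, losses2 = train(ds, cfg, K=2)
    assert losses1[-1] < losses1[0]
    assert losses1 == losses2
    assert np.array_equal(p1.fc_weights, p2.fc_weights)
    for b1, b2 in zip(p1.blocks.blocks, p2.blocks.blocks):
        assert np.array_equal(b1.phi.weights, b2.phi.weights)


def test_training_requires_both_classes(rng):
    ds = _tiny_dataset(rng)
    ds["labels"] = np.ones_like(ds["labels"])
    with pytest.raises(ValueError, match="both classes"):
        train(ds, TrainConfig(epochs=2), K=2)


def test_cross_validation_partitions_and_aggregates(small_separated_cohort):
    cohort = small_separated_cohort
    cfg = TrainConfig(epochs=80, learning_rate=0.01, weight_decay=1.0, seed=0)
    cv = cross_validate(cohort, cfg, M=3, J=2, k=2, K=2, folds=5, seed=0,
                        window_length=30, stride=15, rf_trees=50)
    # folds partition all subjects, sizes differ by <= 1
    test_sets = [set(f.test_idx.tolist()) for f in cv.folds]
    all_test = set().union(*test_sets)
    assert all_test == set(range(cohort.n_subjects))
    assert sum(len(s) for s in test_sets) == cohort.n_subjects
    sizes = [len(s) for s in test_sets]
    assert max(sizes) - min(sizes) <= 1
    # train subjects never enter the fold's screening fit, test never in train
    for f in cv.folds:
        assert set(f.train_idx).isdisjoint(set(f.test_idx))
    # aggregate equals recomputed mean/sd of the fold metrics
    accs = [f.metrics.accuracy for f in cv.folds]
    assert cv.mean["accuracy"] == pytest.approx(float(np.mean(accs)))
    assert cv.sd["accuracy"] == pytest.approx(float(np.std(accs)))
    # selections were refit per fold (supervised step differs across folds)
    sel_sets = {
        tuple(tuple(ix) for ix in f.selection.static_indices) for f in cv.folds
    }
    assert len(sel_sets) > 1


def test_learnable_cohort_reaches_high_training_accuracy(small_separated_cohort):
    from idgcn.model import features_for, prepare_cohort
    from idgcn.screening import fit_screening

    cohort = small_separated_cohort
    prep = prepare_cohort(cohort, k=2, K=2, window_length=30, stride=15)
    sel = fit_screening(prep.static, prep.dynamic, cohort.labels, M=3, J=2,
                        seed=0, n_estimators=50)
    X = features_for(prep, sel, np.arange(cohort.n_subjects))
    cfg = TrainConfig(epochs=200, learning_rate=0.01, seed=0)
    params, losses = train(
        {"features": X, "spatial_basis": prep.spatial_basis,
         "functional_basis": prep.functional_basis, "sites": prep.sites_onehot,
         "labels": cohort.labels},
        cfg, K=2,
    )
    probs = model_forward(X, prep.spatial_basis, prep.functional_basis, params,
                          prep.sites_onehot)
    assert evaluate(probs[:, 1], cohort.labels).accuracy >= 0.95
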