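import numpy as np
import pytest

from conftest import auc_bruteforce
from mnclcda.config import RunConfig
from mnclcda.evaluation import (
    compute_metrics,
    make_folds,
    masked_training_matrix,
    new_drug_eval,
    rank_candidates,
    run_cv,
)
from mnclcda.propagation import build_feature_graph
from mnclcda.similarity import build_similarity_bundle


def planted_Y(seed=0, nc=12, nd=8):
    rng = np.random.default_rng(seed)
    Y = (rng.random((nc, nd)) < 0.35).astype(float)
    Y[0, 0] = 1.0  # ensure positives exist
    return Y


def test_make_folds_balanced_and_stratified():
    Y = np.zeros((10, 5))
    Y[np.arange(10), np.arange(10) % 5] = 1.0  # 10 positives
    plan = make_folds(Y, k=5, seed=0)
    assert len(plan.positives) == len(plan.negatives) == 10
    for fold in range(5):
        pairs, labels = plan.fold_pairs(fold)
        assert labels.count(1) == 2 and labels.count(0) == 2
    # folds partition the sample
    seen = []
    for f in range(5):
        pairs, labels = plan.fold_pairs(f)
        seen.extend(p for p, l in zip(pairs, labels) if l == 1)
    assert sorted(seen) == sorted(plan.positives)


def test_make_folds_deterministic_per_seed():
    Y = planted_Y()
    p1 = make_folds(Y, 3, seed=5)
    p2 = make_folds(Y, 3, seed=5)
    assert p1.positives == p2.positives and p1.negatives == p2.negatives
    np.testing.assert_array_equal(p1.pos_folds, p2.pos_folds)


def test_make_folds_negatives_are_zero_entries():
    Y = planted_Y()
    plan = make_folds(Y, 3, seed=1)
    for i, j in plan.negatives:
        assert Y[i, j] == 0.0
    assert len(set(plan.negatives)) == len(plan.negatives)


def test_make_folds_rejects_impossible_requests():
    Y = np.ones((3, 3))
    Y[0, 0] = 0.0
    with pytest.raises(ValueError):
        make_folds(Y, 2, seed=0)  # not enough negatives


def test_masked_training_matrix_zeroes_only_test_fold_positives():
    Y = planted_Y()
    plan = make_folds(Y, 3, seed=2)
    Y_train = masked_training_matrix(Y, plan, 1)
    zeroed = [(p, f) for p, f in zip(plan.positives, plan.pos_folds) if f == 1]
    assert int((Y - Y_train).sum()) == len(zeroed)
    for (i, j), _ in zeroed:
        assert Y_train[i, j] == 0.0


def test_compute_metrics_confusion_counts():
    scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.6, 0.2]
    labels = [1, 1, 0, 1, 1, 0, 0, 0]
    r = compute_metrics(scores, labels, threshold=0.5)
    assert (r.tp, r.fn, r.tn, r.fp) == (3, 1, 2, 2)
    assert r.recall == pytest.approx(0.75)
    assert r.precision == pytest.approx(0.6)
    assert r.f1 == pytest.approx(2 / 3)
    assert r.accuracy == pytest.approx(0.625)
    assert r.specificity == pytest.approx(0.5)


def test_compute_metrics_perfect_and_tied():
    r = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert r.auc == 1.0 and r.aupr == 1.0
    assert compute_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)
    with pytest.raises(ValueError):
        compute_metrics([0.5, 0.6], [1, 1])


def test_auc_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert compute_metrics(scores, labels).auc == pytest.approx(
            auc_bruteforce(scores, labels), abs=1e-12
        )


def test_rank_candidates_ordering_and_exclusion():
    scores = np.array([[0.1, 0.5], [0.9, 0.5], [0.5, 0.5]])
    Y = np.zeros((3, 2))
    rows = rank_candidates(scores, ["c1", "c2", "c3"], ["d1", "d2"], "d1")
    assert [r[1] for r in rows] == ["c2", "c3", "c1"]
    # ties broken by ascending row index
    rows = rank_candidates(scores, ["c1", "c2", "c3"], ["d1", "d2"], "d2")
    assert [r[1] for r in rows] == ["c1", "c2", "c3"]
    Y[1, 0] = 1.0
    rows = rank_candidates(scores, ["c1", "c2", "c3"], ["d1", "d2"], "d1", exclude_known=True, Y=Y)
    assert [r[1] for r in rows] == ["c3", "c1"]
    rows = rank_candidates(scores, ["c1", "c2", "c3"], ["d1", "d2"], "d1", top=2)
    assert len(rows) == 2
    with pytest.raises(KeyError):
        rank_candidates(scores, ["c1", "c2", "c3"], ["d1", "d2"], "nope")


def test_run_cv_report_structure(small_planted, small_config):
    ds, _ = small_planted
    report = run_cv(ds, small_config.replace(epochs=5), k=2, seed=1)
    assert len(report["folds"]) == 2
    for key in ("auc", "aupr", "accuracy", "precision", "recall", "specificity", "f1"):
        assert 0.0 <= report["mean"][key] <= 1.0


def test_new_drug_column_removed_from_training(small_planted, small_config, monkeypatch):
    ds, _ = small_planted
    j = int(np.argmax(ds.Y.sum(axis=0)))
    drug = ds.drug_ids[j]
    seen = {}
    import mnclcda.evaluation as ev

    orig = ev.train_fold

    def spy(dataset, Y_train, config):
        seen["col"] = Y_train[:, j].copy()
        return orig(dataset, Y_train, config)

    monkeypatch.setattr(ev, "train_fold", spy)
    rows = ev.new_drug_eval(ds, drug, small_config.replace(epochs=3))
    assert seen["col"].sum() == 0.0
    assert len(rows) == ds.n_circ


def test_pipeline_reads_only_training_matrix(small_planted, small_config):
    """Feature construction must be blind to the held-out test labels."""
    ds, _ = small_planted
    plan = make_folds(ds.Y, 2, seed=0)
    Y_train = masked_training_matrix(ds.Y, plan, 0)
    # a second dataset whose test-fold entries are flipped: same Y_train
    Y_alt = ds.Y.copy()
    for (i, j), f in zip(plan.positives, plan.pos_folds):
        if f == 0:
            Y_alt[i, j] = 0.0
    ds_alt = type(ds)(
        circ_ids=ds.circ_ids, drug_ids=ds.drug_ids, Y=Y_alt,
        sequences=ds.sequences, fingerprints=ds.fingerprints,
    )
    b1 = build_similarity_bundle(ds, Y_train)
    b2 = build_similarity_bundle(ds_alt, Y_train)
    for name in ("SC", "SD", "GC", "GD", "CS", "DS"):
        np.testing.assert_array_equal(getattr(b1, name), getattr(b2, name))
    g1 = build_feature_graph(b1, Y_train, small_config)
    g2 = build_feature_graph(b2, Y_train, small_config)
    np.testing.assert_array_equal(g1.X, g2.X)
    np.testing.assert_array_equal(g1.A, g2.A)
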