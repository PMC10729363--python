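"""Cross-validation, metrics, candidate ranking and new-drug protocols.

Evaluation follows the balanced-sampling convention for bipartite link
prediction: unknown pairs equal in number to the known positives are drawn
uniformly as negatives, the pooled sample is split into k stratified folds,
and for each fold the *entire* feature pipeline (GIP kernels, random-walk
features, encoder, predictor) is rebuilt from the training matrix with the
held-out positives zeroed, so no test label leaks into the features.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .data import AssociationDataset
from .propagation import build_feature_graph
from .similarity import build_similarity_bundle
from .training import TrainedModel, predict, train

Pair = tuple[int, int]


@dataclasses.dataclass
class FoldPlan:
    """Balanced positive/negative sample with stratified fold assignments."""

    k: int
    positives: list[Pair]
    negatives: list[Pair]
    pos_folds: np.ndarray
    neg_folds: np.ndarray
    seed: int

    def fold_pairs(self, fold: int) -> tuple[list[Pair], list[int]]:
        """Pairs and labels of one fold's test set."""
        if not 0 <= fold < self.k:
            raise ValueError(f"fold index {fold} out of range for k={self.k}")
        pairs = [p for p, f in zip(self.positives, self.pos_folds) if f == fold]
        labels = [1] * len(pairs)
        neg = [p for p, f in zip(self.negatives, self.neg_folds) if f == fold]
        pairs.extend(neg)
        labels.extend([0] * len(neg))
        return pairs, labels


@dataclasses.dataclass
class MetricsReport:
    auc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def make_folds(Y: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Sample balanced negatives and assign stratified folds, deterministically."""
    if k < 2:
        raise ValueError("k must be >= 2")
    Y = np.asarray(Y, dtype=float)
    pos = [tuple(p) for p in np.argwhere(Y == 1)]
    neg_pool = np.argwhere(Y == 0)
    if len(pos) < k:
        raise ValueError(f"need at least k={k} positives, found {len(pos)}")
    if len(neg_pool) < len(pos):
        raise ValueError(
            f"not enough negatives ({len(neg_pool)}) to balance {len(pos)} positives"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(neg_pool), size=len(pos), replace=False)
    neg = [tuple(p) for p in neg_pool[neg_idx]]

    def assign(n: int) -> np.ndarray:
        folds = np.arange(n) % k           # near-equal fold sizes per class
        return folds[rng.permutation(n)]

    return FoldPlan(
        k=k, positives=pos, negatives=neg,
        pos_folds=assign(len(pos)), neg_folds=assign(len(neg)), seed=seed,
    )


def masked_training_matrix(Y: np.ndarray, plan: FoldPlan, test_fold: int) -> np.ndarray:
    """Copy of Y with the test fold's positive entries zeroed."""
    if not 0 <= test_fold < plan.k:
        raise ValueError(f"fold index {test_fold} out of range for k={plan.k}")
    Y_train = np.asarray(Y, dtype=float).copy()
    for (i, j), f in zip(plan.positives, plan.pos_folds):
        if f == test_fold:
            Y_train[i, j] = 0.0
    return Y_train


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Ranking metrics (AUC, AUPR) plus thresholded confusion metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC is undefined when only one class is present")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(labels)
    return MetricsReport(
        auc=auc, aupr=aupr, accuracy=accuracy, precision=precision, recall=recall,
        specificity=specificity, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn,
    )


def train_fold(
    dataset: AssociationDataset, Y_train: np.ndarray, config: RunConfig
) -> TrainedModel:
    """Rebuild the similarity bundle and feature graph from Y_train, then train."""
    bundle = build_similarity_bundle(dataset, Y_train)
    graph = build_feature_graph(bundle, Y_train, config)
    return train(dataset, Y_train, config, graph=graph)


def run_cv(
    dataset: AssociationDataset,
    config: RunConfig,
    k: int = 5,
    seed: int | None = None,
) -> dict:
    """k-fold cross-validation with full per-fold pipeline rebuilds."""
    seed = config.stage_seed("cv") if seed is None else seed
    plan = make_folds(dataset.Y, k, seed)
    fold_reports: list[MetricsReport] = []
    for fold in range(k):
        Y_train = masked_training_matrix(dataset.Y, plan, fold)
        model = train_fold(dataset, Y_train, config)
        scores_matrix = predict(model)
        pairs, labels = plan.fold_pairs(fold)
        scores = [scores_matrix[i, j] for i, j in pairs]
        fold_reports.append(compute_metrics(scores, labels, config.threshold))
    means = {
        key: float(np.mean([getattr(r, key) for r in fold_reports]))
        for key in ("auc", "aupr", "accuracy", "precision", "recall", "specificity", "f1")
    }
    return {"folds": [r.to_dict() for r in fold_reports], "mean": means, "k": k, "seed": seed}


def rank_candidates(
    scores: np.ndarray,
    circ_ids: list[str],
    drug_ids: list[str],
    drug_id: str,
    exclude_known: bool = False,
    Y: np.ndarray | None = None,
    top: int | None = None,
) -> list[tuple[int, str, float]]:
    """circRNAs ranked by descending score for one drug; ties by row index."""
    if drug_id not in drug_ids:
        raise KeyError(f"unknown drug id {drug_id!r}")
    j = drug_ids.index(drug_id)
    column = np.asarray(scores, dtype=float)[:, j]
    order = np.lexsort((np.arange(len(column)), -column))
    rows = []
    for i in order:
        if exclude_known and Y is not None and Y[i, j] == 1:
            continue
        rows.append((len(rows) + 1, circ_ids[i], float(column[i])))
        if top is not None and len(rows) >= top:
            break
    return rows


def new_drug_eval(
    dataset: AssociationDataset,
    drug_id: str,
    config: RunConfig,
    top: int | None = None,
) -> list[tuple[int, str, float]]:
    """Leave a drug's associations out of training and rank its candidates."""
    if drug_id not in dataset.drug_ids:
        raise KeyError(f"unknown drug id {drug_id!r}")
    j = dataset.drug_ids.index(drug_id)
    Y_train = dataset.Y.copy()
    Y_train[:, j] = 0.0
    model = train_fold(dataset, Y_train, config)
    scores = predict(model)
    return rank_candidates(scores, dataset.circ_ids, dataset.drug_ids, drug_id, top=top)
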