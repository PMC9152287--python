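"""Positive-unlabeled evaluation protocol.

Only disease-associated miRNAs are annotated; negatives are drawn
uniformly without replacement from the unlabeled pool at ``ratio`` times
the positive count (or the whole pool with ratio ``"all"``), once per
experiment. Performance is measured by stratified five-fold
cross-validation with ROC-AUC, PR-AUC (average precision) and F1 at a
0.5 posterior threshold. ROC-AUC follows the Mann-Whitney convention
(ties count one half); PR-AUC is the step-wise average-precision sum
``sum_k (R_k - R_{k-1}) P_k``. These tie/summation conventions are fixed
because they move third-decimal results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .embedding import FeatureTable
from .graphs import ConfigurationError, LabelSet
from .pipeline import CnnGnbClassifier

FEATURE_SOURCES = ("similarity_only", "interaction_only", "both")


@dataclass
class ExperimentConfig:
    """One experimental condition of the evaluation grid."""

    negative_ratio: int | str = "all"
    folds: int = 5
    feature_source: str = "both"
    embedder: str = "node2vec"
    variant: str = "full"
    seed: int = 0
    encoder_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(f"feature_source must be one of {FEATURE_SOURCES}")
        if self.negative_ratio != "all" and int(self.negative_ratio) < 1:
            raise ValueError("negative_ratio must be a positive integer or 'all'")


@dataclass
class MetricsReport:
    """Per-fold and mean metrics for one configuration, plus raw fold scores."""

    config: dict
    fold_roc_auc: list[float]
    fold_pr_auc: list[float]
    fold_f1: list[float]
    fold_scores: list[np.ndarray] = field(repr=False)
    fold_labels: list[np.ndarray] = field(repr=False)

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.fold_roc_auc))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.fold_pr_auc))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def summary(self) -> dict:
        return {
            "config": self.config,
            "fold_roc_auc": self.fold_roc_auc,
            "fold_pr_auc": self.fold_pr_auc,
            "fold_f1": self.fold_f1,
            "mean_roc_auc": self.mean_roc_auc,
            "mean_pr_auc": self.mean_pr_auc,
            "mean_f1": self.mean_f1,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"fold": i, "roc_auc": r, "pr_auc": p, "f1": f}
            for i, (r, p, f) in enumerate(
                zip(self.fold_roc_auc, self.fold_pr_auc, self.fold_f1)
            )
        ]
        rows.append(
            {
                "fold": "mean",
                "roc_auc": self.mean_roc_auc,
                "pr_auc": self.mean_pr_auc,
                "f1": self.mean_f1,
            }
        )
        pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------- sampling


def sample_negatives(
    unlabeled: set[str] | Sequence[str],
    n_pos: int,
    ratio: int | str,
    seed: int = 0,
) -> set[str]:
    """Uniform sample (without replacement) of ``ratio * n_pos`` negatives.

    ``ratio="all"`` returns the entire unlabeled pool. The pool is sorted
    before sampling so identical seeds give identical samples regardless
    of set iteration order.
    """
    pool = sorted(unlabeled)
    if ratio == "all":
        return set(pool)
    k = int(ratio) * n_pos
    if k > len(pool):
        raise ConfigurationError(
            f"ratio {ratio} needs {k} negatives but the unlabeled pool has {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=k, replace=False))


def kfold_split(
    ids: Sequence[str], labels: Sequence[int], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition over sample indices.

    Each test fold's positive count is within one of the even split, and
    the folds partition the index range exactly.
    """
    y = np.asarray(labels).astype(int)
    if min(np.bincount(y, minlength=2)) < k:
        raise ConfigurationError(f"need at least {k} samples of each class for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


# ------------------------------------------------------------------ metrics


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve = Mann-Whitney P(score_pos > score_neg),
    with ties counted one half."""
    y = np.asarray(y_true).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC is undefined with a single class")
    return float(skm.roc_auc_score(y, scores))


def pr_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision: sum_k (R_k - R_{k-1}) P_k over descending thresholds."""
    y = np.asarray(y_true).astype(int)
    if y.sum() == 0:
        raise ValueError("PR-AUC is undefined without positive labels")
    return float(skm.average_precision_score(y, scores))


def f1(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """F1 = 2PR/(P+R), defined as 0 when precision + recall is 0."""
    return float(skm.f1_score(y_true, y_pred, zero_division=0))


def roc_curve_grid(
    fold_labels: list[np.ndarray], fold_scores: list[np.ndarray], n_grid: int = 101
) -> pd.DataFrame:
    """Mean ROC curve with a std band, interpolated on a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for y, s in zip(fold_labels, fold_scores):
        fpr, tpr, _ = skm.roc_curve(y, s)
        tprs.append(np.interp(grid, fpr, tpr))
    arr = np.vstack(tprs)
    return pd.DataFrame(
        {"fpr": grid, "tpr_mean": arr.mean(axis=0), "tpr_std": arr.std(axis=0)}
    )


def pr_curve_grid(
    fold_labels: list[np.ndarray], fold_scores: list[np.ndarray], n_grid: int = 101
) -> pd.DataFrame:
    """Mean precision-recall curve with a std band on a fixed recall grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    precs = []
    for y, s in zip(fold_labels, fold_scores):
        prec, rec, _ = skm.precision_recall_curve(y, s)
        # curves come recall-descending; flip for interpolation
        precs.append(np.interp(grid, rec[::-1], prec[::-1]))
    arr = np.vstack(precs)
    return pd.DataFrame(
        {"recall": grid, "precision_mean": arr.mean(axis=0), "precision_std": arr.std(axis=0)}
    )


# -------------------------------------------------------------- experiments


def assemble_dataset(
    features: FeatureTable, labels: LabelSet, cfg: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix and label vector for one experiment.

    Negatives are sampled once per experiment (not per fold); the feature
    table is block-masked according to ``feature_source``.
    """
    table = features.mask_block(cfg.feature_source)
    universe = {m for m in table.mirna_ids}
    positives = labels.positives & universe
    unlabeled = universe - positives
    negatives = sample_negatives(unlabeled, len(positives), cfg.negative_ratio, cfg.seed)
    ids = [m for m in table.mirna_ids if m in positives or m in negatives]
    y = np.array([1 if m in positives else 0 for m in ids])
    X = table.features[[table.row_of(m) for m in ids]]
    return X, y, ids


def run_experiment(
    features: FeatureTable,
    labels: LabelSet,
    cfg: ExperimentConfig,
) -> MetricsReport:
    """Five-fold cross-validated run of the full pipeline for one condition.

    Per fold: train the encoder on the training split, encode both splits,
    fit GaussianNB on the training codes, score the test split. Fully
    seeded: negatives, folds, and per-fold encoder seeds all derive from
    ``cfg.seed``.
    """
    X, y, _ = assemble_dataset(features, labels, cfg)
    folds = kfold_split([str(i) for i in range(len(y))], y, cfg.folds, cfg.seed)
    fold_roc, fold_pr, fold_f1 = [], [], []
    fold_scores, fold_labels = [], []
    for i, (tr, te) in enumerate(folds):
        model = CnnGnbClassifier(
            variant=cfg.variant,
            random_state=cfg.seed * 1000 + i,
            **cfg.encoder_params,
        ).fit(X[tr], y[tr])
        scores = model.predict_proba(X[te])[:, 1]
        fold_roc.append(roc_auc(y[te], scores))
        fold_pr.append(pr_auc(y[te], scores))
        fold_f1.append(f1(y[te], (scores >= 0.5).astype(int)))
        fold_scores.append(scores)
        fold_labels.append(y[te])
    return MetricsReport(
        config=asdict(cfg),
        fold_roc_auc=fold_roc,
        fold_pr_auc=fold_pr,
        fold_f1=fold_f1,
        fold_scores=fold_scores,
        fold_labels=fold_labels,
    )


def rank_candidates(
    model: CnnGnbClassifier,
    features: FeatureTable,
    labels: LabelSet,
    top_k: int | None = None,
) -> list[tuple[str, float]]:
    """Rank unlabeled miRNAs by positive-class posterior, descending.

    Training positives are excluded. Ties break lexicographically by id
    for reproducibility.
    """
    candidates = [m for m in features.mirna_ids if m not in labels.positives]
    X = features.features[[features.row_of(m) for m in candidates]]
    probs = model.predict_proba(X)[:, 1]
    ranked = sorted(zip(candidates, probs), key=lambda t: (-t[1], t[0]))
    return ranked[:top_k] if top_k is not None else ranked
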