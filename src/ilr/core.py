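"""Iterative logistic regression (iLR).

At each iteration an L2-penalized logistic model

    logit(p) = b0 + b1*g1 + ... + bm*gm

is fitted to the training cells, genes are ranked by |coefficient|, and
the top ``keep_fraction`` (default 80%) are carried into the next
iteration.  The loop stops before the retained set would fall below
``min_genes`` (default 10).  Stratified k-fold cross-validation accuracy
and ROC-AUC are recorded at every iteration; the resulting trajectory of
(gene set, size, accuracy, AUC) is the input to Pareto-front selection.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io import LabeledDataset

__all__ = [
    "IlrConfig",
    "LogisticModel",
    "IterationRecord",
    "Trajectory",
    "fit_logistic",
    "rank_genes",
    "retained_count",
    "run_ilr",
    "test_auc",
    "f1_like",
]

#: numerical agreement expected of refitted coefficients on identical input
COEF_TOL = 1e-6


@dataclass
class IlrConfig:
    """Parameters of the iterative elimination loop.

    ``C`` is the inverse regularization strength of the logistic model
    (default 0.1; values in roughly [0.001, 0.1] are sensible for
    expression data).  ``penalty_type`` is ``"l2"`` (default) or ``"l1"``
    — L1 exists for the regularization-comparison harness only.
    """

    C: float = 0.1
    penalty_type: str = "l2"
    keep_fraction: float = 0.8
    min_genes: int = 10
    cv_folds: int = 5
    seed: int = 0
    scale_features: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.penalty_type.lower() not in ("l1", "l2"):
            raise ValueError("penalty_type must be 'l1' or 'l2'")
        self.penalty_type = self.penalty_type.lower()
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must be in (0, 1)")
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.gene_ids):
            raise ValueError("one coefficient per gene required")
        if not np.all(np.isfinite(self.coefficients)) or not math.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")


@dataclass
class IterationRecord:
    iteration_index: int
    gene_set: list[str]
    size: int
    cv_accuracy: float
    cv_auc: float


@dataclass
class Trajectory:
    """Ordered iteration records plus the configuration that produced them."""

    records: list[IterationRecord]
    config: IlrConfig
    train_fingerprint: str = ""
    warning: str | None = None

    @property
    def sizes(self) -> list[int]:
        return [r.size for r in self.records]

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "train_fingerprint": self.train_fingerprint,
            "warning": self.warning,
            "records": [
                {
                    "iteration": r.iteration_index,
                    "size": r.size,
                    "cv_accuracy": r.cv_accuracy,
                    "cv_auc": r.cv_auc,
                    "genes": r.gene_set,
                }
                for r in self.records
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Trajectory":
        payload = json.loads(text)
        records = [
            IterationRecord(r["iteration"], list(r["genes"]), r["size"], r["cv_accuracy"], r["cv_auc"])
            for r in payload["records"]
        ]
        return cls(
            records,
            IlrConfig(**payload["config"]),
            payload.get("train_fingerprint", ""),
            payload.get("warning"),
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _make_estimator(config: IlrConfig):
    lr = LogisticRegression(
        C=config.C,
        l1_ratio=1.0 if config.penalty_type == "l1" else 0.0,
        solver="liblinear",
        tol=1e-5,
        max_iter=2000,
        random_state=config.seed,
    )
    if config.scale_features:
        return Pipeline([("scale", StandardScaler()), ("logit", lr)])
    return lr


def _final_lr(estimator):
    return estimator.named_steps["logit"] if isinstance(estimator, Pipeline) else estimator


def _check_training_input(matrix: np.ndarray, labels: np.ndarray) -> None:
    if not np.all(np.isfinite(matrix)):
        raise ValueError("training matrix contains non-finite values")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")


def fit_logistic(
    matrix: np.ndarray,
    labels: np.ndarray,
    config: IlrConfig,
    gene_ids: Sequence[str] | None = None,
) -> LogisticModel:
    """Fit one penalized logistic model and return its coefficients."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_training_input(matrix, labels)
    est = _make_estimator(config)
    est.fit(matrix, labels)
    lr = _final_lr(est)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(matrix.shape[1])]
    return LogisticModel(float(lr.intercept_[0]), lr.coef_[0].copy(), list(gene_ids))


def rank_genes(model: LogisticModel) -> list[str]:
    """Genes in decreasing |coefficient| order; ties keep the input order."""
    order = np.argsort(-np.abs(model.coefficients), kind="stable")
    return [model.gene_ids[i] for i in order]


def retained_count(m: int, keep_fraction: float) -> int:
    """Size of the retained set: ceil(keep_fraction*m), forced below m so
    the trajectory strictly shrinks."""
    if m < 1:
        raise ValueError("m must be >= 1")
    k = math.ceil(keep_fraction * m)
    if k >= m and m >= 2:
        k = m - 1
    return min(k, m)


def _cv_metrics(matrix: np.ndarray, labels: np.ndarray, config: IlrConfig) -> tuple[float, float]:
    """Mean validation-fold accuracy and ROC-AUC over stratified folds."""
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    accs, aucs = [], []
    for train_rows, val_rows in cv.split(matrix, labels):
        est = _make_estimator(config)
        est.fit(matrix[train_rows], labels[train_rows])
        proba = est.predict_proba(matrix[val_rows])[:, 1]
        accs.append(accuracy_score(labels[val_rows], proba >= 0.5))
        aucs.append(roc_auc_score(labels[val_rows], proba))
    return float(np.mean(accs)), float(np.mean(aucs))


def _fingerprint(matrix: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.blake2b(digest_size=16)
    h.update(np.ascontiguousarray(matrix).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()


def run_ilr(train: LabeledDataset, config: IlrConfig | None = None) -> Trajectory:
    """Run iterative elimination on a training dataset.

    Iteration 0 uses all genes.  Each subsequent iteration fits on the full
    training set restricted to the current genes and keeps the top
    ``retained_count`` by |coefficient|; the loop stops when the next set
    would be smaller than ``min_genes``.
    """
    config = config or IlrConfig()
    _check_training_input(train.matrix, train.labels)
    fingerprint = _fingerprint(train.matrix, train.labels)
    gene_idx = np.arange(train.n_genes)
    records: list[IterationRecord] = []
    warning = None
    if train.n_genes < config.min_genes:
        warning = (
            f"input has {train.n_genes} genes, fewer than min_genes={config.min_genes}; "
            "single-record trajectory"
        )
        warnings.warn(warning, stacklevel=2)
    iteration = 0
    while True:
        X = train.matrix[:, gene_idx]
        genes = [train.gene_ids[i] for i in gene_idx]
        acc, auc = _cv_metrics(X, train.labels, config)
        records.append(IterationRecord(iteration, genes, len(genes), acc, auc))
        if warning is not None:
            break
        k = retained_count(len(gene_idx), config.keep_fraction)
        if k < config.min_genes:
            break
        model = fit_logistic(X, train.labels, config, genes)
        order = np.argsort(-np.abs(model.coefficients), kind="stable")[:k]
        gene_idx = np.sort(gene_idx[order])
        iteration += 1
    return Trajectory(records, config, fingerprint, warning)


def test_auc(
    gene_set: Sequence[str],
    train: LabeledDataset,
    test: LabeledDataset,
    config: IlrConfig | None = None,
) -> float:
    """ROC-AUC on held-out cells of a model fit on train restricted to ``gene_set``."""
    if len(gene_set) == 0:
        raise ValueError("gene_set must be non-empty")
    if len(np.unique(test.labels)) < 2:
        raise ValueError("AUC undefined for single-class test set")
    config = config or IlrConfig()
    tr = train.subset_genes(gene_set)
    te = test.subset_genes(gene_set)
    _check_training_input(tr.matrix, tr.labels)
    est = _make_estimator(config)
    est.fit(tr.matrix, tr.labels)
    proba = est.predict_proba(te.matrix)[:, 1]
    return float(roc_auc_score(te.labels, proba))


def f1_like(precision: float, auc: float) -> float:
    """Harmonic mean of gene-set precision and classification AUC:
    2*precision*AUC / (precision + AUC), with 0 when both terms are 0."""
    for name, v in (("precision", precision), ("auc", auc)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision + auc == 0:
        return 0.0
    return 2.0 * precision * auc / (precision + auc)
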