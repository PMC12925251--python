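"""Gene-set scoring, rank-sum baselines, overlap enrichment, and a
classifier-benchmark harness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Protocol, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # avoid a runtime import cycle with ilr.io
    from .io import LabeledDataset

__all__ = [
    "EvaluationMetrics",
    "OverlapTestResult",
    "rank_sum_pvalues",
    "gene_set_precision_recall",
    "wilcoxon_topk",
    "count_significant",
    "hypergeom_overlap",
    "bonferroni",
    "benchmark_harness",
    "SklearnClassifier",
    "default_classifiers",
    "evaluate_gene_set",
]

# groups at least this large use the tie-corrected normal approximation;
# smaller groups fall back to scipy's exact/auto method per gene
_ASYMPTOTIC_MIN_N = 20


@dataclass
class EvaluationMetrics:
    precision: float
    recall: float
    f1_like: float
    train_auc: float
    test_auc: float
    gene_set_size: int


@dataclass
class OverlapTestResult:
    overlap: int
    p_value: float
    p_adjusted: float
    universe_size: int
    setA_size: int
    setB_size: int


def _split_groups(matrix: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return matrix[labels == 0], matrix[labels == 1]


def rank_sum_pvalues(matrix: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test per gene column.

    Returns (statistics, p-values); the statistic is the U of group 1
    versus group 0.  Large groups (>= 20 each) use the tie-corrected
    normal approximation, vectorized across genes; small groups use
    scipy's exact method where tie-free.
    """
    matrix = np.asarray(matrix, dtype=float)
    g0, g1 = _split_groups(matrix, labels)
    if min(len(g0), len(g1)) >= _ASYMPTOTIC_MIN_N:
        res = stats.mannwhitneyu(g1, g0, axis=0, alternative="two-sided", method="asymptotic")
        return np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    statistics = np.empty(matrix.shape[1])
    pvalues = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        res = stats.mannwhitneyu(g1[:, j], g0[:, j], alternative="two-sided", method="auto")
        statistics[j], pvalues[j] = res.statistic, res.pvalue
    return statistics, pvalues


def gene_set_precision_recall(
    selected: Sequence[str], truth: Sequence[str]
) -> tuple[float, float]:
    """Set-intersection precision and recall of a selected gene list
    against the ground-truth DE genes."""
    selected_set, truth_set = set(selected), set(truth)
    if not selected_set:
        raise ValueError("selected gene set is empty")
    if not truth_set:
        raise ValueError("truth gene set is empty")
    hits = len(selected_set & truth_set)
    return hits / len(selected_set), hits / len(truth_set)


def wilcoxon_topk(dataset: "LabeledDataset", k: int) -> list[str]:
    """The k genes with smallest rank-sum P-value (ties broken by
    statistic distance from its null mean, then gene order)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > dataset.n_genes:
        raise ValueError(f"k={k} exceeds the {dataset.n_genes} genes available")
    statistics, pvalues = rank_sum_pvalues(dataset.matrix, dataset.labels)
    n0 = int(np.sum(dataset.labels == 0))
    n1 = int(np.sum(dataset.labels == 1))
    effect = np.abs(statistics - n0 * n1 / 2.0)
    order = sorted(range(dataset.n_genes), key=lambda j: (pvalues[j], -effect[j], j))
    return [dataset.gene_ids[j] for j in order[:k]]


def count_significant(dataset: "LabeledDataset", alpha: float = 0.05) -> int:
    """Number of genes with unadjusted rank-sum P below ``alpha``."""
    _, pvalues = rank_sum_pvalues(dataset.matrix, dataset.labels)
    return int(np.sum(pvalues < alpha))


def hypergeom_overlap(
    setA: Sequence[str], setB: Sequence[str], universe: Sequence[str]
) -> OverlapTestResult:
    """Upper-tail hypergeometric probability of the observed overlap
    between two gene lists drawn from a common universe."""
    universe_set = set(universe)
    A, B = set(setA), set(setB)
    if not A <= universe_set or not B <= universe_set:
        raise ValueError("both gene sets must be subsets of the universe")
    overlap = len(A & B)
    # P(X >= overlap) for X ~ Hypergeom(N=|U|, K=|A|, n=|B|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe_set), len(A), len(B)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return OverlapTestResult(overlap, p, p, len(universe_set), len(A), len(B))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """min(1, p * n_tests), order preserved."""
    p_values = list(p_values)
    n = len(p_values)
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError("p-values must be in (0, 1]")
    return [min(1.0, p * n) for p in p_values]


class ClassifierContract(Protocol):
    def fit(self, matrix: np.ndarray, labels: np.ndarray) -> None: ...

    def score_probabilities(self, matrix: np.ndarray) -> np.ndarray: ...


class SklearnClassifier:
    """Adapter giving any scikit-learn style estimator the harness contract.

    Scores come from predict_proba when available, otherwise
    decision_function, otherwise predict (covers PLS regression).
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, matrix: np.ndarray, labels: np.ndarray) -> None:
        self.estimator.fit(matrix, labels)

    def score_probabilities(self, matrix: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(matrix)[:, 1]
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(matrix)).ravel()
        return np.asarray(est.predict(matrix)).ravel()


def default_classifiers(seed: int = 0, n_features: int | None = None) -> dict[str, SklearnClassifier]:
    """The standard comparison panel: L2 logistic regression (C=0.1),
    linear SVC with hinge loss, decision tree (min_samples_split=10),
    random forest, and a 12-component PLS regression."""
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import LinearSVC
    from sklearn.tree import DecisionTreeClassifier

    n_comp = 12 if n_features is None else max(1, min(12, n_features - 1))
    return {
        "logistic_regression": SklearnClassifier(
            LogisticRegression(C=0.1, l1_ratio=0.0, solver="liblinear", random_state=seed)
        ),
        "linear_svc": SklearnClassifier(LinearSVC(loss="hinge", random_state=seed)),
        "decision_tree": SklearnClassifier(DecisionTreeClassifier(min_samples_split=10, random_state=seed)),
        "random_forest": SklearnClassifier(RandomForestClassifier(random_state=seed)),
        "pls": SklearnClassifier(PLSRegression(n_components=n_comp)),
    }


def benchmark_harness(
    train: "LabeledDataset",
    test: "LabeledDataset",
    gene_set: Sequence[str] | None,
    classifiers: Mapping[str, ClassifierContract],
) -> dict[str, float]:
    """Test-set ROC-AUC of each contract classifier trained on the train
    split restricted to ``gene_set`` (or all genes when None)."""
    from sklearn.metrics import roc_auc_score

    if gene_set is not None:
        train = train.subset_genes(gene_set)
        test = test.subset_genes(gene_set)
    results: dict[str, float] = {}
    for name, clf in classifiers.items():
        if not hasattr(clf, "fit") or not hasattr(clf, "score_probabilities"):
            raise TypeError(f"classifier {name!r} does not satisfy the contract")
        clf.fit(train.matrix, train.labels)
        scores = np.asarray(clf.score_probabilities(test.matrix), dtype=float).ravel()
        if np.ptp(scores) == 0:
            results[name] = 0.5  # constant predictions carry no ranking information
        else:
            results[name] = float(roc_auc_score(test.labels, scores))
    return results


def evaluate_gene_set(
    train: "LabeledDataset",
    test: "LabeledDataset",
    gene_set: Sequence[str],
    truth: Sequence[str],
    config=None,
) -> EvaluationMetrics:
    """Precision/recall against truth plus train/test AUC of the fitted set."""
    from .core import IlrConfig, f1_like, test_auc

    config = config or IlrConfig()
    precision, recall = gene_set_precision_recall(gene_set, truth)
    auc_train = test_auc(gene_set, train, train, config)
    auc_test = test_auc(gene_set, train, test, config)
    return EvaluationMetrics(
        precision=precision,
        recall=recall,
        f1_like=f1_like(precision, auc_test),
        train_auc=auc_train,
        test_auc=auc_test,
        gene_set_size=len(gene_set),
    )
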