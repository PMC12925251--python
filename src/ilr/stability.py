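"""Robustness diagnostics for a final gene set.

Three complementary views: (1) how stable each gene's coefficient rank
is under bootstrap resampling of cells; (2) how much held-out AUC is
lost when the gene is ablated from the model; (3) whether the two
importance orderings agree (Spearman), pooled across datasets with a
Fisher-z meta-analysis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .core import IlrConfig, fit_logistic, test_auc
from .io import LabeledDataset

__all__ = [
    "StabilityReport",
    "MetaAnalysisResult",
    "bootstrap_ranks",
    "ablation_auc_drop",
    "spearman_rank_agreement",
    "fisher_meta",
    "stability_report",
]


@dataclass
class StabilityReport:
    gene_set: list[str]
    rank_matrix: np.ndarray  # B x k, each row a permutation of 1..k
    median_ranks: np.ndarray
    ablation_auc_drop: np.ndarray
    spearman_rho: float
    spearman_p: float
    n_bootstraps: int

    def to_json(self) -> str:
        payload = asdict(self)
        for key in ("rank_matrix", "median_ranks", "ablation_auc_drop"):
            payload[key] = np.asarray(payload[key]).tolist()
        return json.dumps(payload, indent=1)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    def save_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tmedian_rank\tauc_drop\n")
            for g, r, d in zip(self.gene_set, self.median_ranks, self.ablation_auc_drop):
                fh.write(f"{g}\t{r:g}\t{d:.6g}\n")


@dataclass
class MetaAnalysisResult:
    pooled_r: float
    ci_low: float
    ci_high: float
    z_scores: list[float]
    weights: list[float]


def _coef_ranks(coefficients: np.ndarray) -> np.ndarray:
    """Ordinal ranks of |coefficient|: 1 = largest, ties by gene order."""
    order = np.argsort(-np.abs(coefficients), kind="stable")
    ranks = np.empty(len(coefficients), dtype=int)
    ranks[order] = np.arange(1, len(coefficients) + 1)
    return ranks


def bootstrap_ranks(
    train: LabeledDataset,
    gene_set: Sequence[str],
    B: int = 200,
    config: IlrConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient ranks over B stratified bootstrap refits.

    Each resample draws cells with replacement within each class
    (preserving class counts), refits the logistic model on ``gene_set``,
    and records the rank of every |coefficient| (1 = largest).  Returns
    the B x k rank matrix and the per-gene median ranks.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    config = config or IlrConfig()
    sub = train.subset_genes(gene_set)
    rng = np.random.default_rng(seed)
    class_rows = [np.flatnonzero(sub.labels == c) for c in (0, 1)]
    rank_matrix = np.empty((B, sub.n_genes), dtype=int)
    for b in range(B):
        for attempt in range(100):
            rows = np.concatenate(
                [rng.choice(rows_c, size=len(rows_c), replace=True) for rows_c in class_rows]
            )
            labels = sub.labels[rows]
            if len(np.unique(labels)) == 2:
                break
        else:  # pragma: no cover - stratified draws always keep both classes
            raise RuntimeError("could not draw a two-class bootstrap sample in 100 attempts")
        model = fit_logistic(sub.matrix[rows], labels, config, sub.gene_ids)
        rank_matrix[b] = _coef_ranks(model.coefficients)
    median_ranks = np.median(rank_matrix, axis=0)
    return rank_matrix, median_ranks


def ablation_auc_drop(
    train: LabeledDataset,
    test: LabeledDataset,
    gene_set: Sequence[str],
    config: IlrConfig | None = None,
) -> np.ndarray:
    """Held-out AUC of the full gene set minus the AUC with each single
    gene removed (positive drop = the gene helped)."""
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("ablation needs a gene set of at least 2 genes")
    config = config or IlrConfig()
    full = test_auc(gene_set, train, test, config)
    drops = np.empty(len(gene_set))
    for i in range(len(gene_set)):
        reduced = gene_set[:i] + gene_set[i + 1 :]
        drops[i] = full - test_auc(reduced, train, test, config)
    return drops


def spearman_rank_agreement(
    median_ranks: Sequence[float], drops: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho between median bootstrap rank and the rank of the
    ablation AUC drop (largest drop = rank 1), with two-sided p."""
    median_ranks = np.asarray(median_ranks, dtype=float)
    drops = np.asarray(drops, dtype=float)
    if len(median_ranks) != len(drops):
        raise ValueError("median_ranks and drops must have equal length")
    if len(drops) < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    drop_ranks = stats.rankdata(-drops)
    result = stats.spearmanr(median_ranks, drop_ranks)
    return float(result.statistic), float(result.pvalue)


def fisher_meta(
    correlations: Sequence[float],
    sample_sizes: Sequence[int],
    confidence: float = 0.95,
) -> MetaAnalysisResult:
    """Fixed-effect pooling of correlations via Fisher's z-transformation.

    z_i = atanh(r_i) weighted by (n_i - 3); the pooled estimate and its
    normal CI are transformed back with tanh.
    """
    correlations = np.asarray(correlations, dtype=float)
    sample_sizes = np.asarray(sample_sizes, dtype=int)
    if len(correlations) != len(sample_sizes) or len(correlations) == 0:
        raise ValueError("need matching, non-empty correlations and sample sizes")
    if np.any(np.abs(correlations) >= 1.0):
        raise ValueError("|r| must be < 1 for the z-transformation")
    if np.any(sample_sizes < 4):
        raise ValueError("each study needs n >= 4")
    z = np.arctanh(correlations)
    w = (sample_sizes - 3).astype(float)
    pooled_z = float(np.sum(w * z) / np.sum(w))
    se = 1.0 / np.sqrt(np.sum(w))
    crit = stats.norm.ppf(0.5 + confidence / 2.0)
    return MetaAnalysisResult(
        pooled_r=float(np.tanh(pooled_z)),
        ci_low=float(np.tanh(pooled_z - crit * se)),
        ci_high=float(np.tanh(pooled_z + crit * se)),
        z_scores=list(z),
        weights=list(w),
    )


def stability_report(
    train: LabeledDataset,
    test: LabeledDataset,
    gene_set: Sequence[str],
    B: int = 200,
    config: IlrConfig | None = None,
    seed: int = 0,
) -> StabilityReport:
    """Bootstrap ranks + ablation drops + their Spearman agreement."""
    rank_matrix, median_ranks = bootstrap_ranks(train, gene_set, B, config, seed)
    drops = ablation_auc_drop(train, test, gene_set, config)
    rho, p = spearman_rank_agreement(median_ranks, drops)
    return StabilityReport(
        gene_set=list(gene_set),
        rank_matrix=rank_matrix,
        median_ranks=median_ranks,
        ablation_auc_drop=drops,
        spearman_rho=rho,
        spearman_p=p,
        n_bootstraps=B,
    )
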