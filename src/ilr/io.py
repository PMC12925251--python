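"""Reading, writing and preparing labeled expression matrices.

Datasets are cells x genes with a binary condition label per cell
(0 = reference/control, 1 = perturbed/case).  Three on-disk layouts are
supported: delimited text (cells as rows, genes as columns, first column
the cell id, label in a named column or a sidecar TSV), MatrixMarket
coordinate triplets with ``genes.tsv``/``barcodes.tsv``/``labels.tsv``
sidecars, and h5ad with the label in a per-cell annotation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "load_dataset",
    "save_dataset",
    "normalize_counts",
    "prefilter_wilcoxon",
    "split_train_test",
    "qc_filter_cells",
]


@dataclass
class LabeledDataset:
    """A cells x genes expression matrix with one binary label per cell."""

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if scipy.sparse.issparse(self.matrix):  # pragma: no cover - asarray densifies
            self.matrix = self.matrix.toarray()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.matrix.shape
        if len(self.cell_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids and "
                f"{len(self.labels)} labels"
            )
        if len(self.gene_ids) != m:
            raise ValueError(f"matrix has {m} columns but {len(self.gene_ids)} gene ids")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "LabeledDataset":
        """Restrict to ``genes`` (kept in the order given)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        cols = [index[g] for g in genes]
        return LabeledDataset(
            self.matrix[:, cols], list(genes), list(self.cell_ids), self.labels.copy()
        )

    def subset_cells(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows)
        return LabeledDataset(
            self.matrix[rows],
            list(self.gene_ids),
            [self.cell_ids[i] for i in rows],
            self.labels[rows],
        )


@dataclass
class SplitSpec:
    """Train/test partition parameters.

    ``train_fraction`` in (0, 1); with ``stratified`` the per-class train
    proportions are within one cell of the overall fraction.
    """

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# load / save
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "mtx", "h5ad")


def load_dataset(
    path: str | os.PathLike,
    format: str | None = None,
    label_field: str = "label",
    label_file: str | os.PathLike | None = None,
) -> LabeledDataset:
    """Read a labeled expression dataset.

    Parameters
    ----------
    path
        File (csv/tsv/h5ad) or directory (mtx triplet + sidecars).
    format
        One of ``csv``, ``mtx``, ``h5ad``; inferred from the path when omitted.
    label_field
        Column (csv) or per-cell annotation (h5ad) holding the binary label.
    label_file
        Optional sidecar TSV with columns ``cell_id`` and ``label``;
        overrides ``label_field`` for csv input.
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "csv":
        return _load_csv(path, label_field, label_file)
    if format == "mtx":
        return _load_mtx(path)
    return _load_h5ad(path, label_field)


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    if suffix == ".h5ad":
        return "h5ad"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}")


def _load_csv(path: Path, label_field: str, label_file) -> LabeledDataset:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if label_file is not None:
        sidecar = pd.read_csv(label_file, sep="\t", index_col=0)
        labels = sidecar.iloc[:, 0].reindex(frame.index)
        if labels.isna().any():
            raise ValueError("label sidecar does not cover all cells")
    else:
        if label_field not in frame.columns:
            raise ValueError(f"label column {label_field!r} not found")
        labels = frame.pop(label_field)
    _check_binary(labels.to_numpy())
    return LabeledDataset(
        frame.to_numpy(dtype=float),
        list(frame.columns),
        [str(i) for i in frame.index],
        labels.to_numpy(dtype=int),
    )


def _load_mtx(path: Path) -> LabeledDataset:
    """MTX directory layout: matrix.mtx (cells x genes), genes.tsv,
    barcodes.tsv, labels.tsv."""
    if path.is_file():
        path = path.parent
    mat = scipy.io.mmread(path / "matrix.mtx")
    genes = _read_single_column(path / "genes.tsv")
    barcodes = _read_single_column(path / "barcodes.tsv")
    labels = np.array([_coerce_label(x) for x in _read_single_column(path / "labels.tsv")])
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    return LabeledDataset(np.asarray(mat, dtype=float), genes, barcodes, labels)


def _load_h5ad(path: Path, label_field: str) -> LabeledDataset:
    import anndata

    adata = anndata.read_h5ad(path)
    if label_field not in adata.obs.columns:
        raise ValueError(f"label annotation {label_field!r} not found in obs")
    labels = adata.obs[label_field].to_numpy()
    _check_binary(labels)
    X = adata.X
    if scipy.sparse.issparse(X):
        X = X.toarray()
    return LabeledDataset(
        np.asarray(X, dtype=float),
        list(adata.var_names),
        list(adata.obs_names),
        np.asarray(labels, dtype=int),
    )


def _check_binary(values: np.ndarray) -> None:
    uniq = set(pd.unique(pd.Series(values).dropna()))
    try:
        uniq = {int(v) for v in uniq}
    except (TypeError, ValueError):
        raise ValueError("labels must be binary (0/1)") from None
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary (0/1); found values {sorted(uniq)}")


def _coerce_label(x: str) -> int:
    try:
        v = int(float(x))
    except ValueError:
        raise ValueError("labels must be binary (0/1)") from None
    if v not in (0, 1):
        raise ValueError("labels must be binary (0/1)")
    return v


def _read_single_column(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def save_dataset(dataset: LabeledDataset, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a dataset in any supported format (inverse of :func:`load_dataset`)."""
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "csv":
        frame = pd.DataFrame(dataset.matrix, index=dataset.cell_ids, columns=dataset.gene_ids)
        frame.insert(0, "label", dataset.labels)
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        frame.to_csv(path, sep=sep, index_label="cell_id")
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(dataset.matrix)
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        _write_lines(path / "genes.tsv", dataset.gene_ids)
        _write_lines(path / "barcodes.tsv", dataset.cell_ids)
        _write_lines(path / "labels.tsv", [str(int(v)) for v in dataset.labels])
    elif format == "h5ad":
        import anndata

        adata = anndata.AnnData(
            X=dataset.matrix.copy(),
            obs=pd.DataFrame({"label": dataset.labels}, index=dataset.cell_ids),
            var=pd.DataFrame(index=dataset.gene_ids),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def _write_lines(path: Path, lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")


# ---------------------------------------------------------------------------
# normalization, prefilter, split
# ---------------------------------------------------------------------------


def normalize_counts(counts: np.ndarray, target_sum: float = 10_000.0) -> np.ndarray:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    Cells whose total is zero are passed through as all-zero rows.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = counts.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(counts * scale)


def normalize_dataset(dataset: LabeledDataset, target_sum: float = 10_000.0) -> LabeledDataset:
    return replace(dataset, matrix=normalize_counts(dataset.matrix, target_sum))


def prefilter_wilcoxon(dataset: LabeledDataset, alpha: float = 0.05) -> np.ndarray:
    """Indices of genes significant between the two classes after BH adjustment.

    A two-sided rank-sum test is run per gene; Benjamini-Hochberg adjusted
    P-values below ``alpha`` are retained, original gene order preserved.
    """
    from .evaluate import rank_sum_pvalues

    _require_two_classes(dataset.labels, min_per_class=2)
    _, pvals = rank_sum_pvalues(dataset.matrix, dataset.labels)
    if alpha <= 0:
        return np.empty(0, dtype=int)
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return np.flatnonzero(adjusted < alpha)


def _require_two_classes(labels: np.ndarray, min_per_class: int = 1) -> None:
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=2)
    if counts[0] < min_per_class or counts[1] < min_per_class:
        raise ValueError(
            f"both classes need at least {min_per_class} cells "
            f"(found {counts[0]} and {counts[1]})"
        )


def stratified_allocation(class_counts: Sequence[int], fraction: float) -> list[int]:
    """Per-class train counts: floors of ``fraction * n_c`` topped up by
    largest remainder (ties broken by class label order) to reach
    ``round(fraction * n)``."""
    quotas = [fraction * n for n in class_counts]
    take = [int(np.floor(q)) for q in quotas]
    total = int(round(fraction * sum(class_counts)))
    remainders = [q - t for q, t in zip(quotas, take)]
    order = sorted(range(len(take)), key=lambda c: (-remainders[c], c))
    i = 0
    while sum(take) < total and i < len(order):
        c = order[i]
        if take[c] < class_counts[c]:
            take[c] += 1
        i += 1
    return take


def split_train_test(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition cells into disjoint train/test sets, stratified by label."""
    _require_two_classes(dataset.labels, min_per_class=2)
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        classes = [0, 1]
        counts = [int(np.sum(dataset.labels == c)) for c in classes]
        takes = stratified_allocation(counts, spec.train_fraction)
        for c, take in zip(classes, takes):
            members = np.flatnonzero(dataset.labels == c)
            members = rng.permutation(members)
            train_idx.extend(members[:take])
            test_idx.extend(members[take:])
    else:
        perm = rng.permutation(dataset.n_cells)
        cut = int(round(spec.train_fraction * dataset.n_cells))
        train_idx = list(perm[:cut])
        test_idx = list(perm[cut:])
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)
    return dataset.subset_cells(np.array(train_idx)), dataset.subset_cells(np.array(test_idx))


# ---------------------------------------------------------------------------
# cell-level quality control
# ---------------------------------------------------------------------------


def qc_filter_cells(
    adata,
    min_genes: int = 200,
    max_genes: int = 8000,
    max_mito_fraction: float = 0.15,
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-", "Mt-"),
):
    """Standard scRNA-seq cell filters on an AnnData object.

    Removes cells expressing fewer than ``min_genes`` or more than
    ``max_genes`` genes, or with more than ``max_mito_fraction`` of counts
    from mitochondrial genes (identified by gene-name prefix).  Returns the
    filtered AnnData and the boolean keep-mask.
    """
    X = adata.X
    if scipy.sparse.issparse(X):
        genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        genes_per_cell = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
    mito = np.array([str(g).startswith(mito_prefixes) for g in adata.var_names])
    if mito.any():
        sub = X[:, mito]
        mito_counts = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.divide(mito_counts, totals, out=np.zeros_like(mito_counts, dtype=float), where=totals > 0)
    keep = (genes_per_cell >= min_genes) & (genes_per_cell <= max_genes) & (mito_frac <= max_mito_fraction)
    return adata[keep].copy(), keep
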