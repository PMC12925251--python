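"""Gene-set size selection by Pareto-front optimization.

Every iteration of the elimination loop yields one (AUC, size) point.
Both axes are min-max normalized to [0, 1]; the ideal point zeta sits at
maximum AUC and minimum size, i.e. (1, 0) in (auc_norm, size_norm)
coordinates.  The unpenalized optimum is the point at minimal Euclidean
distance dm from zeta.  A penalty epsilon widens the search to every
point within dm + epsilon and takes the smallest gene set among them,
whose distance is recorded as dp.  Repeating the whole procedure over
independently re-split data and keeping genes that recur builds a
consensus set.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import IlrConfig, Trajectory, run_ilr
from .io import LabeledDataset, SplitSpec, split_train_test

__all__ = [
    "ParetoSelection",
    "ConsensusConfig",
    "normalize_front",
    "select_pareto",
    "consensus_gene_set",
    "consensus_rounds",
]

_DIST_TOL = 1e-12  # float guard when comparing distances to dm + epsilon


@dataclass
class ParetoSelection:
    chosen_iteration: int
    zeta: tuple[float, float]
    dm: float
    epsilon: float
    dp: float
    normalized_points: list[tuple[float, float]]
    gene_set: list[str]
    size: int
    auc: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


@dataclass
class ConsensusConfig:
    """Consensus over repeated Pareto-optimized runs: ``rounds`` re-splits,
    genes appearing at least ``min_appearances`` times (default 6, i.e.
    strictly more than 5 of 10) enter the final set."""

    rounds: int = 10
    min_appearances: int = 6
    round_seed_base: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 1 <= self.min_appearances <= self.rounds + 1:
            raise ValueError("min_appearances must be in [1, rounds + 1]")


def normalize_front(trajectory: Trajectory) -> list[tuple[float, float]]:
    """Min-max normalize (cv_auc, size) per iteration.

    A constant axis is mapped to 0 for all points so selection is driven
    by the other axis; zeta is then (max auc_norm, min size_norm).
    """
    aucs = np.array([r.cv_auc for r in trajectory.records], dtype=float)
    sizes = np.array([r.size for r in trajectory.records], dtype=float)
    return list(zip(_minmax(aucs), _minmax(sizes)))


def _minmax(values: np.ndarray) -> list[float]:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return [0.0] * len(values)
    return list((values - lo) / (hi - lo))


def select_pareto(trajectory: Trajectory, epsilon: float = 0.0) -> ParetoSelection:
    """Pick the iteration closest to zeta, or the smallest set within
    dm + epsilon of it.

    Ties among equal-size candidates go to the higher AUC, then the
    earlier iteration.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if not trajectory.records:
        raise ValueError("trajectory is empty")
    points = normalize_front(trajectory)
    auc_norm = np.array([p[0] for p in points])
    size_norm = np.array([p[1] for p in points])
    zeta = (float(auc_norm.max()), float(size_norm.min()))
    dist = np.hypot(auc_norm - zeta[0], size_norm - zeta[1])
    dm = float(dist.min())
    candidates = np.flatnonzero(dist <= dm + epsilon + _DIST_TOL)
    sizes = np.array([trajectory.records[i].size for i in candidates])
    aucs = np.array([trajectory.records[i].cv_auc for i in candidates])
    best = min(
        range(len(candidates)),
        key=lambda j: (sizes[j], -aucs[j], candidates[j]),
    )
    chosen = int(candidates[best])
    record = trajectory.records[chosen]
    return ParetoSelection(
        chosen_iteration=record.iteration_index,
        zeta=zeta,
        dm=dm,
        epsilon=float(epsilon),
        dp=float(dist[chosen]),
        normalized_points=points,
        gene_set=list(record.gene_set),
        size=record.size,
        auc=record.cv_auc,
    )


def consensus_gene_set(
    trajectories: list[Trajectory],
    epsilon: float = 0.0,
    config: ConsensusConfig | None = None,
) -> list[tuple[str, int]]:
    """Count per-gene appearances across the per-round Pareto selections.

    Returns (gene, count) pairs with count >= ``min_appearances``, sorted
    by count descending then by gene order in the first trajectory.
    """
    config = config or ConsensusConfig()
    if len(trajectories) != config.rounds:
        raise ValueError(
            f"expected {config.rounds} trajectories, got {len(trajectories)}"
        )
    gene_order = {g: i for i, g in enumerate(trajectories[0].records[0].gene_set)}
    counts: dict[str, int] = {}
    for traj in trajectories:
        for gene in select_pareto(traj, epsilon).gene_set:
            counts[gene] = counts.get(gene, 0) + 1
    kept = [(g, c) for g, c in counts.items() if c >= config.min_appearances]
    kept.sort(key=lambda gc: (-gc[1], gene_order.get(gc[0], math.inf)))
    return kept


def consensus_rounds(
    dataset: LabeledDataset,
    ilr_config: IlrConfig | None = None,
    epsilon: float = 0.0,
    consensus: ConsensusConfig | None = None,
    train_fraction: float = 0.8,
) -> tuple[list[tuple[str, int]], list[Trajectory], list[ParetoSelection]]:
    """Run ``rounds`` independently re-split iLR rounds and build the consensus.

    Round r draws a fresh stratified train/test split and CV folds with
    seed ``round_seed_base + r``.
    """
    ilr_config = ilr_config or IlrConfig()
    consensus = consensus or ConsensusConfig()
    trajectories: list[Trajectory] = []
    selections: list[ParetoSelection] = []
    for r in range(consensus.rounds):
        seed = consensus.round_seed_base + r
        train, _ = split_train_test(dataset, SplitSpec(train_fraction, True, seed))
        cfg = IlrConfig(**{**asdict(ilr_config), "seed": seed})
        traj = run_ilr(train, cfg)
        trajectories.append(traj)
        selections.append(select_pareto(traj, epsilon))
    return consensus_gene_set(trajectories, epsilon, consensus), trajectories, selections
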