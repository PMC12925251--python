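import json

import numpy as np
import pytest
from scipy.optimize import minimize

from ilr import (
    IlrConfig,
    LogisticModel,
    Trajectory,
    f1_like,
    fit_logistic,
    normalize_dataset,
    rank_genes,
    retained_count,
    run_ilr,
    simulate_counts,
    split_train_test,
    test_auc as compute_test_auc,
)
from ilr.core import _cv_metrics
from ilr import SimulationConfig, SplitSpec

from conftest import gaussian_two_class, make_dataset


def reference_logistic_fit(X, y, C):
    """Independent convex-optimization fit of the liblinear objective:
    0.5*(||w||^2 + b^2) + C * sum log(1 + exp(-t(Xw + b))), t in {-1,+1}."""
    t = 2.0 * y - 1.0
    Xb = np.hstack([X, np.ones((len(y), 1))])

    def loss(wb):
        margins = t * (Xb @ wb)
        return 0.5 * wb @ wb + C * np.sum(np.logaddexp(0.0, -margins))

    res = minimize(loss, np.zeros(Xb.shape[1]), method="L-BFGS-B", tol=1e-12)
    return res.x[:-1], res.x[-1]


class TestFitLogistic:
    def test_zero_feature_gets_zero_coefficient(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 0.0
        y = (X[:, 0] > 0).astype(int)
        model = fit_logistic(X, y, IlrConfig())
        assert model.coefficients[1] == 0.0

    def test_all_zero_matrix_symmetric_solution(self):
        X = np.zeros((40, 4))
        y = np.repeat([0, 1], 20)
        model = fit_logistic(X, y, IlrConfig())
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-8)
        assert abs(model.intercept) < 1e-6

    def test_informative_feature_outranks_noise(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([y.astype(float), rng.normal(size=n)])
        config = IlrConfig(C=0.1)
        model = fit_logistic(X, y, config)
        w_ref, _ = reference_logistic_fit(X, y, config.C)
        # both routes agree the label-copy feature dominates ...
        assert abs(model.coefficients[0]) > abs(model.coefficients[1])
        assert abs(w_ref[0]) > abs(w_ref[1])
        # ... and on the coefficients themselves
        np.testing.assert_allclose(model.coefficients, w_ref, atol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones((5, 2)), np.zeros(5, dtype=int), IlrConfig())

    def test_nonfinite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_logistic(X, np.array([0, 0, 1, 1]), IlrConfig())

    def test_refit_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 10))
        y = rng.integers(0, 2, size=80)
        a = fit_logistic(X, y, IlrConfig())
        b = fit_logistic(X, y, IlrConfig())
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-6)


class TestRankGenes:
    def test_magnitude_order(self):
        model = LogisticModel(0.0, [0.5, -2.0, 0.1], ["g1", "g2", "g3"])
        assert rank_genes(model) == ["g2", "g1", "g3"]

    def test_ties_keep_input_order(self):
        model = LogisticModel(0.0, [0.3, 0.3, 0.3], ["a", "b", "c"])
        assert rank_genes(model) == ["a", "b", "c"]

    def test_column_permutation_permutes_ranking(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 8))
        y = rng.integers(0, 2, size=120)
        genes = [f"g{j}" for j in range(8)]
        ranking = rank_genes(fit_logistic(X, y, IlrConfig(), genes))
        perm = rng.permutation(8)
        permuted = rank_genes(
            fit_logistic(X[:, perm], y, IlrConfig(), [genes[j] for j in perm])
        )
        assert ranking == permuted


class TestRetainedCount:
    @pytest.mark.parametrize("m,frac,expected", [(100, 0.8, 80), (12, 0.8, 10), (2, 0.8, 1), (11, 0.8, 9), (1, 0.8, 1)])
    def test_values(self, m, frac, expected):
        assert retained_count(m, frac) == expected

    def test_always_shrinks_above_one(self):
        for m in range(2, 200):
            assert retained_count(m, 0.8) < m


class TestRunIlr:
    def test_size_schedule_forced_by_retention(self):
        ds = gaussian_two_class(30, 100, 5, 2.0, seed=4)
        traj = run_ilr(ds, IlrConfig(cv_folds=3))
        assert traj.sizes == [100, 80, 64, 52, 42, 34, 28, 23, 19, 16, 13, 11]

    def test_separable_data_perfect_cv_auc(self):
        ds = gaussian_two_class(40, 20, 20, 8.0, seed=5)
        traj = run_ilr(ds, IlrConfig(cv_folds=3))
        assert all(r.cv_auc == 1.0 for r in traj.records)

    def test_gene_sets_nested_and_strictly_shrinking(self):
        ds = gaussian_two_class(30, 50, 5, 1.0, seed=6)
        traj = run_ilr(ds, IlrConfig(cv_folds=3))
        for prev, nxt in zip(traj.records, traj.records[1:]):
            assert set(nxt.gene_set) < set(prev.gene_set)
            assert nxt.size < prev.size
        assert traj.sizes[-1] >= traj.config.min_genes
        assert traj.records[0].size == 50

    def test_permuted_labels_give_null_cv_auc(self):
        # random labels: iteration-0 CV AUC should sit in the null band
        rng = np.random.default_rng(7)
        inside = 0
        for seed in range(20):
            X = rng.normal(size=(500, 12))
            y = np.repeat([0, 1], 250)
            auc = _cv_metrics(X, y, IlrConfig(seed=seed))[1]
            inside += 0.4 <= auc <= 0.6
        assert inside >= 19

    def test_too_few_genes_single_record_with_warning(self):
        ds = gaussian_two_class(20, 5, 5, 2.0, seed=8)
        with pytest.warns(UserWarning, match="fewer than min_genes"):
            traj = run_ilr(ds, IlrConfig(cv_folds=3))
        assert len(traj.records) == 1 and traj.warning is not None

    def test_cv_auc_invariant_under_gene_permutation(self):
        ds = gaussian_two_class(30, 15, 3, 1.0, seed=9)
        rng = np.random.default_rng(10)
        perm = rng.permutation(ds.n_genes)
        shuffled = make_dataset(
            ds.matrix[:, perm], ds.labels, gene_ids=[ds.gene_ids[j] for j in perm],
        )
        a = run_ilr(ds, IlrConfig(cv_folds=3)).records[0]
        b = run_ilr(shuffled, IlrConfig(cv_folds=3)).records[0]
        assert a.cv_auc == pytest.approx(b.cv_auc, abs=1e-12)

    def test_json_round_trip(self, tmp_path):
        ds = gaussian_two_class(20, 15, 3, 1.5, seed=11)
        traj = run_ilr(ds, IlrConfig(cv_folds=3))
        path = tmp_path / "traj.json"
        traj.save(path)
        back = Trajectory.from_json(path.read_text())
        assert back.sizes == traj.sizes
        assert back.records[2].gene_set == traj.records[2].gene_set
        assert back.config == traj.config


class TestCoefficientShrinkage:
    def test_l2_norm_nonincreasing_with_stronger_regularization(self):
        ds = gaussian_two_class(60, 25, 5, 1.0, seed=12)
        norms = []
        for C in (1.0, 0.1, 0.01):
            model = fit_logistic(ds.matrix, ds.labels, IlrConfig(C=C))
            norms.append(np.linalg.norm(model.coefficients))
        assert norms[0] >= norms[1] >= norms[2]


class TestTestAuc:
    def test_single_class_test_set_rejected(self):
        train = gaussian_two_class(20, 5, 5, 2.0, seed=13)
        test = make_dataset(np.ones((4, 5)), [1, 1, 1, 1])
        with pytest.raises(ValueError, match="single-class test"):
            compute_test_auc(train.gene_ids, train, test)

    def test_separable_upper_bound(self):
        ds = gaussian_two_class(30, 10, 10, 8.0, seed=14)
        assert compute_test_auc(ds.gene_ids, ds, ds) == 1.0

    def test_empty_gene_set_rejected(self):
        ds = gaussian_two_class(10, 5, 5, 1.0, seed=15)
        with pytest.raises(ValueError, match="non-empty"):
            compute_test_auc([], ds, ds)


class TestF1Like:
    @pytest.mark.parametrize(
        "precision,auc,expected",
        [(1.0, 1.0, 1.0), (0.0, 0.9, 0.0), (0.5, 0.9, 2 * 0.45 / 1.4), (0.0, 0.0, 0.0)],
    )
    def test_closed_form(self, precision, auc, expected):
        assert f1_like(precision, auc) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_like(1.2, 0.5)


class TestRegularizationComparison:
    def test_l2_beats_l1_across_regularization_strengths(self):
        """Averaged over the C grid {1, 1e-1, ..., 1e-5} on scaled-down
        DE-scale x cell-count grids, ranking by L2 coefficients yields a
        better mean F1-like score (gene-set precision vs CV AUC) than
        ranking by L1 coefficients, which collapses to all-zero
        coefficients at strong regularization."""
        from ilr import gene_set_precision_recall, select_pareto

        C_grid = (1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
        wins = 0
        reps = 5
        for rep in range(reps):
            grids = []
            for scale in (0.1, 0.25, 0.5, 1.0):
                for n_cells in (100, 300):
                    sim = simulate_counts(SimulationConfig(
                        n_cells=n_cells, n_genes=100, de_scale=scale,
                        seed=1000 * rep + n_cells + int(scale * 100),
                    ))
                    ds = normalize_dataset(sim.to_labeled_dataset())
                    train, _ = split_train_test(ds, SplitSpec(0.8, True, rep))
                    grids.append((sim, train))
            means = {}
            for penalty in ("l2", "l1"):
                scores = []
                for sim, train in grids:
                    for C in C_grid:
                        traj = run_ilr(train, IlrConfig(C=C, penalty_type=penalty, cv_folds=3, seed=rep))
                        sel = select_pareto(traj, 0.0)
                        precision, _ = gene_set_precision_recall(sel.gene_set, sim.true_de_genes)
                        scores.append(f1_like(precision, sel.auc))
                means[penalty] = np.mean(scores)
            wins += means["l2"] >= means["l1"]
        assert wins > reps / 2
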