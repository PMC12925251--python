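# ilr — iterative logistic-regression marker-gene selection

`ilr` selects **small, informative marker-gene sets** that separate two
conditions (disease vs control, treated vs vehicle) in bulk or
single-cell RNA-seq expression data. Differential-expression tests rank
genes by significance but give no principled way to choose a *compact*
set; `ilr` instead couples a classifier to an explicit
size-vs-accuracy trade-off.

## Method

At each iteration an L2-penalized logistic model

```
logit(p) = b0 + b1 g1 + b2 g2 + ... + bm gm
```

is fitted to the training cells (inverse regularization strength
`C = 0.1` by default). Genes are ranked by |b_g|, the top 80% are kept,
and the loop repeats until fewer than 10 genes would remain. Five-fold
cross-validated accuracy and ROC-AUC are recorded at every iteration.

The trajectory of (AUC, gene-set size) points is then resolved by
**Pareto-front optimization**: both axes are min-max normalized to
[0, 1], the ideal point ζ sits at maximum AUC and minimum size, and the
unpenalized optimum is the iteration at minimal Euclidean distance d_m
from ζ. A penalty ε admits every point within d_m + ε and takes the
smallest gene set among them (its distance is d_p). Ten rounds on
independently re-split data, keeping genes selected in more than five
rounds, yield a consensus set.

The package also ships:

- a self-contained two-condition scRNA-seq **count simulator**
  (gamma gene means, lognormal libraries, negative-binomial noise,
  expression-dependent dropout, configurable DE scale factor / DE
  fraction / group imbalance) with ground-truth DE labels,
- evaluation utilities (gene-set precision/recall, an F1-like score
  `2·precision·AUC/(precision+AUC)`, a size-matched Wilcoxon rank-sum
  top-k baseline, a classifier benchmark harness, hypergeometric
  overlap enrichment with Bonferroni correction),
- stability diagnostics (200-fold bootstrap coefficient-rank stability,
  one-gene-ablation ΔAUC, Spearman agreement, Fisher-z meta-analysis).

## Worked example

```python
from ilr import (IlrConfig, SimulationConfig, SplitSpec, normalize_dataset,
                 run_ilr, select_pareto, simulate_counts, split_train_test,
                 test_auc, gene_set_precision_recall)

sim = simulate_counts(SimulationConfig(n_cells=2000, n_genes=1202,
                                       de_scale=0.25, seed=1))
data = normalize_dataset(sim.to_labeled_dataset())      # 1e4 + log1p
train, test = split_train_test(data, SplitSpec(0.8, True, seed=1))

trajectory = run_ilr(train, IlrConfig(C=0.1, seed=1))
selection = select_pareto(trajectory, epsilon=0.0)
auc = test_auc(selection.gene_set, train, test)
precision, recall = gene_set_precision_recall(selection.gene_set,
                                              sim.true_de_genes)
print(f"iterations: {len(trajectory.records)}, "
      f"chosen size: {selection.size} at iteration {selection.chosen_iteration}")
print(f"held-out AUC: {auc:.3f}, precision: {precision:.3f}, recall: {recall:.3f}")
```

prints

```
iterations: 23, chosen size: 105 at iteration 11
held-out AUC: 0.950, precision: 0.533, recall: 0.467
```

i.e. from 1202 genes (120 truly DE at a modest log2-fold-change scale of
0.25) the elimination loop produced 23 nested candidate sets; the Pareto
optimum kept 105 genes (~9% of the input), classifies held-out cells
with AUC 0.95, and roughly half of the chosen genes are true DE genes.
Raising `epsilon` trades AUC for smaller sets; `consensus_rounds`
stabilizes the selection across re-splits.

The same pipeline is available from a shell:

```
ilr simulate --preset fig2_grid --out-dir grids/ --seed 1
ilr run grids/cells2000_scale0.25_p0.5 --rounds 10 --epsilon 1 \
    --out-dir results/ --seed 1
ilr benchmark grids/ --out-tsv metrics.tsv --seed 1
ilr stability <dataset> <gene_set.txt> -B 200 --out-dir stab/ --seed 1
ilr enrich gene_set.txt reference.txt universe.txt
```

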