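# aconas

Ant-colony architecture search for regularized feed-forward classifiers on
gene-expression matrices.

Given a samples × genes expression matrix (log2 scale) and per-sample class
labels, `aconas`:

1. filters genes with a one-vs-rest differential-expression gate
   (Welch t-test **and** Wilcoxon rank-sum, Benjamini–Hochberg FDR,
   |log2 fold-change| > 1 and Q < 0.05 by default);
2. searches a layered graph of network hyperparameters — epochs, optimizer,
   learning rate, depth, and per-layer width / activation / dropout /
   batch-norm / L1 / L2 — with pheromone-guided ants. A gradient-boosted-tree
   surrogate is re-fit each iteration on the one-hot/numeric hybrid encodings
   of all evaluated candidates; its per-column feature importances (scaled by
   fit quality) become the edge heuristics, and only the globally best
   candidate deposits pheromone;
3. scores every candidate by stratified cross-validated accuracy of a
   pure-numpy MLP (dense → batch-norm → activation → dropout blocks, softmax
   head, L1/L2-penalized cross-entropy, early stopping on validation
   accuracy);
4. reports confusion matrices, per-class and macro sensitivity/specificity/
   accuracy, and Wilcoxon-ranked marker genes per class.

A synthetic-data generator (multiclass Gaussian background with planted
class-informative genes) makes every stage testable without downloads.

## CLI

```sh
# synthetic 4-class dataset with 8 informative genes per class
aconas simulate --out sim/ --n-classes 4 --n-per-class 45 --n-genes 300 \
    --n-informative 8 --effect 2.5 --seed 3

# differential gene filter
aconas select-degs --expr sim/expression.tsv --labels sim/labels.tsv \
    --fc 1.0 --q 0.05 --out degs.tsv

# architecture search (config optional; see RunConfig fields)
aconas search --expr sim/expression.tsv --labels sim/labels.tsv \
    --genes degs.genes.txt --config cfg.yaml --out run/

# train / predict / evaluate a single architecture
aconas train --expr sim/expression.tsv --labels sim/labels.tsv \
    --arch arch.json --out run2/ --seed 1
aconas predict --model run/best_model --expr sim/expression.tsv --out preds.tsv
aconas evaluate --model run/best_model --expr sim/expression.tsv \
    --labels sim/labels.tsv --out report.json --markers markers.tsv
```

Every subcommand writes a `manifest.json` (tool version, config hash, input
checksums, seed, timestamp) before any other artifact, and a single `--seed`
fans out to derived per-component seeds so runs are reproducible end to end.

Expression files are tab-separated (UTF-8, `.` decimal) with a `sample_id`
first column; `--orientation genes_in_rows` style transposed matrices are
supported by the library loader. Values are assumed already
log2-transformed/normalized — nothing is re-normalized.

A `cfg.yaml` for `search` may override any pool or optimizer constant:

```yaml
pools:
  epochs_choices: [40]
  optimizer_choices: [adam, sgd]
  lr_choices: [0.01, 0.001]
  depth_choices: [1, 2]
  width_choices: [16, 32]
  activation_choices: [relu, tanh]
  dropout_choices: [0.0]
  bn_choices: [false]
  l1_choices: [0.0]
  l2_choices: [0.0]
aco: {population_size: 5, iterations: 5, surrogate_trees: 100}
cv_folds: 3
seed: 5
```

## Package layout

| module | contents |
| --- | --- |
| `aconas.data_io` | TSV/CSV matrix and label readers/writers, config, run report, logging |
| `aconas.synthetic` | planted-signal and null dataset generators |
| `aconas.deg` | one-vs-rest t-test + rank-sum filter with BH adjustment |
| `aconas.search_space` | hyperparameter pools, hybrid encoding, layered search graph |
| `aconas.network` | numpy MLP: forward/backward, BN, dropout, penalized loss, training |
| `aconas.aco` | transition rule, pheromone updates, surrogate heuristics, search driver |
| `aconas.evaluation` | confusion/metrics, leakage-safe stratified CV, marker ranking |
| `aconas.cli` | `aconas` entry point binding the pipeline |
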