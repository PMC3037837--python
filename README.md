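# generank

Hybrid gene selection for two-class expression studies, as a tested library
and CLI:

1. **Fisher filtering** — rank genes by `(m1 − m2)² / (s1² + s2²)` and keep
   the top *k* (default 500).
2. **Redundancy reduction** — greedy pruning of the ranking against a
   pairwise similarity that averages Pearson expression correlation (|r|)
   with Lin-style GO semantic similarity (information content from the
   annotation corpus, most-informative-common-ancestor sharing); pairs
   lacking annotations fall back to expression similarity alone. Default
   threshold `ts = 0.8`, tunable over the grid 0.10–0.95 (step 0.05).
3. **SVM-RFE** — recursive feature elimination by squared linear-SVM
   weights, with the final subset chosen as the smallest nested prefix that
   maximizes internal cross-validated accuracy on training data.

Evaluation uses **external 10-fold cross-validation**: the entire selection
pipeline reruns inside each training fold, so held-out samples never
influence gene selection. A deliberately biased internal protocol
(selection once on all data) is included only to demonstrate the optimism
it produces on pure-noise data.

A synthetic-data module generates matrices with planted differential genes,
planted redundant near-copy groups, and a toy ontology whose annotations
mirror the redundancy structure, so every stage is testable without any
external downloads.

## Layout

| module                      | contents                                              |
|-----------------------------|-------------------------------------------------------|
| `generank.io_core`          | expression/OBO/annotation parsing, preprocessing      |
| `generank.fisher_filter`    | Fisher score and ranking                              |
| `generank.go_semantics`     | term frequency, IC, Share, Lin, gene-level similarity |
| `generank.redundancy`       | combined similarity, greedy reduction, ts tuning      |
| `generank.svmrfe`           | linear SVM contract, RFE, best-subset selection       |
| `generank.evaluation_cv`    | external/internal CV, metrics, variant registry       |
| `generank.synthetic_data`   | generators, fixtures, ground truth                    |

## CLI

Simulate a dataset, then run the full pipeline on it:

```bash
generank simulate --preset duplicates_heavy --seed 3 --out sim/
generank run \
  --expr sim/expr.tsv --labels sim/labels.tsv \
  --obo sim/go.obo --annot sim/ann.tsv \
  --variant fisher_rg_svmrfe --filter-k 500 --ts 0.8 \
  --folds 10 --seed 42 --out outdir/
```

Outputs: `outdir/selected_genes.tsv` (gene, per-fold selection frequency,
rank in the final whole-data selection), `outdir/report.json` (per-fold and
aggregate accuracy/sensitivity/specificity plus the config echo), and
`outdir/run.log`.

Variants: `none`, `fisher`, `svmrfe`, `fisher_r`, `fisher_rg`, `svmrfe_r`,
`svmrfe_rg`, `fisher_svmrfe`, `fisher_r_svmrfe`, and the full
`fisher_rg_svmrfe` (`_r` = expression-only redundancy reduction, `_rg` =
combined expression + GO).

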