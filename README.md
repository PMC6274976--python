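# exprules

Contrasting cell-type expression patterns of lncRNAs (positive class) and
mRNAs (negative class) from a labeled gene × feature table of per-cell-facet
maximum-CPM values: expression-specificity scoring, mutual-information
feature ranking, incremental feature selection with cross-validated
performance curves, interpretable rule induction, and a randomized
feature-subset significance test.

## What's inside

| Module | Purpose |
| --- | --- |
| `exprules.feature_table` | Labeled gene × feature table model, validation, TSV/CSV I/O, column slicing |
| `exprules.specificity` | Chao–Shen coverage-corrected Shannon entropy (bits) of a CPM profile and the derived specificity score `1 − H/log2(K)` |
| `exprules.mrmr` | 3-state discretization (mean ± α·sd), discrete mutual information, MaxRel and greedy mRMR (MID) feature ranking |
| `exprules.model_eval` | Classifier contracts (random forest, RIPPER, 1-NN, linear SVM, logistic), stratified k-fold CV with pooled confusion counts, SN/SP/ACC/MCC |
| `exprules.ripper` | From-scratch RIPPER rule learner: FOIL-gain growing, reduced-error pruning, MDL stopping, optimization passes; rule text parse/format; first-match application |
| `exprules.ifs` | Incremental feature selection curves over a ranked list, optimal-point/threshold-crossing extraction, anchored random-subset null distribution and sigma excess |
| `exprules.synthetic` | Zero-inflated log-normal table generator with planted informative facets, plus the transcribed 18-rule reference ruleset fixture |
| `exprules.pipeline` / `exprules.cli` | End-to-end orchestration with a manifest; `click` CLI |

## CLI

```bash
# generate a synthetic labeled table (writes a .truth.json sidecar)
exprules simulate --out scratch/table.tsv --n-pos 800 --n-neg 1200 --effect-log2 4 --seed 1

# rank features (mRMR or MaxRel)
exprules rank --input scratch/table.tsv --out scratch/ranking.tsv --criterion mrmr

# incremental feature selection with a chosen classifier
exprules ifs --input scratch/table.tsv --out scratch/ifs.tsv --classifier random_forest --folds 10

# learn / apply an ordered ruleset
exprules rules --input scratch/table.tsv --out scratch/rules.txt
exprules rules --input scratch/table.tsv --out scratch/rules.txt --apply scratch/table.tsv

# anchored random-subset significance test
exprules signif --input scratch/table.tsv --out scratch/null.tsv \
    --anchor "Expression specificity" --subset-size 13 --n-iter 1000

# everything at once (YAML config optional, flags override)
exprules run-all --input scratch/table.tsv --out scratch/run --seed 1
```

`run-all` writes ranked lists, per-classifier IFS tables, an optimal-point
summary (algorithm, n_features, SN, SP, ACC, MCC), the learned ruleset, the
null distribution with a box-plot summary, and a `manifest.json` tying the
outputs to the config and seed.

## Conventions

* Labels: `lncRNA` = positive, `mRNA` = negative (case-insensitive in files).
* Feature indices are 0-based in code, 1-based in reports.
* Entropies are in bits; specificity is clamped to [0, 1].
* All stochastic stages (folds, bootstrap, subset draws, grow/prune splits)
  derive from one explicit seed; repeated runs are bit-identical.
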