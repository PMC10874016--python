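# cppuptake

Quantitative prediction of cell-penetrating peptide (CPP) uptake.

CPPs are short (≈4–40 residue), usually arginine/lysine-rich peptides that
cross cell membranes and ferry cargo — fluorophores, nucleic acids,
proteins, nanoparticles — into cells. Most published predictors only
classify a sequence as CPP / non-CPP. This package targets the harder,
more useful question: **how much** peptide is internalized, as a
regression on log10 of the experimentally measured uptake, conditioned on
the peptide sequence, its cargo(es), the cell line, and the assay
conditions (concentration, temperature, incubation time).

It provides, as composable sklearn-style estimators plus a CLI:

* **Featurization** (`CPPFeaturizer`): 2,908 columns in frozen blocks —
  31 whole-peptide physicochemical descriptors (mass, net charge at pH 7,
  pI, aliphatic/Boman/instability indices, hydrophobicity and helical /
  sheet hydrophobic moments, and the Kidera-10 / Cruciani-3 / Z-scale-5 /
  MS-WHIM-3 scale means), a 100-position × 20-residue one-hot encoding,
  a 70-column anomalous-residue block (24 position + 46 substitution-type
  flags, fed by a 56-entry substitution vocabulary for D-residues and
  bracketed modifications such as `[Orn]`), 735 cell-line gene-mutation
  indicators + an exact-match flag joined from a GDSC-style table, and
  71 experimental-condition columns (concentration, 5-category
  temperature, incubation availability/duration, 63-label cargo
  multi-hot).
* **Benchmark curation** (`cppuptake.curation`): unit harmonization, six
  ordered filters with per-step row accounting, log10 target transform,
  Tukey-fence outlier removal, null-variance pruning, a seeded 70–30
  split (train size = ⌊0.7·n⌋) and z-scoring with train-fitted
  statistics; plus feature–target Pearson ranking.
* **A nine-model regression zoo** (`cppuptake.models`): SVM, SGD, k-NN,
  decision tree, random forest, extremely randomized trees,
  gradient-boosted trees (xgboost), a deep MLP, and a **forked neural
  network** — a multi-branch net with a separate input branch per feature
  block merged into a shared trunk — implemented in numpy with full
  hyperparameter grids, seeded search, and a six-metric evaluation
  (RMSE, MSE, MAE, Pearson, Spearman, r²).
* **A synthetic-data generator** (`cppuptake.synthetic_data`) that
  emulates the statistical shape of curated uptake collections, injects
  controlled dirty rows for every curation filter, and plants a known
  linear signal (net charge, length, concentration, one gene, one cargo)
  whose noise is calibrated to a best-achievable r² of 0.85 — so the
  whole pipeline is testable end to end with no downloads.

## Worked example

Generate a synthetic benchmark, curate it, featurize, split, and train
gradient-boosted trees:

```python
import numpy as np
from cppuptake.synthetic_data import GeneratorSpec, generate_dataset
from cppuptake.curation import (apply_benchmark_filters, transform_target,
    remove_null_variance, split_and_normalize, SplitSpec,
    rank_feature_correlations)
from cppuptake.pipeline import CPPFeaturizer
from cppuptake.models import ModelConfig, build_model, evaluate

ds = generate_dataset(GeneratorSpec(n_records=1300, seed=42))
survivors, report = apply_benchmark_filters(ds.records)
print("curation counts:", report.counts_after)

fz = CPPFeaturizer(genomics_table=ds.genomics_table).fit(survivors)
fm = fz.transform(survivors)
fm.target = np.array([transform_target(r.uptake_value) for r in survivors])
pruned, _ = remove_null_variance(fm)
train, test, stats = split_and_normalize(pruned, SplitSpec(seed=42))

feats = [c for c in train.columns if c != "target"]
model = build_model(
    ModelConfig("gradient_boosted_trees",
                {"n_estimators": 100, "max_depth": 5, "learning_rate": 0.15,
                 "booster": "gbtree", "alpha": 1, "lambda": 3, "gamma": 0},
                seed=42),
    schema=fm.schema)
model.fit(train[feats].to_numpy(), train["target"].to_numpy())
for name, df in (("train", train), ("test", test)):
    m = evaluate(model, df[feats].to_numpy(), df["target"].to_numpy(), name)
    print(f"{name}: rmse={m.rmse:.3f} mae={m.mae:.3f} "
          f"pearson={m.pearson:.3f} spearman={m.spearman:.3f} r2={m.r2:.3f}")
print(rank_feature_correlations(fm).head(5)[
    ["feature", "block", "pearson_r"]].to_string(index=False))
```

Output:

```
curation counts: [1274, 1235, 1209, 1196, 1183, 1146]
train: rmse=0.216 mae=0.160 pearson=0.992 spearman=0.990 r2=0.983
test: rmse=0.895 mae=0.706 pearson=0.832 spearman=0.831 r2=0.692
         feature         block  pearson_r
  net_charge_ph7 whole_peptide   0.435942
           G0001      genomics   0.403398
molecular_weight whole_peptide   0.401463
      cargo_FITC         cargo   0.392462
concentration_uM concentration   0.390479
```

Reading it: of 1,300 generated rows the six filters keep 1,146 (each
count is "rows remaining after that filter"); the model then recovers
most of the recoverable signal — the generator's noise ceiling is
r² = 0.85, and the test r² of 0.69 with Pearson 0.83 reflects honest
out-of-sample performance, while the train/test gap shows the expected
overfitting direction for boosted trees. The correlation ranking
rediscovers the five planted drivers (net charge, the planted gene,
length via molecular weight, the cargo flag, concentration) at the top.

The same workflow is available from the shell:

```bash
cppuptake synth --n 1300 --seed 42 --out raw.csv --genomics-out genomics.csv
cppuptake curate --in raw.csv --out bench.csv --report report.csv
cppuptake pipeline --bench raw.csv --genomics genomics.csv \
    --model gradient_boosted_trees --seed 42 --out run/
cppuptake train --bench raw.csv --genomics genomics.csv --seed 42 --out trained/
cppuptake predict --artifact trained/artifact --fasta peptides.fa --out preds.csv
```

Every command appends a JSON manifest entry (seeds, config hash,
per-stage counts), so any result is regenerable from its artifacts.

## Layout

```
src/cppuptake/
  schema_io.py       dataset schema, CSV/FASTA/feature-matrix I/O
  descriptors.py     the 31 whole-peptide descriptors + scale tables
  encoders.py        anomaly substitution, one-hot/multi-hot blocks
  genomics.py        cell-line mutation join with tissue-proxy fallback
  pipeline.py        CPPFeaturizer and feature-schema assembly
  curation.py        filters, split, normalization, correlation ranking
  models.py          model zoo, grids, search, metrics, predictor bundle
  _nn.py             numpy deep + forked network estimators
  synthetic_data.py  generator with planted signal and dirty-row injection
  cli.py             `cppuptake` console entry points
  data/              scale tables and synthetic default vocabularies
docs/methods.md      model and design documentation
```
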