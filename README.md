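# cycloqsar

QSAR modeling pipeline for a 93-compound series of cyclopamine-derivative
Hedgehog-pathway inhibitors assayed against four tumor cell lines
(BxPC-3, NCI-H446, SW1990, NCI-H157). The package implements the full
study design:

- **Descriptors** — two competing sets: `general` physicochemical
  descriptors (Wildman–Crippen logP/MR, Labute approximate surface area
  and its SlogP/SMR/PEOE VSA partitions, Gasteiger charge statistics) and
  a topological `drug_like_index` set (rings, ring systems, linkers,
  framework, side chains, and a scalar index).
- **Dataset division** — a greedy max-min *Diverse Subset* ranking in
  normalized descriptor space with a 65/35 round-half-up split, and a
  *cluster + diverse* variant that ranks and splits each k-means cluster
  separately (93 compounds divide 60/33 globally, 61/32 under the
  clustered scheme).
- **Models** — PLS regression (NIPALS with a condition limit on the
  latent-component transform), RBF support-vector regression, an RBF SVM
  classifier, and a binary Bayesian classifier built from
  Gaussian-smoothed class-conditional descriptor histograms. Regression
  targets are log10 IC50; classifiers see activity binarized at the
  positive control's (cyclopamine's) IC50 per cell line.
- **Evaluation** — R2/Q2/RMSE and r2 (training self-fit, leave-one-out
  cross-validation, independent test) for regression; At/Av/Ap accuracies
  for classification; σ columns (drug-like minus general) per results
  grid; a paired t-test comparing the two division schemes over all grid
  cells. The printed grids of the original study ship as package data
  (`cycloqsar.evaluation.load_reference_grids`) and their σ arithmetic is
  reproduced exactly, 95/96 cells at 3 decimals — the one exception is a
  sign typo in the source table (see `analysis/05_reference_sigma_check.py`).
- **SAR suggestion engine** — enumerates single-point R-group *chimeras*
  within each scaffold, scores them by predicted activity gain over the
  average input molecule, weights by structural support, and reports a
  ranked mutation table (e.g. "demethylation at position 8").
- **Synthetic library generator** — because the original structures and
  proprietary descriptors are unavailable, a seeded generator emulates the
  dataset's statistical shape: 93 compounds over four close-analogue
  scaffolds plus six off-scaffold decoys, four cell lines of which exactly
  one (the NCI-H446 analogue) carries a descriptor-driven signal, with the
  most beneficial planted modification being demethylation at position 8.

## Worked example

```python
import numpy as np
from cycloqsar import (
    CYCLOPAMINE_IC50, GeneratorConfig, generate_library,
    build_matrix, normalize, rank_diverse, split_by_rank,
    binarize, fit_binary_bayes,
)

library, truth = generate_library(GeneratorConfig(seed=0))
raw = build_matrix(library, "general")
norm, _ = normalize(raw)
split = split_by_rank(rank_diverse(norm), 0.65)
print(f"library: {len(library)} compounds, "
      f"train {len(split.train_indices)} / test {len(split.test_indices)}")

labels = binarize(library, "NCI-H446", CYCLOPAMINE_IC50["NCI-H446"])
y = np.asarray(labels.labels)
tr, te = split.train_indices, split.test_indices
model = fit_binary_bayes(raw.values[tr], y[tr])
ap = (model.predict(raw.values[te]) == y[te]).mean()
print(f"binary Bayes Ap on NCI-H446: {ap:.3f} "
      f"({(model.predict(raw.values[te]) == y[te]).sum()}/{len(te)})")
```

Output:

```
library: 93 compounds, train 60 / test 33
binary Bayes Ap on NCI-H446: 0.909 (30/33)
```

The suggestion engine on the same library (see
`analysis/04_sar_suggestions.py`) prints:

```
mean input P(active) = 0.430
 rank  parent scaffold                     mutation  percent_gain  weight                  smiles
    1 CPD-076       S1  demethylation at position 8        56.677   0.400      OC1CCC(c2ccccc2)O1
    2 CPD-063       S2  demethylation at position 8        56.294   0.392     COC1CCC(c2cccnc2)O1
    3 CPD-045       S3  demethylation at position 8        56.858   0.323      OC1CCC(c2ccncc2)O1
```

recovering the planted ground truth that removing the position-8 methyl
is the most efficient activity-improving modification.

## Command line

```
cycloqsar generate --seed 0 --out results/fixture   # synthetic fixture
cycloqsar run --seed 0 --out results/run            # full study
cycloqsar suggest --top-n 10                        # SAR suggestions only
cycloqsar report --run-dir results/run              # re-render grids
```

`cycloqsar run` writes per-division results grids with σ columns
(`grid_*.csv`, `sigma_*.csv`), the division-scheme paired t-test
(`ttest.json`), the ranked suggestion table (`suggestions.csv`) and a
replayable `manifest.json`.

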