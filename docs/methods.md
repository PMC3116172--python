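# Methods

This note records the modeling choices, parameters and numerical
conventions of the package, the scope of the synthetic data generator,
and known limitations. Nothing here claims empirical results beyond what
the shipped scripts and tests compute.

## Data model

A compound is a molecular graph plus IC50 measurements (µg/mL) against
the four study cell lines (BxPC-3, NCI-H446, SW1990, NCI-H157); missing
measurements are explicit (`None`). Record order is significant: the
diversity ranking is seeded from the first record. Activity is binarized
per cell line against the positive control cyclopamine's IC50
(38.11, 9.13, 61.05, 58.33 µg/mL respectively); a compound is *active*
iff its IC50 is ≤ the cut-off (the boundary counts active). Regression
targets are log10 IC50.

## Descriptors

`general`: Wildman–Crippen SlogP and SMR, Labute approximate surface
area, the 12/10/14-bin SlogP_VSA / SMR_VSA / PEOE_VSA partitions, and
four Gasteiger charge statistics (positive and negative charge sums,
extreme charges) computed on the hydrogen-complete graph with 12
equilibration sweeps. These are open published analogues of the
commercial 2D descriptor set used in the original study; exact parity
with the proprietary implementations is not claimed.

`drug_like_index`: counts of SSSR rings, fused ring systems (rings merged
when sharing an atom), Murcko-framework atoms, linker atoms (acyclic
framework atoms), side-chain atoms, and a scalar index
`DLI = Σ log2(1 + count)` combining the five counts on a diminishing
scale. The scalar is a reconstruction — the original "drug-like index"
formula is not published.

Normalization: per-column z-score over the *full* library (computed
before division, since the max-min ranking must see all compounds in a
common metric); zero-variance columns are dropped and recorded.

## Dataset division

*Diverse subset*: greedy max-min ranking — rank 1 is the first record;
each later rank goes to the unranked compound maximizing its minimum
Euclidean distance (in normalized descriptor space) to the ranked set,
ties broken to the lowest original index. The first
`floor(0.65·N + 0.5)` ranked compounds train, the rest test: 60/33 for
N = 93.

*Cluster + diverse subset*: seeded k-means (k ≈ N/20, minimum 2; 10
restarts, fixed random state) stands in for the original software's
undocumented clustering; labels are relabeled by first occurrence so the
partition is deterministic. Each cluster is ranked and split with the
same rule (singletons go to training). Cluster sizes (21, 20, 18, 17, 17)
give the 61/32 split implied by the published accuracy denominators
(e.g. 29/32 = 0.906).

## Models

**PLS** — NIPALS PLS1 on z-scored predictors and centered response.
Component accrual stops when: residual covariance ‖X'y‖ falls below
1e−12 of its initial value; score variance t't ≤ 1e−12; the response
residual falls below 1e−13 of its initial sum of squares; an explicit
component cap is hit; or the ratio (t1't1)/(tk'tk) exceeds the condition
limit (default 1e6). The last rule is this package's realization of the
original "condition limit on the principal-component transform"; the
exact proprietary formulation is unrecoverable.

**SVR / SVM** — RBF-kernel ε-insensitive support-vector regression
(C = 1, ε = 0.1) and soft-margin SVC (C = 1), both on z-scaled features
with γ = 1/p by default, delegated to scikit-learn (libsvm); results are
deterministic. A constant regression response yields a constant
predictor; single-class classification training is an error.

**Binary Bayes** — per descriptor, training values are min-max
normalized to [0, 1] over the training range and histogrammed per class
over 25 equal bins. Each histogram is convolved with a discrete Gaussian
kernel (σ = 0.25 in normalized-range units, i.e. σ·25 bins; support
−25…+25 bin offsets, kernel normalized to unit sum), floored at 1e−9 and
renormalized. Prediction clamps query values into the training range
(clamp events are counted), combines per-descriptor log-likelihoods
under the naive independence assumption with the class priors via
log-sum-exp, and labels active when P(active) > 0.5. By construction
P(active) + P(inactive) = 1.

**Evaluation** — R2/Q2/r2 are squared Pearson correlations (defined as 0
when either vector is constant); Q2/RMSE come from leave-one-out
cross-validation on the training set; r2/Ap from the untouched test set.
Classification accuracies retain integer numerators/denominators. LOO
folds whose remaining labels are single-class predict that majority
class instead of refitting.

## Results grids, σ, and scheme comparison

A results grid holds one value per (model, metric, cell line, descriptor
set) for one division scheme. σ = drug-like − general per cell; display
rounds to 3 decimals and marks the per-cell-line best Ap with an
asterisk. The published grids of the original study are shipped as
package data; recomputing σ from their own operands reproduces 95 of 96
printed values exactly at 3 decimals — the one exception
(diverse/SVR/R2/BxPC-3) is printed with the opposite sign of its own
operands' difference, and magnitudes agree.

The two division schemes are compared with a two-sided paired t-test
whose pairing universe is every non-σ cell present in both grids (96
cells for the full study). A zero-variance difference vector is reported
as degenerate with no numeric p. On the published grids this test gives
t = 0.952, p = 0.344 over 96 pairs — the same qualitative conclusion as
the original report (no significant difference between schemes at 0.05),
though the originally printed p-value was computed over an unstated
pairing universe and is not reproduced exactly.

## SAR suggestion engine

Compounds are assigned to scaffolds by R-group decomposition against
cores bearing numbered attachment points (substituents allowed only at
those points; cores are automorphism-free so position assignment is
unambiguous). Chimeras are all single-point mutants using the R-group
vocabulary observed at the same position of the same scaffold,
deduplicated by their full substitution map and excluding existing
inputs. A chimera reachable from several parents is attributed to the
parent with the lowest predicted activity (largest credited gain),
tie-broken by parent id. Score = P(active | chimera) − mean P(active)
over all input molecules; weight = mean positionwise R-group identity to
the same-scaffold inputs; ranking is by score × weight, then weight,
then parent id.

## Synthetic generator: scope and design

The original structures are not redistributable, so the generator
emulates the dataset's statistical shape, not its chemistry. 87
compounds are drawn over four close-analogue scaffolds sharing an
aryl–tetrahydrofuranyl template (S1–S4, differing in the aromatic
heteroatom pattern) with three substitution positions — 7 (aromatic; H,
methyl or ethyl), 8 (aliphatic; methyl or H) and 11 (ether-adjacent; H,
hydroxyl or methoxy) — plus six fixed off-scaffold decoys.

Activity is additive on log10 IC50: on the single signal cell line
(NCI-H446 analogue, baseline 1.25, noise SD 0.15) the planted
coefficients are −0.90 for H at position 8 (demethylation, the largest
gain), −0.50 for methyl at 7, −0.30 for hydroxyl at 11, +0.10 for ethyl
at 7 and for methoxy at 11. The other three cell lines are pure noise
(SD 0.35) centered on their own cut-offs, so their active/inactive
balance is near chance and no descriptor signal exists — mirroring the
study's contrast between one Hedgehog-specific assay and non-specific
cytotoxicity. The close-analogue design is deliberate: with structurally
diverse scaffolds the scaffold variance swamps the R-group signal in
whole-molecule descriptors and no method could recover the planted
effects. Ground truth (noiseless means, labels, assignments) is returned
alongside the library and exported with fixtures.

## Numerical conventions

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; repeated runs are byte-identical. Train sizes
round half up. Distances in the max-min ranking compare squared
Euclidean norms (argmax-equivalent, tie rule preserved). Probabilities
are combined in log space. Displayed values round to 3 decimals;
internal values keep full precision.

## Limitations

- Descriptors are RDKit analogues of a proprietary set; the published
  accuracy values cannot be (and are not) reproduced numerically — only
  the σ arithmetic, split arithmetic and method behavior are.
- The drug-like-index scalar and the k-means stand-in for the original
  clustering are reconstructions.
- The PLS condition-limit rule approximates an undocumented original.
- The synthetic generator reproduces the dataset's statistical contrast,
  not cyclopamine chemistry; conclusions drawn from it concern the
  pipeline's behavior, not the original compounds.
- The binary Bayes classifier assumes descriptor independence; the SVM
  and SVR use fixed default hyperparameters without tuning.
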