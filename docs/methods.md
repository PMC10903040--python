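# Methods

## Problem and pipeline

The package predicts hormone–drug interactions (HDI) in two stages.
Hormones act through receptor proteins and drugs through target
proteins; both are represented purely by their amino-acid sequences.
Stage 1 is a binary classification — does the (receptor, target) pair
interact — trained on labelled protein–protein interaction (PPI) pairs.
Stage 2 assigns each positive pair a severity class derived from
drug-interaction annotations: major → A, moderate → B, minor → C.

The pipeline is: FASTA input → inclusion filtering → PseAAC encoding of
receptor⊕target pairs → relational join into benchmark tables → SMOTE
balancing → CNN training → metric reports.

## Sequence inclusion rules

Sequences shorter than 50 residues are dropped (strict inequality:
length exactly 50 is kept), as are sequences containing `X`. The
forbidden set defaults to all non-canonical letters (`X B Z U O *`)
because the property scales underlying the encoding are defined only
for the 20 canonical residues; the set is configurable. Filtering
partitions its input (kept ∪ dropped, with a machine-readable reason
per dropped record) and is idempotent.

## Property table

Thirty physicochemical and conformational scales (molecular weight,
hydropathy, volume, thermodynamic unfolding quantities, secondary-
structure tendencies, …) ship as a CSV compiled from published
literature scales matching those property names. Users may substitute
any table with the same layout — first column property name, twenty
residue columns. Each scale is standardized to zero mean and unit
*population* standard deviation (denominator 20) across the residues;
a constant scale is rejected as degenerate. Standardization makes the
correlation function scale-free, so none of the package's guarantees
depend on the specific numeric values — only on the standardization
contract, which is what the tests pin down.

## PseAAC encoding

For a chain of length L, tier-k correlation factors average the
squared standardized-property differences of residues k apart; the
correlation function Θ averages over the P properties of a group
(1/P generalizes the classic three-attribute form and reduces to it at
P = 3). The (20+λ)-vector shares a single denominator Σf + ωΣθ so each
block sums to one. Defaults: λ = 30, ω = 0.05, a single group holding
all 30 properties → 50 components per protein, 100 per pair.

Pair width is config-driven (2 × groups × (20+λ)). A `paper-dims`
profile splits the first 27 properties into 9 disjoint triples, giving
2 × 9 × 50 = 900-wide pairs for users who want that dataset shape; no
grouping of 30 properties yields 900 exactly, so the choice of which
27 to use (the first, in table order) is a package convention.

f_u is interpreted as a frequency n_u/L rather than a raw count:
with counts the order-information weight would vanish as L grows,
while the frequency form keeps composition and order components on
comparable scales regardless of protein length.

Encoding requires L > λ; shorter sequences raise a distinct error from
the inclusion filter so callers can tell curation failures from
configuration errors.

## Dataset construction and splitting

The relational join keeps hormones with at least one receptor and
drugs with at least one target, emits one stage-1 row per hormone–drug
combination whose (receptor, target) pair appears among the labelled
PPIs (PPI lookup is unordered, as physical interaction is symmetric),
and restricts stage 2 to positives with a mapped risk class. Rows
whose proteins lack a kept sequence are excluded with a logged warning,
never silently. Output order is canonicalized by sorted identifiers, so
the join is deterministic.

Holdout splitting takes ceil(fraction × N) test rows — the rounding
that maps 4773 rows at 0.25 to a 1194-row test set and 11103 rows to
2776. Both unstratified (default) and stratified holdouts are
available, plus k-fold (default k = 3) cross-validation where every row
is tested exactly once. All splits are seeded.

## SMOTE

Implemented from scratch: within-class Euclidean k-nearest neighbours
(k = 5 default; k is not dictated by the source procedure, so the
technique's canonical default is used), distance ties broken by lowest
row index, interpolation s = x + u(x^R − x) with u ~ U[0,1]. Each
minority class is topped up to the pre-call majority count; originals
are preserved verbatim and first, synthetic rows are flagged. Two
scopes: `train_only` (default — balances only the training partition,
avoiding information leakage into the test set) and `full_dataset`
(balances before splitting, which is the procedure that reproduces a
benchmark whose train *and* test partitions are both balanced).

## Networks

`hormonet.nets` is a self-contained NumPy layer library with
reverse-mode gradients: valid (no-padding) 1D convolution via im2col,
max pooling, per-channel batch normalization, global average pooling,
dense layers, inverted dropout, an LSTM cell with full backpropagation
through time, sigmoid/softmax heads with binary/categorical
cross-entropy, and RMSprop (ρ = 0.9). Gradients of every layer are
verified against central finite differences in the test suite.

Reference stacks: the interaction CNN is conv(64,3)·conv(64,3)·
pool(2,2)·conv(128,3)·conv(1024,3)·pool(2,2)·GAP·dense(256)·
dropout(0.5)·4×dense(128)·sigmoid; the risk CNN shares the trunk with
batch normalization after conv blocks 2 and 4, an extra activation
layer, five dense layers and a 3-class softmax. Kernel 3 and pool 2
are fixed and each model reports its own shape propagation; dropout
defaults to 0.5 (conventional, configurable). Baselines: an MLP
(dense-ReLU stack, width configurable) and an LSTM (one recurrent
layer, then a dense head) with the same I/O contract. Default training
configuration: epochs 50, learning rate 2.5e-4, batch 16, RMSprop.
Training aborts with a diagnostic if the loss becomes non-finite, and
is bit-reproducible under a fixed seed in single-threaded execution.

## Feature selection

Three harnesses return a `SelectionResult` (sorted indices, scores,
threshold): random-forest impurity importance (300 trees, depth 9),
l2-penalized linear SVC |coefficients| (one-vs-rest max per feature;
the iteration cap is 300, an interpretation of a tuning note that
names a parameter a linear SVC does not have — flagged in the result's
notes), and XGBoost gain importances at library defaults. All use the
mean-score select-from-model threshold. `selection_report` fits a
caller-supplied classifier on an identical split before and after
reduction so the effect of selection can be re-examined on any
dataset. Mean-threshold selection is not idempotent in general (on a
reduced set the mean moves), so the suite pins determinism under a
fixed seed rather than idempotence.

## Evaluation

One-vs-rest confusion counts; accuracy, precision, recall and
F1 = 2PR/(P+R). Ratios with an empty denominator are reported as
`None`, never NaN. Multiclass summaries are macro (primary — the
unweighted mean over classes), micro and support-weighted. ROC curves
use the standard threshold sweep with trapezoidal area; the suite
checks the area against the Mann–Whitney rank statistic. The
before/after-balancing report holds the split and seed fixed and
varies only the balancing arm.

## Synthetic data

The generator emulates the study conditions: uniform random sequences
over the 20-letter alphabet (length 50–500), relational tables in
which every hormone–drug combination has one labelled (receptor,
target) PPI row, a positive-PPI fraction of 4773/9230, and risk labels
drawn in the 561 : 3701 : 511 imbalance. Feature tables are isotropic
Gaussian clusters with centres `class_sep` apart along random
orthogonal directions; integer proportions summing to n are honoured
exactly, which makes the balancing arithmetic (3701 per class, 11103
total) and split arithmetic (1194 / 2776 test rows) deterministic.

What the generator does *not* emulate: real amino-acid usage biases,
homology structure between receptors, the geometry of PseAAC feature
clouds, or any dependence of interaction labels on the sequences
themselves. Passing tests therefore demonstrate that the machinery is
correct and that the procedures have their intended statistical
effects at desk scale — not that the learned models would reach any
particular accuracy on curated hormone–drug data.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale
as a deliberate design point: encoding oracle checks use 50–200-residue
sequences; the CNN sanity check overfits a 20-sample separable set
(200 epochs, learning rate 1e-3, batch 4 — a higher rate than the
production default because the check wants fast, certain convergence
on 20 points); the balancing-effect analogue uses 955 samples in the
561 : 3701 : 511 proportions, 10 dimensions, class separation 1.5,
and a briefly trained MLP (15 epochs) — a lightly fit model is
prior-dominated, which is precisely the regime class balancing
addresses, and the directional effect (macro recall improves in the
majority of 20 replicates) is the claim under test, not any absolute
accuracy.

Known limitations: the NumPy engine is single-threaded and desk-scale;
no GPU path; no type-II/amphiphilic PseAAC variants; no SMOTE variants
(borderline, ADASYN); the CLI consumes tabular exports and performs no
database retrieval or identifier resolution.
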