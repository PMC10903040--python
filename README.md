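# hormonet

Two-stage prediction of hormone–drug interactions (HDI) from protein
sequence alone. Stage 1 asks whether a hormone — acting through one of
its receptor proteins — interacts with a drug, acting through one of its
target proteins. Stage 2 grades each positive interaction by severity:
major (class A), moderate (B) or minor (C).

The package is aimed at computational biologists who want a fully
inspectable, desk-scale version of this pipeline: every stage (sequence
filtering, encoding, dataset assembly, class balancing, training,
feature selection, evaluation) is an importable module with a seeded
synthetic-data generator, so the whole system runs and is testable
without any database downloads.

## Method

**Encoding.** A protein chain S = R₁R₂…R_L is represented by its
pseudo-amino-acid composition (PseAAC): the 20 residue frequencies
f_u = n_u/L plus λ sequence-order correlation factors

```
θ_k = 1/(L−k) · Σ_{i=1}^{L−k} Θ(R_i, R_{i+k}),   k = 1…λ
Θ(R_i, R_j) = 1/P · Σ_p [prop_p(R_j) − prop_p(R_i)]²
```

where the P physicochemical property scales (30 ship with the package)
are standardized to zero mean and unit population SD over the 20
residues. The combined vector is

```
X_u = f_u / (Σf + ω·Σθ)          u ≤ 20
X_u = ω·θ_{u−20} / (Σf + ω·Σθ)   20 < u ≤ 20+λ
```

with λ = 30 and ω = 0.05 by default, so each 50-component block sums
to one. A receptor–target pair is the receptor blocks concatenated with
the target blocks (100 components by default; a `paper-dims` profile
groups the properties into 9 triples for 900).

**Balancing.** The risk classes are heavily imbalanced (561 : 3701 :
511). SMOTE oversamples each minority class by interpolating between a
point and one of its k = 5 nearest same-class neighbours,
s = x + u·(x^R − x), until every class matches the majority count.

**Models.** A 1D convolutional network (four kernel-3 valid
convolutions of 64/64/128/1024 filters, two window-2 max-pools, global
average pooling, dense layers, sigmoid or 3-class softmax head) trained
with RMSprop on binary / categorical cross-entropy (epochs 50, learning
rate 0.00025, batch 16 by default), alongside MLP and LSTM baselines.
The layer library (including backpropagation) is implemented in NumPy
inside `hormonet.nets`.

**Evaluation.** One-vs-rest confusion counts, accuracy / precision /
recall / F1 (per class, macro, micro, weighted), trapezoidal ROC areas,
threefold cross-validation, and paired before/after-balancing reports.

## Worked example

```python
import numpy as np
from hormonet import aaprops, pseaac, smote, synthgen

table = aaprops.default_property_table()
seqs = synthgen.gen_sequences(2, synthgen.SynthConfig(seed=1))
pair = pseaac.encode_pair(seqs[0], seqs[1], table)
print(len(pair), round(pair.values[:50].sum(), 6))

X, y = synthgen.gen_feature_table(4773, 10, 3, imbalance=(561, 3701, 511), seed=0)
Xb, yb, flag = smote.balance(X, y, smote.SMOTEConfig(seed=0, scope="full_dataset"))
print(np.bincount(yb), len(yb), int(flag.sum()))
```

prints

```
100 1.0
[3701 3701 3701] 11103 6330
```

— the pair vector has 2 × (20 + 30) = 100 components whose receptor
block sums to one, and balancing the 561/3701/511 risk table raises
every class to the majority count 3701 (11103 rows, 6330 synthetic).

The same stages are available from the shell:

```bash
hormonet simulate --seed 1 --out run/raw
hormonet build-dataset --in run/raw --out run/built
hormonet encode --fasta run/raw/sequences.fasta --pairs run/built/stage2.csv \
    --out run/features.csv
hormonet split --in run/features.csv --out run/split
hormonet balance --in run/split/train.csv --out run/balanced.csv
hormonet train --task risk --train-csv run/balanced.csv --out run/model
```

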