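# dpiscope

Structural-feature profiling of the human postsynaptic density (PSD)
proteome: what kinds of interaction-capable elements do PSD proteins carry,
how do those elements co-occur, and do they suffice to recognise a PSD
protein?

The PSD is the dense protein network under the postsynaptic membrane of
excitatory synapses; its continuous reorganisation underlies synaptic
plasticity. `dpiscope` implements a protein-level analysis of that system
for computational biologists: per-protein structural and sequence features,
a composite interaction-diversity score, set-comparison statistics,
co-occurrence partitioning of structural elements, and a bagged
neural-network classifier — plus a synthetic proteome generator so the whole
pipeline runs and is tested without any database downloads.

## The score and the statistics

Each protein is summarised by counts of interaction-capable elements, and
its **Diversity of Potential Interactions (DPI)** is

```
DPI = ln(DOM) + ln(CC10) + ln(IDR10) + ln(TMH) + ln(Ph + Ub) + ln(ELM)
```

where `DOM` is the number of structured domains, `CC10` and `IDR10` the
numbers of coiled coils and intrinsically disordered regions (IDRs) longer
than 10 residues, `TMH` the transmembrane-helix count, `Ph`/`Ub` the
phosphorylation and ubiquitination site counts and `ELM` the number of
LIG/DOC short linear motifs. Because the raw sum is undefined at zero
counts, each term is evaluated as `ln(1 + x)` by default (a raw `ln(x)`
variant with zero terms dropped is available).

Disorder calling is stringent: the consensus (intersection) of two
per-residue disorder predictions, minus all residues in oligomeric fibrillar
motifs (coiled coils by either of two predictors, single α-helices, collagen
triple helices), which disorder predictors routinely misclassify.

Set comparisons use bootstrap enrichment (log-ratio of resampled feature
means, 1000 replicates, sample size 80% of the smallest set = 41 of the
51-protein postsynaptic scaffold set), a non-overlap rule mapping 1/2/3-SD
interval separation to p < 0.32 / 0.05 / 0.01, two-sample
Kolmogorov–Smirnov tests, Yates-corrected chi-square on above/below-mean
contingency tables, and Spearman correlations. Proteins are partitioned by
which of IDR / coiled coil / TM helix / domain they contain into twelve
exhaustive co-occurrence categories. The classifier is an ensemble of ten
single-hidden-layer (40 logistic units) networks, each trained by
per-sample SGD on a balanced down-sample of the 12:1-imbalanced data, with
predictions weighted by each network's confidence |2p − 1|; it is evaluated
by MCC, balanced accuracy and ROC AUC under stratified 10-fold
cross-validation and an independent hold-out, in two feature modes
(`all` annotations vs sequence-derivable `intrinsic` features only).

## Worked example

```python
import pandas as pd
from dpiscope import (GeneratorConfig, generate_feature_table,
                      LabeledFeatureMatrix, split_holdout, train_bagged,
                      evaluate, spearman_corr)

cfg = GeneratorConfig(size_factor=0.05)          # desk-scale proteome
table, sets = generate_feature_table(cfg, seed=5)

# DPI tracks interaction degree
r = spearman_corr(table["dpi"], table["ppi_degree"])
print(f"Spearman(DPI, PPI) = {r.statistic:.2f}")

# classify PSD membership from all features
ids = sorted(sets.sets["proteome"])
X = table.loc[ids].select_dtypes("number").drop(columns=["dpi"])
y = pd.Series([int(i in sets.sets["psd"]) for i in ids], index=ids)
train, test = split_holdout(LabeledFeatureMatrix(X, y), 0.2, seed=1)
model = train_bagged(train, n_bags=10, seed=2)
rep = evaluate(model.predict(test.X), test.y.to_numpy())
print(f"hold-out AUC {rep.auc:.3f}  MCC {rep.mcc:.3f}  BAC {rep.bac:.3f}")
```

Output:

```
Spearman(DPI, PPI) = 0.38
hold-out AUC 0.923  MCC 0.582  BAC 0.874
```

The correlation shows the planted rank coupling between DPI and interaction
degree; the hold-out metrics show that PSD-like proteins in the synthetic
proteome are recognisable from their feature profile alone.

There is also a thin CLI (`dpiscope simulate / dpi / cooccur / enrich /
classify`) over the same functions; see `dpiscope --help`.

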