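# coelnet

**Protein interactome inference from co-elution data — and what
integrating external genomic evidence does to it.**

Co-elution (protein correlation profiling) experiments separate native
protein complexes across dozens of chromatographic fractions and
quantify thousands of proteins in each; proteins that migrate together
are candidate co-complex partners.  Turning these noisy abundance
profiles into a protein–protein interaction network is a classification
problem, and most published pipelines boost their classifiers with
external genomic evidence — mRNA coexpression, phylogenetic profiles,
domain–domain interactions, literature co-citation, gene fusion and
neighborhood, and interologs from other species.

`coelnet` implements that whole pipeline, end to end, for people who
want to study the practice itself: proteomics methods developers and
computational biologists asking what genomic data integration does to
the networks it produces.  The package predicts networks from
chromatograms with or without any combination of the nine evidence
types, and then measures each network's functional connectivity,
novelty, time-split validation rate, study bias, and complex recovery —
together with a synthetic data generator that provides a fully
controlled world (known complexes, known study bias, time-stamped
discovery) in which every one of those outcomes has a ground truth.

## The model

For every co-quantified protein pair the package computes six
profile-similarity features (Euclidean distance, raw and cleaned Pearson
correlations with P-value, co-apex distance, and the minimum distance
between fitted Gaussian mixture components), optionally joins external
evidence columns, and trains a naive Bayes classifier on a reference
complex set: intra-complex pairs are positives, cross-complex pairs
negatives.  Continuous likelihoods are kernel density estimates, binary
ones Laplace-smoothed Bernoulli; missing evidence contributes a unit
likelihood ratio.  Pairs are ranked by stratified 10-fold
cross-validated posteriors (out-of-fold for labeled pairs, median across
folds for unlabeled ones), and the top-N pairs — or all pairs above a
precision-controlled threshold — form the predicted network.

Evaluation follows guilt-by-association: a network is functionally
coherent if a protein's annotations can be predicted from the fraction
of its neighbors sharing them (per-term AUROC, median over terms).
Novelty is the fraction of edges absent from a known-interaction
catalog; the time-split validation rate asks how many putatively novel
edges are rediscovered after a cutoff year; study bias is the Spearman
correlation between a protein's degree and its publication count; and
the global clustering coefficient measures complex-like (clique-like)
topology.

## Worked example

```python
from coelnet.synthetic import WorldConfig, simulate_study_inputs
from coelnet.elution import filter_proteins, build_pair_features
from coelnet.classifier import CoComplexModel
from coelnet.evaluation import evaluate_network

config = WorldConfig(seed=42)                     # 300 proteins, 50 complexes
inputs = simulate_study_inputs(config, n_datasets=1)
matrix = filter_proteins(inputs["matrices"]["dataset_1"])
pairs = build_pair_features(matrix, seed=0)       # six features, ~45k pairs

results = CoComplexModel(pairs, inputs["complexes"]).fit(k=10, seed=0)
print(results.summary())
```

```
Co-complex naive Bayes classifier
========================================
pairs scored:        44850
positive pairs:      198
negative pairs:      7183
unlabeled pairs:     37469
features:            6
cv folds:            10
held-out AUROC:      0.9694
```

The classifier separates labeled pairs almost perfectly (held-out AUROC
0.969), yet the network it yields is far from perfect — most of its
~45,000 candidate pairs are unlabeled, and co-eluting non-partners
abound:

```python
network = results.top_n(500)
report = evaluate_network(network, inputs["annotations"], inputs["catalog"],
                          inputs["publication_counts"], cutoff_year=2017, seed=0)
```

```
median neighbor-voting AUROC: 0.494 over 41 terms
novelty fraction:             0.894
time-split validation rate:   0.013
degree-publication bias rho:  -0.043
clustering coefficient:       0.548
```

Read: function prediction from this baseline network is near chance for
the median term (0.494) because only part of the true complex map is
recovered; 89% of its edges are absent from the known-interaction
catalog; 1.3% of those novel edges are rediscovered after the 2017 time
split; degree is essentially uncorrelated with publication count
(ρ = −0.043 — co-elution data itself carries no study bias); and the
high clustering coefficient (0.548) reflects recovered complex cliques.
Attaching external evidence shifts these outcomes — run the sweep to see
the trends:

```bash
coelnet --seed 1 simulate --out scratch/study
coelnet --seed 1 sweep --inputs scratch/study --out scratch/report \
        --max-per-size 3 --top-n 500 --cutoff-year 2017
coelnet report --sweep-dir scratch/report
```

which evaluates every sampled combination of 0–9 external features on
every dataset and prints, per outcome, the Spearman trend against the
number of integrated features.

## Layout

| module | contents |
|---|---|
| `coelnet.synthetic` | ground-truth world + all observables (chromatograms, evidence tables, catalog, annotations, publication counts) |
| `coelnet.elution` | chromatogram cleaning, Gaussian deconvolution, the six pair features |
| `coelnet.genomic` | the nine external evidence types, interaction catalog |
| `coelnet.classifier` | `CoComplexModel` / `CoComplexResults`, naive Bayes, network assembly |
| `coelnet.evaluation` | the five evaluation outcomes |
| `coelnet.sweep`, `coelnet.stats` | combination sweep, trend statistics |
| `coelnet.experiments` | the standard replicated study and controls |
| `coelnet.cli` | `coelnet simulate / features / predict / evaluate / sweep / report` |

See `docs/methods.md` for the full model description, the synthetic
world's assumptions, and known limitations.
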