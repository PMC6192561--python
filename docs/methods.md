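# Methods

`coelnet` implements a complete pipeline for predicting protein–protein
interaction networks from co-elution (protein correlation profiling)
data, optionally integrating external genomic evidence, together with an
evaluation battery that measures what that integration does to the
resulting networks.  This note documents the models, the synthetic data
generator, the numerical choices, and the limitations.

## The prediction model

### Dataset-derived features

Each protein's chromatogram (abundance across F ordered fractions,
missing values allowed) is summarized pairwise by six features:

| feature | definition |
|---|---|
| `euclidean_distance` | ‖a − b‖₂ between cleaned profiles |
| `pearson_r`, `pearson_p` | Pearson r over jointly observed raw fractions; two-sided P via t = r·√((n−2)/(1−r²)), df = n−2 |
| `cleaned_pearson` | Pearson r between cleaned profiles |
| `coapex_distance` | \|argmax a − argmax b\| in fractions |
| `gaussian_min_distance` | minimum Euclidean distance between fitted Gaussian components of the two profiles, each component represented as its (μ, σ, A) vector |

*Cleaning* imputes isolated single missing values by the mean of the two
flanking observations and replaces the remaining missing values with
zero-mean Gaussian noise whose standard deviation is 5% of the profile's
observed maximum.  The 5% noise floor is a scale-free package choice:
small relative to any real peak, non-zero so that runs of missing values
do not fabricate flat segments.  Observed values are never altered.  The
two correlation features are deliberately computed on different supports
(raw co-observed fractions vs. full cleaned vectors); this is the only
reading under which they differ meaningfully.

*Deconvolution* fits mixtures of k = 1..5 Gaussians by bounded
nonlinear least squares (analytic Jacobian; bounds μ ∈ [−1, F+2],
σ ∈ [0.5, F], A ∈ [0, 2·max]).  Initialization is deterministic: the
first component starts at the global apex, each further component at the
largest absolute residual of the previous fit.  The component count is
selected by corrected AIC; the residual sum of squares is floored at
10⁻¹² of the signal's total sum of squares so that a noiseless profile
cannot reward spurious extra components.  The search stops after the
AICc has worsened twice in a row.  Degenerate profiles fall back to a
single component at the apex, with a warning.

Proteins quantified in three or fewer fractions are filtered before any
pair feature is computed, as are isoform-suffixed identifiers
(accession-dash-number) on request.

### Classification

Training labels come from a reference complex set: intra-complex pairs
are positives, pairs whose proteins both occur in the reference but
never together are negatives, everything else is unlabeled.  A naive
Bayes classifier assumes conditional feature independence with class
priors from training frequencies.  Continuous features use
class-conditional binned kernel density estimates (256-point grid,
Gaussian kernel, Silverman's bandwidth, densities floored at 10⁻¹²);
binary features use Laplace-smoothed (α = 1) Bernoulli likelihoods.  A
missing feature value contributes a unit likelihood ratio — absence of
evidence is not evidence.  Features with a single observed value, or
unobserved in one class, are dropped with a warning.

Scoring uses stratified 10-fold cross-validation.  Unlabeled pairs
receive the median of their ten fold scores.  Labeled pairs receive, by
default, the score of the one model that excluded them: the plainer
"median across folds" rule would score labeled pairs mostly by models
that saw their label, so out-of-fold scoring is the default and the
median rule is available behind a flag.

Networks are assembled either as the top-N pairs (ties at the boundary
broken by lexicographic pair order) or by thresholding where the
labeled-pair precision reaches a target (the most inclusive qualifying
threshold is used; networks below a minimum edge count are rejected).

### External genomic features

Nine pair-level evidence types are supported: mRNA coexpression and
phylogenetic-profile correlation (computed from raw expression and
presence/absence tables via Pearson correlation), a domain–domain
interaction indicator, co-citation / gene-fusion / gene-neighborhood
scores (consumed from prepared [0, 1] tables, duplicate pairs resolved
by maximum), and three interolog indicators (literature-curated
small-scale, yeast two-hybrid, co-immunoprecipitation).  Interolog
classes are matched by case-insensitive substring search of the evidence
string ("two hybrid", "coimmunoprecipitation"); small-scale means
supported by a publication reporting at most 25 interactions, counted
within the assembled catalog itself so the definition is self-contained.
Interactions from the focal species are always excluded from interolog
features to avoid circularity.

## Evaluation battery

1. **Functional connectivity.** Annotations supported only by evidence
   codes ND/IPI/IEA/NAS are dropped; terms must annotate 0.5–5%
   (inclusive) of the network's proteins.  Annotation assignments are
   split into three folds; per fold and term each protein is scored by
   the fraction of its network neighbors annotated with the term in the
   training folds, and hidden positives are ranked against
   never-annotated proteins (mid-rank AUROC).  A term's AUROC is the
   mean over folds that have hidden positives, training annotations and
   negatives; the network summary is the median over terms.  The plain
   fraction-of-neighbors score is used, without a node-degree null
   correction.
2. **Novelty.** One minus the fraction of network edges present in the
   known-interaction catalog (optionally restricted to records dated
   strictly before a cutoff year; a record's earliest year is its
   discovery date).
3. **Time-split validation.** Records supported only by excluded
   publication ids are removed; edges with no remaining record before
   the cutoff are novel; the reported rate is the fraction of novel
   edges carrying a record dated in or after the cutoff.
4. **Study bias.** Spearman correlation between network degree and
   per-protein publication count (mid-ranks; proteins without counts
   enter as zero with a warning).
5. **Topology and robustness.** Global clustering coefficient
   (transitivity, 3·triangles / connected triples), and the pairwise
   Jaccard indices between networks rebuilt after randomly withholding a
   fraction of one evidence table (pair-level rows for pair-native
   evidence; whole proteins for protein-derived evidence).

Undefined metrics propagate as missing values, never as zeros.

## The synthetic world

The generator supplies every input the pipeline consumes, with explicit
knobs for the properties under study.  Its defaults are the package's
standard study conditions.

**Structure.** 300 proteins; 50 disjoint complexes of 3–5 members (true
interactions = intra-complex pairs); 50 fractions.  Each complex sits in
a *functional module* with 3 additional associated, non-complexed
proteins; a further set of *cross-module associations* (equal in number
to the true interactions, sampled preferentially between well-studied
proteins) models functional relationships — co-regulation, pathway
co-membership, incidental co-citation — that involve no physical
interaction.  Functional association is thus strictly broader than
physical interaction, which is the central distinction the evaluation
probes.  Every protein carries a latent log-normal (σ = 1) *study
intensity*; publication counts are Poisson with mean proportional to it.

**Chromatograms.** Complex members elute as unit-amplitude Gaussian
peaks at their complex's position (jitter SD 0.3 fractions, widths
1.5–3), non-complexed proteins at random positions; additive Gaussian
noise (SD 0.12) and 20% missingness.  With 50 complexes in 50 fractions,
peak collisions between unrelated complexes are frequent — co-elution
alone is informative but substantially ambiguous, as in real data.  By
default each replicate experiment is its own separation gradient:
complex positions are redrawn per replicate, so different experiments
resolve (and confuse) different complexes, as across real separation
methods.

**Catalog.** Each true interaction can be discovered each year
(2010–2018).  Before the 2017 time split the per-year probability is
`floor + rate·g^bias` with g the pair's geometric-mean study intensity
(floor 0.04, rate 0.12, bias 2) — discovery is strongly study-biased but
no pair is undiscoverable.  From 2017 on, discovery is unbiased
(probability 0.3 per year for every true pair), so the validation era is
independent of study intensity and of evidence coverage.  5% of records
are false positives on non-interacting pairs.  The training reference
complexes are a 60% subset of the true complexes sampled with weight
(geometric-mean study intensity)², emulating the study bias of curated
complex databases.

**External evidence.** For each evidence type, associated pairs are
*elevated* with probability `informativeness · (u_a·u_b)^coverage_bias`
(u = study-intensity percentile): evidence for an association exists
only where someone looked.  Non-associated pairs of well-studied
proteins are spuriously elevated at 2% of that rate.  Elevated scores
are drawn from a high range (binary kinds emit 1), background scores
from a low range; co-citation-like backgrounds additionally scale with
the pair's study level, because famous proteins are co-mentioned at base
rates regardless of association.  Indicator-type evidence is complete
(absence is an observed 0); continuous evidence is observed with
probability `0.8·(u_a·u_b)^coverage_bias`.  Per-kind informativeness and
coupling defaults encode field knowledge: co-citation is the richest and
most biased source, gene fusion is rare and weak, genome-scale
measurements (coexpression, phylogenetic profiles) are the least
study-coupled.

One further coupling is essential: a *true* interaction that nobody has
reported cannot be documented by literature-derived evidence, and
pair-level genomic evidence has not proven able to single it out either.
Elevation of true pairs is therefore gated on the pair's presence in the
pre-cutoff catalog (hard for literature-type evidence; the damping for
genome-scale types is configurable via `undocumented_elevation_factor`,
default 0).  Associated-but-not-interacting pairs are not gated — their
functional signal exists independently of interaction discovery.  This
is what makes external evidence recapitulate known biology rather than
reveal new physical interactions, the central premise being tested.

**Annotations.** One GO-like term per module; each member annotated with
probability 0.9; evidence codes sampled with a realistic mix (45% IDA,
20% IMP, 15% TAS, 15% IEA, 5% NAS), so downstream evidence filtering has
something to remove.

**What the generator does not emulate.** Instrument-level artifacts
(ratio compression, carryover), monomer/complex abundance differences
(monomer peaks exist but default off), overlapping complexes (flag
exists, default off), ontology structure (terms are flat), and any
specific published dataset.  Passing tests on this generator shows the
pipeline reproduces the *mechanisms* of interest under controlled
conditions, not that any particular real dataset would behave
identically.

## Standard experiments and problem sizes

The reference experiment replicates the study design at desk scale: 5
synthetic worlds (master seeds), each observed by 5 independent
co-elution experiments; combinations of 0–9 external features with up to
3 sampled combinations per combination size (26 combinations, fully
enumerating sizes 0 and 9); top-500 networks over the ~45,000 candidate
pairs of each dataset; all five outcomes per network (time-split cutoff
2017).  This yields 130 networks per world — enough that a Spearman
trend of |ρ| ≈ 0.2 across feature counts is resolvable per world — while
a full five-world replication runs on one CPU in minutes.  Trends are
summarized per world and compared across worlds; the degenerate controls
(zero-informativeness features, no-withholding robustness, label-copy
oracle feature) run on two datasets of a separate world.  The
uninformative-feature control reports the median over terms of the
*paired* per-term AUROC difference between the null-feature network and
the baseline network; pairing removes the between-term spread that makes
a difference of unpaired medians unstable.

## Numerical and design choices

- All randomness flows from explicit seeds; per-stage seeds are derived
  from a master seed by CRC-32 hashing of the stage key, so stages are
  independent and reorderable.  Profile cleaning seeds per protein by
  identifier, making pair tables invariant to protein order.
- Fractions are 1-based.  Pair tables are keyed on the lexicographically
  sorted pair and symmetric by construction.
- Co-apex ties break to the earliest maximal fraction.
- The "distance between Gaussians" metric treats a component as its
  (center, width, amplitude) vector; centers dominate in practice.
- Duplicate external scores resolve by maximum (evidence-union
  semantics).
- Brunner–Munzel, Fisher's method, Spearman correlation and the
  two-proportion z test (no continuity correction) delegate to
  scipy/statsmodels; the test suite checks them against permutation and
  closed-form oracles.
- Catalog "known before year" uses any record year strictly before the
  cutoff; "discovered from year" uses any record year at or after it.

## Known limitations

- The naive Bayes posterior is uncalibrated; only the ranking is used.
- Binned KDE likelihoods are evaluated by linear interpolation on a
  256-point grid; extreme tail ratios are clipped by the density floor.
- The neighbor-voting implementation holds the network's adjacency
  matrix densely; it is intended for networks of up to a few thousand
  proteins.
- The sweep caches nothing across worlds; each world is fully
  regenerated from its seed.
- With very small complexes and few folds, a cross-validation fold can
  lose all of a term's annotations; such folds are skipped rather than
  imputed.
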