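# Methods

`pathcalib` simulates drug response in silico. The premise: if a machine
learning model can discriminate disease from normal samples almost perfectly
from pathway activity signatures, then a simulated drug effect that moves a
patient's signature across the decision boundary is evidence the drug
addresses the disease-relevant pathways. The pipeline has four stages —
pathway scoring, classification, calibration, screening — plus a synthetic
cohort generator that makes every stage testable without external data.

## Pathway activity scores (ssGSEA)

For each sample independently, genes are ranked by expression in descending
order (ties broken lexicographically by gene symbol, so scores are identical
across platforms and runs). A gene set G with m member genes in an n-gene
matrix receives the running-sum statistic

    score(G) = Σ_{i=1..n} [ P_in(i) − P_out(i) ]

where P_in(i) is the cumulative weight of in-set genes among the top i ranks
divided by the total in-set weight (weights |x|^α on the expression values)
and P_out(i) is the cumulative count of out-of-set genes divided by n − m.
This is the integral form of the single-sample enrichment statistic: the sum
over all rank positions, not the maximum deviation used by cohort-level
GSEA. With α = 0 the statistic depends only on ranks; for a 5-gene sample
with values 5,4,3,2,1 and set {top two genes} the position-wise differences
are 0.5, 1, 2/3, 1/3, 0, summing to 2.5.

Defaults: α = 0.25 and matrix-wide (max − min) normalization, the common
convention of ssGSEA tooling. Scores are computed for the whole cohort in a
single call so the normalization constant is shared between classes.
Sets overlapping the matrix in fewer than `min_genes` (default 2) genes are
dropped with a warning; a set covering every gene has no complement and is
rejected. A sample whose in-set expression is all zero at α > 0 falls back
to unweighted counts so the statistic stays defined.

Whether normalization should be matrix-wide or per-sample is genuinely open;
the chosen mode is recorded in the result's parameter block so downstream
artifacts are self-describing.

## Disease/normal classifier

An elastic-net penalized logistic regression (scikit-learn's saga solver)
on the pathways × samples score matrix. Protocol:

- outer loop: repeated stratified K-fold CV (default 10 repeats × 10 folds)
  provides held-out AUC-ROC and AUC-PR estimates;
- inner loop: a grid search over l1_ratio ∈ {0.1, 0.3, 0.5, 0.7, 0.9} and
  inverse regularization strength C ∈ 10^−3 … 10^2 (log-spaced, 6 values),
  run on each outer training split only (3-fold), so tuning never touches
  the held-out fold;
- final model: refit on all samples with the hyperparameter pair selected
  most often across outer folds; ties resolve toward stronger regularization
  (smaller C), then toward sparser solutions (larger l1_ratio). Refit-on-all
  is recorded in the model artifact.

Features are standardized per pathway inside each training split; the final
scaler is stored in the model and reapplied at prediction time — including
to calibrated scores, which can sit far outside the training range. The
classification threshold is fixed at 0.5. The model is persisted as a
versioned JSON artifact so screens are exactly reproducible.

## Drug-effect scores and calibration

Drug-target interactions carry a signed effect: +1 activation, −1
inhibition (free-text action vocabularies are mapped on ingest; the shipped
default maps inhibitor/antagonist/blocker to −1 and
agonist/activator/inducer/stimulator to +1, everything else dropped with a
count). The drug's effect score on pathway p is the arithmetic mean of its
signed effects over the targets it has inside p; a drug that activates one
protein and inhibits another in the same pathway nets to ES = 0. The ES = 0
test is exact — zero iff equally many +1 and −1 records — by keeping the
integer numerator, avoiding any floating tolerance.

Per-pathway dysregulation is μ(p) = |mean score in healthy − mean score in
disease|, computed over the full cohort, with quartiles Q1–Q3 taken over all
pathways (linear-interpolation percentiles). All-pathway quartiles are
drug-independent and stable; computing μ on the full cohort mirrors a
single-cohort design and is a known source of leakage if the screen is later
evaluated on held-out samples. For each disease sample d and targeted
pathway p:

    CS(p,d) = |PAS(p,d)| · w · sign(ES(p))   if ES(p) ≠ 0
    CS(p,d) = PAS(p,d)                       otherwise

with w = w1 if μ(p) > Q3, w2 if Q2 ≤ μ(p) ≤ Q3 (closed middle bin), w3
otherwise. Defaults (w1, w2, w3) = (20, 5, 10). Note the deliberate
non-monotonicity of the defaults: the middle bin weighs less than the lowest
bin; all three are configurable. The weight magnitude is what drives label
flips — the sign merely rectifies the score in the drug's direction — so
very small weights leave predictions unchanged even for drugs targeting the
right pathways.

## Screening, validation, robustness

A screen calibrates and re-classifies every disease sample for every drug.
Eligible samples are the disease samples the model predicts as diseased
before simulation (with near-perfect models this is essentially all of
them); a responder is an eligible sample predicted healthy afterwards. Drugs
are ranked by responder proportion (ties by drug id) and prioritized when
the proportion reaches the threshold, default 0.8 — the "at least 80 % of
patients" rule. The threshold is exposed rather than selected automatically.

Validation reports the positive predictive value: the percentage of
prioritized drugs that are approved or clinically tested for the indication
(the two ground-truth lists are unioned, so a drug on both counts once).
Enrichment over chance uses the hypergeometric upper tail with the screened
library as population and all known positives in it as successes.

The permutation analysis rebuilds the library `n_reps` times (default 100):
each drug keeps its target count, targets are drawn uniformly from the gene
universe of the expression matrix, and effect signs are drawn at the
original activation:inhibition ratio. Reported: the per-replicate
prioritized counts and the empirical p-value (fraction of replicates
prioritizing at least as many drugs as the real library).

Drug pairs are screened as a single virtual drug whose interaction records
are the multiset union of both partners'; pathway effect scores are averaged
over the pooled records, so opposing effects on a shared pathway can cancel
to ES = 0 and neutralize the treatment there. Pair screening is symmetric,
and pairing a drug with itself reproduces its single-drug result. By default
only pairs of already-prioritized drugs are enumerated (`combine_all`),
which keeps the quadratic cost down; any pair can be screened directly.

## Synthetic cohorts

The generator plants a known answer so recovery is checkable end to end:

- **Gene universe**: 20 000 genes with log-normal expression (baseline
  log-mean N(3, 1), per-sample log-noise SD 0.5), mimicking the positivity
  and right skew of normalized RNA-seq units. Only 2 000 genes (50 pathways
  × 40 genes, a random subset) carry pathway annotation — as with curated
  pathway databases against a full transcriptome — so randomly chosen
  targets rarely land in a disease-relevant pathway, the property the
  permutation analysis probes.
- **Planted disease signal**: 5 pathways whose member genes get a +1.5
  log-scale baseline elevation (active in normal tissue) and a −1.0
  log-scale shift in the 60 disease samples (suppressed in disease); 60
  healthy samples are unshifted. These pathways score positively in all
  samples and separate the classes cleanly, the regime the method requires
  ("highly predictive model"). Suppression-type dysregulation is the default
  because it exercises the weight magnitude: reactivating an
  already-positive score at weight 1 is a near no-op, while weight 20
  pushes it well past the healthy level.
- **Drug library**: 5 oracle drugs, each targeting one gene in every planted
  pathway with effect +1 (opposing the suppression), labeled approved in the
  ground truth; 95 decoys with 3 targets each (about the mean target count
  of public drug-target datasets) drawn uniformly from the universe, signs
  50:50. A decoy cures only if it happens to hit a planted pathway with the
  right sign — about 1.5 % per drug under the defaults, so a handful of
  decoys per library are genuine lucky hits, matching the expectation that
  only a minority of random drugs flips predictions.

What the generator does not emulate: overlapping gene sets, correlated
pathway activity, batch effects, count noise, dose dependence, or realistic
pathway topology. Passing tests therefore demonstrate that the machinery
recovers planted signal under the stated statistical structure, not that it
ranks real compounds correctly on clinical data.

## Problem sizes and numerical choices

The test suite and examples run the default scenario with a 3×5-fold outer
CV (the full 10×10 protocol is the library default and is configurable);
unit tests use a miniature scenario (1 000 genes, 20 pathways, 30+30
samples). The saga solver runs with max_iter 5000 and tol 1e-4; a fixed RNG
seed threads through data generation, CV splitting and permutation
replicates, so identical seeds give byte-identical result tables. Expression
ties are broken by gene symbol; ranking ties therefore never depend on input
order. Floats are written at 6 significant digits in all TSV output.

## Known limitations

- Transcriptomics-only: indications where pathway scores do not separate
  disease from normal give weak classifiers, and flipped labels can no
  longer be attributed to the simulated drug.
- The calibration replaces scores rather than perturbing them continuously;
  there is no dose axis.
- μ and its quartiles use the same cohort the classifier was trained on.
- The enrichment test treats drugs as exchangeable; target-count or
  class-structure confounding is only addressed by the permutation analysis.
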