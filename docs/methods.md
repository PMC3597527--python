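# Methods

## Evidence model

Every genomic dataset is reduced to one real score per unordered gene pair:

- **Expression**: Fisher z-transformed Pearson correlation of the two
  genes' condition profiles, `atanh(r)`. `r` is clamped to `±(1 − 1e−6)`
  before the transform so perfectly correlated profiles stay finite;
  constant profiles score 0; pairs with fewer than two overlapping finite
  conditions are skipped.
- **Interactions**: the number of supporting assay records (records, not
  distinct assay types — two-hybrid plus western blot counts 2).
- **TF motif profiles**: Pearson correlation of the two genes' binary
  motif-hit vectors; a constant vector has undefined correlation and is
  scored 0 (neutral evidence).
- **Phenotype/disease memberships**: `sum_k I_k(i) I_k(j) / N_k` over all
  phenotypes, where `N_k` is the phenotype's gene-set size.

Scores are discretized into `|D_k|` levels over half-open bins (a score
exactly on an edge joins the upper bin). The shipped default for
continuous evidence places edges at the empirical 50/80/95/99% quantiles
of the dataset — five levels that resolve the informative upper tail;
counts and phenotype scores use fixed low-cardinality bins. The source
never states per-type discretizations, so these defaults are ours and are
recorded with every fitted model.

## Network integration

The pairwise gold standard calls a pair *related* when co-annotated to an
expert fringe process term, and *unrelated* when the two genes share no
fringe/pathway term, excluding pairs whose two terms overlap more than
expected by chance (hypergeometric p < 0.05 on the annotated-gene
background) and pairs co-annotated to configured minimally-informative
"negative" terms.

Conditional probability tables use pseudocount `n_s = 3` spread uniformly
over levels: `P(d_k = v | c) = (count + n_s/|D_k|) / (count_c + n_s)`;
entries are therefore strictly positive and posteriors never saturate at
0/1. Redundancy weighting: `U_k = sum_{i≠k} I_neg(D_k; D_i) / H(D_k)` and
`a_k = exp(−U_k)`, with mutual information and entropy (base-2) estimated
over the unrelated pairs only — the exact algebra of the weighting is the
one deliberate reconstruction in the package (the published equations are
only available as rendered figures); the sum runs over all `i ≠ k` so the
weight is order-independent. Datasets with zero entropy or no
gold-standard coverage in a class are excluded with a warning. The class
prior is a configuration parameter (default 0.05); the gold standard's
class balance is curation-dependent, so the prior is never estimated from
counts. The posterior is evaluated in log space; pairs with no observed
evidence fall back to the prior. A per-context mode (one model per fringe
term, edges averaged over the contexts in which they are defined) is
provided via `integrate_contexts`; the default pipeline trains a single
global model, which is equivalent when contexts share one gold standard.

## Functional analogs

Networks are binarized at probability ≥ 0.5. A gene's neighborhood
profile is the set of distinct families of its direct neighbors
(unmapped neighbors skipped; the gene itself excluded). For a candidate
within-family homolog pair the score is `P(X ≥ k)` with
`X ~ Hypergeom(N, m, n)` — `m`, `n` the two profile sizes, `k` their
overlap, and `N` the number of distinct families represented among
family-mapped genes across the two organisms' networks. The published
description of `N` ("families around G1 and G2") is ambiguous; the
union-of-neighborhoods reading makes the tail degenerate (every draw
overlaps maximally), so the package uses the proper sampling universe
above. Pairs with `p ≤ 0.01` are analogs; no multiple-testing correction
is applied, matching the original cutoff as printed. Empty neighborhoods
give `p = 1` and are flagged. Cross-organism comparability comes entirely
from the shared family vocabulary; gene identities are never compared
across organisms.

## Transfer and training sets

Annotations are filtered to the six experimental evidence codes with all
NOT-qualified records removed, then propagated to all is_a/part_of
ancestors (duplicates collapse keeping the earliest date). Transfer copies
*direct* records both ways along each analog pair — one hop, never
chained, which also makes the operation idempotent; transferred records
keep the source date and carry `source_gene` provenance. Because both
transfer and propagation close over the same term sets, their order is
irrelevant (verified against a brute-force closure oracle). Per-term
training sets take positives = direct ∪ transferred annotations;
negatives = the organism's network genes minus positives and minus genes
annotated to the term's ancestors/descendants or to configured exclusion
terms. Ontology roots are never used for exclusion — after propagation
they annotate every gene and would empty the negative pool.

## Classifiers

Features are network rows: gene *i*'s vector holds its edge probability
to every gene of the organism (0 at self and undefined edges), so the
feature dimension equals the gene count. All three models are
scikit-learn estimators:

- `NetworkSVM`: linear soft-margin SVM, `C = 100`, squared-hinge via
  liblinear's dual coordinate descent (the primal solver is orders of
  magnitude slower at this `C` on ~600×600 designs), tolerance 1e−6,
  inverse-class-frequency instance weights (per-term universes are
  severely imbalanced). Margins are mapped to probabilities by a
  maximum-likelihood sigmoid `1/(1+exp(A·s+B))` with Platt's smoothed
  targets `(N±+1)/(N±+2)`, fitted on 3-fold cross-validated decision
  values (training-set values would give optimistic sigmoids); degenerate
  scores fall back to the class prevalence. Calibration preserves ranking
  exactly.
- `L1LogisticNetwork`: `lam·‖w‖₁ +` logistic loss via liblinear.
- `FeatureBaggedForest`: 61 trees, each trained on a bootstrap sample of
  the examples *and* a bootstrap sample (with replacement, deduplicated)
  of the feature space; prediction is the average of hard votes — an odd
  tree count keeps the vote away from exactly 0.5. The original
  description of the forest's "bootstrap of the feature space" is
  ambiguous; this joint example/feature-bagging reading is flagged as a
  choice.

Rankings cover the whole universe, descending score, ties broken
lexicographically by gene id; training genes are flagged, not removed.

## Evaluation

Temporal holdout: train on records dated ≤ cutoff, test on later direct
experimental records whose (gene, term) is not already in training;
transferred records are never test targets. k-fold: seeded partition of
positive genes (default k = 3). Precision at 10% recall walks the ranking
until `ceil(0.1·|positives|)` positives are retrieved (no interpolation);
fold over random divides by the evaluation-universe prevalence. Terms are
labeled by direct-annotation count at the cutoff (zero / ≤5 / ≤15 / all);
comparative summaries use the nested groups (zero ⊂ ≤5 ⊂ ≤15 ⊂ all), the
grouping used by the original comparisons. A leakage check
(evaluation positives ∩ training positives = ∅) runs on every metric
record and raises.

When modes are compared (no transfer vs FKT vs sequence-only), all modes
are evaluated against identical targets: planted members minus the union
of training positives across the compared modes. Evaluating each mode
against its own leftovers would score methods on different target sets
and turn fold-over-random differences into a prior artifact. A term that
is untrainable under a mode contributes zero performance to that mode's
median (the "absent bar"). For the FKT vs sequence-only fold comparison
the summary statistic is the median of paired per-term fold differences:
at 40 terms, separate medians of each mode are dominated by per-term
prior quantization (fold = precision/prior) and flip sign on selection
noise even when per-term precisions tie exactly.

## Synthetic worlds

The generator emulates the study design end to end; its defaults are the
benchmark's study conditions:

- 3 organisms × 600 genes; 560 families, one copy per organism plus a
  10% chance of a within-organism paralog; 40 planted pathways of 8–14
  families. Pathway membership is family-conserved except that each copy
  diverges (same family, *not* in the pathway) with probability 0.15
  (the divergence experiment raises the pair-level diverged share to 30%,
  i.e. a per-copy rate of 0.176).
- Pathways decompose into sub-modules of 4 families (complexes) with full
  intra-sub signal and 0.7 of the signal gap across sub-modules —
  conserved through families, so analog neighborhoods span the pathway
  while continuous edge weights retain core/periphery structure.
- Evidence: 3 pairwise-score datasets per organism; background scores
  `N(0.30, 0.15)`, within-group means lifted toward 0.80 scaled by
  per-family participation weights `U(0.7, 1)`. Each organism also has 50
  *latent co-function modules* (sizes 5–9, weights `U(0.5, 1)`,
  organism-specific): genes take part in processes beyond the evaluated
  pathways, which is what makes rankings from one or two positives
  genuinely ambiguous. An expression-matrix mode generates gene×condition
  data with per-sub-module factors for end-to-end I/O tests.
- Annotations: per term, a rotating source organism annotated at density
  0.9; one organism with zero direct annotations; remaining organisms
  mostly hold 0–2 direct annotations (35% chance of none, otherwise a
  low/moderate density mixture around 0.2). Dates fall 70%/30% before and
  after a fixed synthetic cutoff; 5% of records carry non-experimental
  codes and 2% NOT qualifiers to exercise filtering.

What the generator does **not** emulate: real assay noise structure
(batch effects, probe biases), sequence evolution, unbalanced gene
universes across organisms, ontology depth beyond a flat stub with one
root, and annotation curation biases. Passing benchmarks therefore show
that the pipeline's machinery behaves as designed under planted truth,
not that the same margins would be observed on real compendia.

One calibration pass fixed the generator's signal strength so that
planted-truth analog recovery sits in a regime where the published
cutoff is meaningful (recall ≈ 0.80–0.86, diverged-pair specificity
≥ 0.99 at the defaults); the thresholds asserted by the acceptance
checks (recall ≥ 0.8, specificity ≥ 0.9) are recorded in
`PipelineConfig`. At the uncorrected p ≤ 0.01 cutoff, chance two-family
overlaps make a handful of diverged pairs scorable as analogs on some
seeds (~0–3 of ~600 candidates); the sequence-only baseline meanwhile
transfers annotations to hundreds of diverged pairs, which is the
contrast the divergence experiment measures.

## Determinism and sizes

All randomness in the generator and pipeline descends from a single seed
(classifier seeds are derived arithmetically from it). The default
benchmark (3 organisms × 600 genes × 40 terms, three classifiers, two
transfer modes) runs in about four minutes on one CPU; the unit-test
worlds use 60–150 genes. Networks are stored dense and symmetric with
NaN for undefined edges; pairwise structures use condensed upper-triangle
vectors.
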