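# Methods

## Problem and model

`ceradys` detects lncRNA–miRNA–mRNA competing-endogenous (ceRNA) triplets
whose joint behaviour breaks down between two biological states — e.g.
healthy controls versus disease, or consecutive disease stages — from
sample-matched expression matrices of the three transcript classes plus
experimentally supported miRNA→mRNA and miRNA→lncRNA interaction tables.
Under the ceRNA hypothesis, an mRNA and a lncRNA that share miRNA binding
compete for a common miRNA pool: in a reference state the miRNA is
negatively correlated with both targets while the two targets are
positively correlated with each other. Dysregulation is the loss of this
structure together with differential expression of the members.

The pipeline runs in four phases.

### 1. Candidate triplets (reference state)

A candidate triplet (lncRNA *l*, miRNA *mi*, mRNA *m*) must satisfy, in
reference samples:

1. *m* and *l* share a significant number of targeting miRNAs: with
   universe *N* = distinct miRNAs carrying at least one interaction
   (restricted by default to miRNAs present in the expression data),
   *K* = miRNAs targeting *m*, *n* = miRNAs targeting *l*, and *k*
   shared, the upper-tail hypergeometric probability P(X ≥ k) must fall
   below `hyper_alpha` (default 0.05). The universe choice is the union
   of both interaction maps — the least arbitrary option, and
   configurable via `shared_mirna_test(..., universe=...)`.
2. Pearson correlations r(mi, m) < 0, r(mi, l) < 0, r(l, m) > 0, each
   with two-sided t-transform p < `corr_alpha` (default 0.05). Exact
   t-based p-values (n − 2 df) are used instead of permutation p-values
   for determinism and speed.
3. Percentile retention: within each link class (miRNA–mRNA,
   miRNA–lncRNA, lncRNA–mRNA) only distinct pairs whose |r| reaches the
   `percentile_cut` percentile (default 90) of |r| among all sign- and
   significance-valid pairs of that class are kept; a triplet survives
   only if all three of its links survive. Absolute value unifies the
   negative and positive link classes ("most correlated" means most
   negative for repressive links). The comparison is non-strict
   (|r| ≥ threshold): `numpy.percentile` of a single-pair class equals
   that pair's own |r|, and a strict comparison would empty any class
   with one valid pair.

### 2. Dysregulation score (two states)

Writing Φ for the standard normal CDF, every component statistic d ≥ 0 is
mapped onto the normal quantile scale by

    T(d) = Φ⁻¹(2Φ(d) − 1),

with the probability 2Φ(d) − 1 clamped into [ε, 1 − ε] (ε =
`clamp_eps` = 1e-15) so T is finite and monotone everywhere (at d = 0 the
probability is exactly 0, whose quantile is −∞).

- **Node scores** (one per transcript): D = (−log₁₀ p) · |log₂FC| from a
  two-group differential-expression test between the states; score
  = T(D). p-values are floored at 1e-300 before the logarithm.
- **Edge scores** (one per link): with F(r) = ½ ln((1+r)/(1−r)) the
  Fisher z-transform (|r| clamped to 1 − 1e-7),

      ξ = [F(r₂)(−log₁₀ p₂) − F(r₁)(−log₁₀ p₁)] / √(1/(n₂−3) + 1/(n₁−3)),

  where (r, p, n) are the link's Pearson correlation, its p-value and the
  sample count in each state; score = T(|ξ|). State 1 is the reference
  (control) and state 2 the comparison state, fixing the sign of ξ; only
  |ξ| enters the score, so orientation affects signs, never scores.
- **Triplet score**: ω · mean(3 node scores) + (1 − ω) · mean(3 edge
  scores), ω = 0.5 by default (equal weighting); with ω = 0.5 this is the
  plain mean of the six components.

### 3. Empirical significance

One shared null distribution is built by drawing `n_permutations`
(default 10,000) random triplets — one lncRNA, one miRNA, one mRNA,
sampled independently from pools — and scoring each with the identical
machinery. Null triplets need no interaction support. The empirical
p-value of an observed triplet is the fraction of null scores strictly
greater than its score (so p is a multiple of 1/n_permutations and can be
exactly 0); triplets with p < `perm_alpha` (default 0.05) are flagged
dysregulated. A single shared null is the default because the definition
is one empirical comparison, and it costs 10⁴ scorings rather than
10⁴ × |candidates|; `per_triplet_null=True` switches to per-triplet
nulls. Null pools default to the genes appearing in candidate triplets
(keeping the null on comparable expression strata); `pool_scope="all"`
widens them to all profiled genes.

A threshold-based comparator (`traditional_method`) is provided: all
three members SDE between the states, shared-miRNA test significant, the
three reference-state correlation constraints, and loss of the positive
lncRNA–mRNA correlation in the comparison state (r ≤ 0 or p ≥ α). It
returns an unscored triplet set.

### 4. Downstream analyses

- **Differential expression** (`diffexpr`): default is a moderated
  t-statistic — per-gene pooled variances are shrunk toward a scaled
  inverse-chi-square prior whose df and scale are moment-matched on the
  log variances across genes; the posterior df adds the prior df. Plain
  Welch is available. log₂FC is the difference of group means on the
  already-log₂ data. A gene is SDE at raw p < 0.05 (no multiple-testing
  gate, matching the thresholding convention the score consumes); a
  Benjamini–Hochberg FDR column is emitted for information only. Groups
  are treated as independent (no pairing by patient).
- **Time-course utilities** (`dynamics`): per-stage group means,
  standardized per gene, clustered with hand-implemented fuzzy c-means
  (fuzzifier m = 2 by default, membership exponent 2/(m−1), convergence
  when the largest membership change < 1e-6 or 500 iterations, seeded
  random membership initialization). Cluster counts are user inputs.
  Co-expressed mRNA partners of an ncRNA require |r| > 0.7 and p < 0.01.
  Gene-set enrichment is a hypergeometric upper tail against a
  configurable universe (default: all profiled mRNAs in the workflow);
  sets sharing a parent pathway label (the GMT description field, else
  the set name) keep only their lowest-p member.
- **Biomarker panels** (`biomarkers`): features are reduced by a bagged
  decision-tree ensemble (500 trees, sqrt-feature splits) ranked by
  out-of-bag permutation importance — per tree, the OOB-accuracy drop
  after permuting one feature among the OOB rows, averaged over trees.
  The ensemble is bagged by hand because the per-tree OOB partition is
  needed. Each round drops ⌊current/3⌋ lowest-ranked features (at least
  one, never past `target_k`). Survivors enter an exhaustive search over
  all 2^k − 1 non-empty subsets, each scored by pooled stratified 5-fold
  CV accuracy of an SVC (RBF kernel, C = 1, γ = 1/#subset-features — the
  defaults of the classical SVM package family; linear kernel by flag).
  Fold assignment is seeded and shared across subsets. Ties break toward
  fewer features, then lexicographically. The winning panel's ROC AUC is
  computed from decision values pooled over test folds. A guard refuses
  k > 16 without `force=True`. Sample structure is summarized by
  complete-linkage Euclidean hierarchical clustering cut at two
  clusters, reporting per-cluster label fractions.

## Synthetic cohorts

`generate_cohort` plants triplets via a per-sample latent factor L:
mRNA = ρ·L + ε, lncRNA = ρ·L + ε, miRNA = −ρ·L + ε with ε ~ N(0, σ²),
giving pairwise |r| ≈ ρ²/(ρ² + σ²) with the ceRNA sign pattern guaranteed
by construction. Defaults: 46 controls / 73 cases, 200 mRNAs, 60 lncRNAs,
40 miRNAs, 20 planted triplets (10 dysregulated), ρ = 0.9, δ = 1 log₂
unit, σ = 0.3 — a scale-down of a typical two-arm cohort that keeps test
runtimes in seconds. In case samples, dysregulated triplets replace the
latent coupling with independent noise of matched marginal variance and
receive ±δ mean shifts (+δ mRNA, −δ lncRNA, +δ miRNA). Decoy
interactions land on background genes only: a decoy hitting a planted
mRNA/lncRNA would perturb that pair's shared-miRNA test. Thirteen cases
carry an HF/non-HF outcome label (7 HF), emulating a follow-up subset.
`generate_stages` adds stage-trend genes — a "spike" family jumping at
stage 1 and halving back toward baseline each later stage, and its
mirrored "dip" family — so that every adjacent-stage comparison moves the
mean, while background genes stay flat.

The generator does **not** emulate probe-level noise, batch structure,
heavy-tailed expression, partially overlapping triplets (each planted
triplet uses distinct genes), or realistic interaction-network topology.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not performance on real microarray cohorts.

## Numerical choices

- Clamps and floors: q = 2Φ(d) − 1 clamped to [1e-15, 1 − 1e-15]; |r|
  clamped to 1 − 1e-7 before Fisher z; all p-values floored at 1e-300
  before −log₁₀; variances floored at machine-scale values before
  ratios.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; TSV output uses a 17-significant-digit float format so
  write/read round-trips are bit-identical and repeated runs compare
  byte-for-byte.
- Candidate output is sorted by (lncRNA, miRNA, mRNA), independent of
  enumeration order.
- Delimiters are auto-detected between tab and comma from the header
  row, ties toward tab. Duplicate gene rows collapse to the elementwise
  median, preserving first-appearance order.
- Expression input is assumed already log₂-transformed and normalized;
  no normalization is performed. Samples missing from any of the three
  matrices (or the metadata) are dropped to the ordered intersection,
  with a log message.
- Two-group comparisons require ≥ 4 samples per state: correlation
  p-values need n > 3 and the edge statistic divides by n − 3.

## Known limitations

- For links that are strongly correlated in **both** states, the
  (−log₁₀ p) weights inside ξ amplify correlation sampling noise: the
  statistic can be large even when the underlying correlation is
  unchanged, because the weight is itself a steep function of r. Against
  an empirical null of randomly assembled (hence mostly uncorrelated)
  triplets, tightly coupled but intact triplets can therefore be flagged
  between two identically distributed states. The signed ξ remains
  centred on zero in that situation (verified by test); interpret flags
  for strongly coupled candidates with the score components in hand.
- Accuracy and AUC of a selected panel are optimistically biased by the
  exhaustive search (no nested cross-validation); the selection-bias
  guard test bounds, but does not remove, this effect.
- The hypergeometric shared-miRNA test ignores correlation between an
  mRNA's and a lncRNA's target sets induced by interaction-database
  ascertainment.
- The stopping rule of the importance reduction is an explicit
  `target_k`; no automatic accuracy/size trade-off is applied, and the
  per-round survivors are reported so the trace can be inspected.
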