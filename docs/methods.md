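# Methods

## Model and assumptions

`phenonet` treats phenotype prediction as per-term binary classification
over a fixed gene universe. The central assumption is guilt by
association: genes whose network neighborhoods resemble those of a
phenotype's known genes are likely to share the phenotype. The network
itself is assumed to encode, as edge weight K(a, b) ∈ [0, 1], the
posterior probability of a functional relationship, and to exclude
phenotype-derived evidence (enforced at integration time by rejecting
dataset names containing "phenotype"), so training labels and features
come from independent sources.

### Gold standards

Annotations are collapsed from allele to gene level (any annotated allele
annotates the gene), then propagated up the ontology's is_a hierarchy:
an annotation at a term annotates all its ancestors. Positives for a term
are the universe genes annotated to it after propagation; negatives are
all remaining universe genes — "unknown" genes are deliberately treated
as negatives, which the class-weighted SVM and the precision-recall
metrics both tolerate. Only is_a edges participate in propagation; other
OBO relationship types are ignored. The gene universe defaults to the
network node set and can be switched to the annotated-gene set
(`--universe annotations`); both readings are defensible, so the choice
is explicit.

Terms are grouped for reporting into half-open size bins [30, 50),
[50, 100), [100, 200), [200, 300) by n_p; half-open intervals make the
boundary counts (50, 100, 200) land in exactly one bin. Prediction itself
is available for any term with n_p ≥ 1; size filtering is the caller's
decision.

### Scoring

*Summed weight*: f(x) = Σ_{x_i ∈ P} K(x_i, x), computed with exactly
rounded summation (`math.fsum`) so results do not depend on addend order.
A positive example's self-term is excluded: the connection weight of a
gene to itself is defined as 0 throughout, preventing a trivially
separating identity feature.

*SVM*: each gene's feature vector is its connection weights to the n_p
positives. The classifier is a soft-margin linear SVM (hinge loss, dual
solver, C = 1 by default) with class weights inversely proportional to
class frequencies — necessary because n_n/n_p is typically 10–1000. The
default feature space uses all n_p positives as columns in every
bootstrap round ("fixed" mode); a "strict" mode restricts columns to
in-bag positives, removing the mild test-identity leakage of fixed
columns at the price of a round-varying feature space. Default mode keeps
the feature-space definition and n_p dimensionality of the method as
described; the strict option exists for hygiene-sensitive comparisons.

*Bootstrap aggregation*: per round, |universe| genes are drawn with
replacement; genes never drawn (~e⁻¹ of the universe) are out-of-bag and
receive a recorded decision value. Final score = per-gene median of
recorded out-of-bag values over 25 rounds (default). A training draw
lacking one of the classes is redrawn, at most 10 times. Genes that are
never out-of-bag across all rounds (probability ≈ (1−e⁻¹)²⁵ per gene, so
rare at 25 rounds but certain at 1 round) are scored by a model trained
on all genes and flagged `never_oob`; leaving them unscored would break
the ranking contract. Randomness is a single top-level seed; round r uses
substream seed + r, making the whole procedure bit-reproducible.

### Calibration

Raw decision values for positives and negatives are each fitted with a
normal distribution (sample mean, sample SD with ddof = 1; an SD of zero
is floored at 1e-6 with a warning). Bayes' rule with these two densities
maps a score X to p(y|X). The class prior defaults to the empirical
prevalence n_p/(n_p + n_n) (configurable to 0.5). Scores strictly below
μ_n are assigned probability exactly 0; X = μ_n is calibrated normally
(the cutoff is "lower than", not "at"). Far in the upper tail, where both
densities underflow, the implementation switches to log-density
arithmetic so the probability approaches 1 instead of 0/0. With equal
class variances and μ_y > μ_n the mapping is monotone for X ≥ μ_n, so
calibration never changes rank-based evaluation.

### Evaluation

Genes are sorted by score descending; tied scores form a single threshold
group (no intra-tie ordering credit — deterministic and optimism-free).
At each distinct threshold: precision = TP/(TP+FP), recall = TP/n_p.
AUPRC is the step sum Σ ΔR·P over curve points, consistent with the
achieved-point convention for precision-at-recall (the precision of the
first point with recall ≥ r, no interpolation). Under these conventions
a perfect ranking has AUPRC exactly 1 and an all-tied ranking exactly the
prevalence. Fold over random divides a precision (or AUPRC) by the
prevalence. Bootstrapped evaluation always uses the single out-of-bag
median score vector, not per-round curves.

### Network integration

Evidence sources are discretized per unordered gene pair into B bins.
Against a pair gold standard, each source's conditional probability table
is the Laplace-smoothed bin frequency among positive and among negative
pairs (pseudocount 1 by default); pairs a source does not cover fall into
an explicit extra "missing" bin, which is added automatically only when
needed — a source that covers every queried pair keeps its declared B
bins, so its CPT denominators are n + B·pseudocount. Sources are combined
by naive Bayes (conditional independence given relationship status), in
log space for numerical stability. This is deliberately the minimal
integration model: structured dependencies between sources are out of
scope, and per-source preprocessing/binning of real datasets is the
caller's responsibility.

### Locus overlap

Coordinates are 1-based, intervals closed, and touching endpoints count
as overlap (matching centimorgan usage; the convention is stated to avoid
the 0/1-based trap). Loci may be expanded symmetrically (e.g. a 5 cM
window around QTL peaks). The test universe is the positioned genes
intersected with the prediction universe; the reported result always
carries (k, x, K, N) alongside p so the universe choice is auditable.
p is the inclusive upper tail P(X ≥ x) of the hypergeometric
distribution.

## Synthetic data: what it emulates, and what it does not

The generator produces, from one seed: a rooted tree ontology (optionally
with one diamond), a planted-module network, annotations with a held-out
fraction, gene positions, and locus sets.

Defaults — 1000 genes, five modules of 50, within-module weights
Beta(8, 2) (mean 0.8), background edges at 5% density with weights
Beta(1, 9) (mean 0.1), 40% annotation holdout — give a separable but
noisy signal at a held-out prevalence of ~2%: strong enough that both
rankers beat chance by a wide margin, weak enough that ranking quality is
informative.

Hub genes model promiscuous connectors. Each non-hub gene x carries an
affinity a_x ~ Beta(8, 2) drawn once; hub h connects to x with weight
clip(s_h · a_x) where s_h ~ U(0.85, 1.15). Two consequences are intended:
(i) a hub's summed weight to a module's observed positives (~n_obs·0.8)
interleaves with genuine members' scores, so the summed-weight baseline
ranks hubs among held-out positives; (ii) all hub feature vectors lie
near a ray through the shared profile (a_{p1}, ..., a_{p n_p}), while
member vectors scatter isotropically around 0.8·**1**, so a linear
classifier that has seen hubs as training negatives can separate them.
This is the package's operationalization of the known failure mode of
weight summation on hubby networks; it is a modelling choice, not a
property of any particular real network.

What the generator does **not** emulate: realistic degree distributions
and edge-weight correlations of integrated functional networks, biased
annotation depth across phenotype areas, ontology cross-links beyond one
diamond, realistic genome coordinates, or linkage-disequilibrium
structure in loci (synthetic loci are placed independently of modules, so
enrichment p-values on synthetic data are calibrated but unremarkable).
Passing tests therefore demonstrate correctness of the machinery and the
qualitative SVM-vs-baseline relationship under the planted model — not
performance levels on real mouse data.

Locus sets are grown by proposing random intervals (2% of a chromosome
each) and accepting while coverage stays below target + 2%, stopping at
target − 2%; coverage targets within 2% of 1 degenerate to
whole-chromosome loci.

## Numerical choices and degenerate inputs

- Duplicate network edges keep the maximum weight (deterministic,
  monotone); self-loops are dropped with a warning; absent pairs score
  `default_weight` (0 unless configured — released edge lists are
  thresholded, and 0 is the conservative completion).
- Network TSV output prints 17 significant digits so read/write round
  trips are exact.
- A gene absent from the network is still scorable (all-default feature
  vector) with a warning, rather than an error.
- `LinearSVC` runs with a fixed internal random_state and tight
  tolerance, so fits are deterministic given identical inputs.
- Problem sizes in the test and acceptance workloads (1000-gene networks,
  10 replicate seeds, 25 bootstrap rounds) were chosen as the smallest
  configuration at which between-seed variance is visibly smaller than
  the method differences being asserted.

## Known limitations

- The SVM hyperparameters (C, solver) are conventions, not recovered
  values; results on real data should be read with that freedom in mind.
- Naive-Bayes integration ignores between-source dependencies and will
  overcount correlated evidence.
- Treating all unannotated genes as negatives deflates measured precision
  when annotations are incomplete; the bootstrap mitigates but does not
  remove this.
- The dense in-memory network representation targets desk-scale analyses
  (up to a few thousand genes); genome-scale networks would need a sparse
  backend behind the same interface.
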