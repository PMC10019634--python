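# Methods

## Problem setting

`phenomkl` classifies ion-channel missense variants into net gain-of-function
(GOF, +1) versus net loss-of-function (LOF, −1) from three data modalities:
clinical phenotype annotations (sets of ontology terms), numeric
sequence/structure descriptors, and the variant's channel within a channel
taxonomy. All three are converted to kernels and fed to a C-SVM; the package's
contribution is the phenotype kernel and its integration through multi-task
and (localized) multiple-kernel learning.

## Phenotype semantic similarity

Annotations are propagated before any similarity is computed: every ancestor
of every annotated term, up to the ontology root, is added to the set
(reflexive transitive closure over IS-A edges). Only IS-A relations of the
OBO input are honored; obsolete terms are dropped; the parser requires a
single root and an acyclic graph.

Information content is corpus-relative: IC(t) = −log₂(n_t/n) where n_t counts
the propagated sets containing t. The corpus is the full cohort's propagated
sets; after propagation the root occurs everywhere, so IC(root) = 0, and IC is
non-increasing toward the root.

Pairwise measures:

* **Jaccard** — |A∩B| / |A∪B| on propagated sets (a flag allows raw sets).
  Always PSD as a set kernel.
* **Resnik** — per term pair, IC of the most informative common ancestor
  (ancestors are reflexive, so MICA(t,t) = t; IC ties break to the
  lexicographically smallest id).
* **Lin** — 2·IC(MICA)/(IC(t₁)+IC(t₂)); a pair with both ICs zero scores 0
  (zero-information terms carry no signal, and this avoids 0/0).

Resnik and Lin are term-pair measures; variants carry sets. They are
aggregated with the symmetric best-match average
sim(A,B) = ½(mean_a max_b s(a,b) + mean_b max_a s(a,b)), the common choice in
ontology-similarity software; `max` and `mean` are available as options. This
set-level aggregation (and its interaction with propagation) is a design
choice of this package.

## Indefinite kernels and spectral correction

On multi-parent ontologies the Resnik/Lin matrices are generally indefinite,
which breaks SVM convexity. Three spectral corrections are provided, all via
a symmetric eigendecomposition S = VΛVᵀ:

* **clip** — negative eigenvalues set to zero (the Frobenius-nearest PSD
  matrix);
* **flip** — eigenvalues replaced by their absolute values (the matrix's
  singular values);
* **shift** — S + |λ_min|·I, applied only when λ_min is genuinely negative;
  off-diagonal entries are untouched.

PSD checks use a relative tolerance, λ_min ≥ −1e−8·max(1, λ_max): float noise
near zero eigenvalues is expected for Jaccard matrices with near-duplicate
rows. In cross-validation the phenotype matrix is built and corrected once on
the whole cohort and fold blocks are sliced from it — the correction is
spectrum-global, and term frequencies are cohort-level statistics rather than
label information. For workflows that must embed genuinely new samples into a
clip/flip-corrected kernel, `kernels.embed_test_columns` applies the training
eigenbasis transform (s → s·V g(Λ)Λ⁺Vᵀ); shift leaves off-diagonals
unchanged, so new rows pass through.

## Task and structure kernels

The structure kernel is the Gaussian RBF with bandwidth σ. Besides the
canonical grid {1e−5 … 1}, σ = "median" selects the median pairwise distance
(median heuristic), which adapts the bandwidth to the feature scaling of the
cohort at hand; synthetic cohorts use it by default.

Task similarity comes from a rooted taxonomy with unit edge lengths:
K_task(s,t) = (a + c(s,t))/(a + c_max) with c(s,t) the number of common
ancestor nodes (reflexive) and c_max the maximal self-count. The baseline
a > 0 sets the floor: a → ∞ makes all tasks identical (the pooled limit). The
exact functional form is this package's surrogate for an alignment-derived
tree distance; it is monotone in tree proximity, equals 1 for deepest leaves,
and is pluggable. The multi-task kernel is the Schur product of the expanded
task kernel with the structure kernel, PSD whenever both factors are.

## Multiple-kernel combination

All modality kernels are feature-space normalized (k̂ = k/√(k·k), unit
diagonal, idempotent) before combination K = Σ β_m K_m.

* **Uniform** weights: β_m = 1/M.
* **Global learned** weights: a wrapper search maximizing inner-CV AU-ROC —
  exhaustive simplex grid at resolution 0.1 for M ≤ 3 modalities,
  deterministic coordinate ascent from uniform above that. Ties keep the
  earliest candidate in a fixed enumeration, making results reproducible.
* **Hierarchical decomposition (localized)**: every node n of the taxonomy
  defines the task subset S_n = leaves(n) and the masked kernel K_leaves(n)
  (zero outside the subset's sample block). Modality weights are learned per
  node on that node's block by the same wrapper; blocks with fewer than 10
  samples or a single class fall back to uniform modality weights. The outer
  β over node kernels is then learned by the wrapper, and
  K̂ = Σ_n β_n K_leaves(n). Latent task similarity γ_{k,l} = Σ_{S∋k,l} β_S
  summarizes which tasks the data treat as related.

GOF is the positive class (+1) throughout; no class weighting and no
probability calibration are applied — ROC/PRC ranking uses raw decision
values.

## Evaluation protocol

Nested stratified k-fold CV, k = 5 outer and inner. Inner folds of each outer
training set choose the hyperparameters (C, σ, a, measure, correction — the
dimensionality depends on the configuration) by mean inner AU-ROC; grid ties
break toward smaller C, then larger σ. The winning configuration is retrained
on the full outer-training set and scored on the untouched outer test fold;
aggregates are the arithmetic mean and SD over outer folds. Stratification is
by label only — per-task counts are too small to stratify jointly. For the
learned-weight configurations, hyperparameters are selected under uniform
weights and the weights are then learned on the outer-training set at the
selected configuration; a joint search over weights and grid would be
combinatorial with no clear benefit at M = 3.

The `dirac` configuration trains one SVM per channel; channels whose training
block lacks both classes score test samples with the training-block class
prior. Metric conventions: degenerate 0/0 ratios (MCC, κ, F1 components)
report 0; a single-class test fold is an error rather than a silent NaN.
AU-PRC is step-function integration (average precision); AU-ROC is the rank
statistic.

## Perturbation protocol

Sparsity/noise is expressed as a term ratio r applied to raw sets before
propagation and similarity: r < 1 keeps round-half-up(r·|raw|) terms (floor
one term — a variant never loses its last annotation); r > 1 adds
round-half-up((r−1)·|raw|) terms drawn without replacement, per variant, from
the ontology's non-root terms outside the set. Under this rounding, ratio
0.25 on a 4-term set keeps exactly 1 term and ratio 4 adds exactly 3 terms
per original term. Propagation is re-applied afterwards. Everything is
deterministic given the seed.

## Confidence analysis

Training samples are projected onto the hyperplane normal; the projection is
the margin-scaled decision value f(x) (not the geometric ‖w‖-normalized
distance — the support-vector band is exactly [−1, 1] for f). Samples with
|f| ≤ 0.5 form the low-confidence group (boundary inclusive). Features are
compared between groups with two-sided Wilcoxon rank-sum tests (exact for
small groups, tie-corrected normal approximation otherwise), BH-adjusted
across features, significant at adjusted p ≤ 0.05; features constant across
both groups are recorded with p = 1 and flagged.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
channel biophysics. Defaults mirror the annotation statistics of the kind of
curated cohort the framework targets: 62 feature dimensions, 9 tasks in a
two-level taxonomy, ~45% GOF, and right-skewed raw term-set sizes (log-normal,
median 9, clipped to 3–42) over a 250-term random single-root DAG with up to
3 parents per term (enough multi-parent structure to reproduce Resnik/Lin
indefiniteness). Signal knobs: `feature_effect` shifts a ~d/6-dimensional
feature block between classes (in SD units, with task-level random
intercepts); `phenotype_effect` is the probability that an annotated term is
drawn from a class-specific preferred pool (disjoint pools per class;
per-task values allowed, planting signal in chosen subtrees);
`task_effect` draws label-uninformative task-pool terms. What passing tests
show is therefore that the pipeline recovers planted class signal and
degrades as designed under annotation sparsity/noise — not that any accuracy
level transfers to real cohorts, whose term correlations, feature
distributions and class imbalances are richer.

## Verification problem sizes

The acceptance script and test suite run at sizes chosen to exercise every
code path while staying comfortably reproducible on a laptop: 300-variant
cohorts, 10 seeds for pipeline recovery, reduced grids (C ∈ {1, 100},
σ = median, a ∈ {1, 5}, Jaccard/clip) for nested CV, the full 20×20 random
matrix batteries for the spectral oracles, and 50–100 random corpora for the
PSD properties.

## Known limitations

* The full-cohort IC/correction convention slightly couples CV folds through
  unlabeled statistics; the embedding API exists for strictly out-of-sample
  workflows.
* The task-similarity formula is a surrogate with the right limits, not an
  alignment-score kernel; swap in a custom `TaskSimilarityMatrix` if one is
  available.
* `mkl_hierarchical` is the slowest configuration (a wrapper search per tree
  node per outer fold).
* Only IS-A ontology semantics are supported; part-of and other relations are
  ignored by design.
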