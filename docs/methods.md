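# Methods

This note documents the models, estimators and design choices behind the
package, what the synthetic data does and does not emulate, and the
numerical conventions used throughout.

## Feature definitions and estimators

**Expression features.** Matrices are preprocessed by log2 (pseudocount
1.0, configurable; disabled pseudocount raises on non-positive values)
followed by quantile normalization: each sample column is replaced by the
across-sample mean of the column-sorted values at its ranks, with tied
entries receiving the mean of the reference entries over their tied
positions. exp1/exp2 are per-gene sample means. PCC and SRC are the
Pearson and Spearman (mid-rank) correlations; zero-variance inputs raise
an explicit undefined-correlation signal rather than returning 0, and the
model layer decides whether a pair is dropped or imputed.

**MI and CMI** use the plug-in estimator on discretized profiles, base-2
logarithm (bits). Discretization is equal-frequency with 8 bins by
default: bin = floor((midrank − 0.5)·B/n), so tied values always share a
bin, counts are exactly balanced for distinct values with B | n, and both
estimators are invariant under monotone transforms of the inputs. The
plug-in estimator has an upward bias of roughly (B−1)²/(2n ln 2) under
independence; tests account for it. CMI conditions on the joint
discretization of at most one panel gene by default (the panel gene most
correlated with either member of the pair); full joint conditioning over
many genes is sample-infeasible at realistic sample counts, and the cap
is configurable (`cmi_panel_cap`).

**PPC** is the full-order partial Pearson correlation: both profiles are
residualized by least squares on [1, Z] and the residuals correlated.
Rank-deficient panels fall back to the pseudoinverse solution. The
conditioning panel is a configured gene set; when none is given, the
feature assembler uses the most-variable genes in the matrix, capped at
10 (excluding the scored pair). A full all-other-genes panel is
mathematically attractive ("remove the influence of every other gene")
but violates the estimator's own requirement that samples exceed panel
size + 2 for any panel wider than the sample count, so a capped
high-variance panel is the default; callers with few genes and many
samples can pass the full panel explicitly.

**goSim.** Term probabilities come from descendant counts on the
"is a" DAG: P(o) = (|D(o)|+1)/(|D(root)|+1), with D(o) excluding o
itself so P(root) = 1 exactly and P is monotone along child→parent
edges. A term counts among its own ancestors when forming the common
ancestor set, so identical annotations give similarity exactly 1. When
the only common ancestor is the root, the numerator 2·log P(ms) is 0 and
the similarity is defined as 0. Genes are compared on their directly
assigned terms; up-propagating annotations before the max would be
redundant because the most-specific-common-ancestor search is already
ancestor-aware.

**lcSim** is the Jaccard index of cellular-component sets; two empty
sets are a missing feature, not 0.

**hgSim** is algebraically the φ coefficient — the Pearson correlation
of the two binary profiles — and is exercised against that identity in
tests. Profiles that are all-absent or all-present (n = 0 or n = N) have
a zero denominator and surface as missing rather than being clamped.
The species panel defaults to N = 21.

**rxSim** = 1 − dis/dis_max with dis the unweighted shortest-path
distance on the pathway-interaction graph and dis_max the largest finite
pairwise distance. Disconnected pairs are treated as being at dis_max
(similarity 0); the same-gene distance is 0 (similarity 1). Per-gene BFS
results are cached.

**trSim** is a direction-agnostic membership test: the pair
canonicalization used everywhere else (lexicographic ordering) erases
regulator/target order, so a recorded interaction in either direction
scores 1.

## Model layer

Features are min-max scaled to [0, 1] per feature, fitted on training
data only; constant features map to 0.5 with a warning. The scaler is
part of the serialized model. Missing features are either dropped with
the pair (expression features are mandatory; by default a pair survives
at most 2 missing knowledge features) or imputed at 0.5 *in scaled
space* — the bounded space is what makes a mid-point imputation
meaningful, and it mirrors the protocol of scoring genes that have no
prior knowledge.

Training solves the soft-margin linear-SVM dual via LIBSVM/SMO
(scikit-learn `SVC`), default C = 1.0, tolerance 1e−4, deterministic
given the seed. The returned model keeps the support vectors and dual
coefficients so the KKT conditions (dual balance Σα_i y_i = 0, box
constraints, complementary slackness, margins of non-support points) can
be verified directly; the test suite does so. The score is the plain
logistic sigmoid of the decision value — no Platt recalibration — so
scores are monotone in each feature according to its weight sign.

The published 12-weight scorer ships the printed weight vector verbatim
with an identity scaler. Its bias term was never published; it defaults
to 0 and is a parameter. Exact reproduction of that weight vector by
retraining is not expected: the training corpus behind it, its feature
scaling and its C are all unavailable.

CXP averages the five *scaled* coexpression features; raw MI/CMI are
unbounded in principle and would dominate an unscaled mean.

## Evaluation

AUC uses the average-rank Mann–Whitney formula, which equals trapezoidal
integration of the tie-grouped ROC curve exactly — including in floating
point, which is why the suite can assert bitwise equality against a
brute-force pairwise comparison. B0/B1 matched pairs are defined on raw
feature values as (PCC > t or SRC > t) and goSim > t and lcSim > t, at
t = 0.5 and 0.3 respectively — the disjunction covers the two expression
correlations, the conjunction the two knowledge similarities — so B0 ⊆
B1 by construction. Top-k% counts are floor(k%·n), minimum 1.

Cross-validation is 81/9/10: a stratified 10% test split is held out
once; the remaining 90% is split into 10 label-stratified folds, each
round training on 9 folds (81% of all pairs) and developing on 1 (9%).
The box constraint maximizing mean development AUC wins (ties prefer the
smaller C), the model is refitted on the full 90% and evaluated once on
the test split. Reports are deterministic given the seed.

Dataset assembly mirrors the three source types: coexpression positives
are each gene's top-n ranked partners (default 50) with negatives from a
centered middle window of the ranked list (default 80, read as a
centered contiguous window); pathway positives share at least 3 pathway
memberships with random different-pathway negatives; regulatory
positives are the recorded pairs with negatives from random
regulator×target permutation, disjoint from all positives and balanced.
Only negative sampling consumes randomness, so positives are identical
across seeds. The generation can be repeated (100 repeats in the
original protocol; configurable) since negatives are resampled each
time.

## Networks and function prediction

Mutual Rank is √(rank_i(j)·rank_j(i)) on descending score ranks with the
self-score excluded and ties averaged; the matrix is symmetric even for
asymmetric input scores. The top-3 graph uses the union rule — an edge
exists if either endpoint ranks the other among its 3 smallest MR values
— which guarantees minimum degree 3 and a usable connected graph where
an intersection rule often fragments. Modules come from
Clauset–Newman–Moore greedy modularity maximization (networkx).

Up-regulation calling is the conjunction fold-change > 1.5 and BH
q < 0.05 from a Welch two-sample t-test on the log2 values. Fold change
is computed on the linear scale (ratio of means of 2^x) by default
because a ratio "between average expression levels" is ambiguous on log2
matrices; a log2-difference variant is a flag. The t-test is a plain
Welch test; an empirical-Bayes moderated variance in the style of
microarray linear-model pipelines is a documented possible extension,
not the core path. Enrichment is the hypergeometric upper tail
P(X ≥ k) = 1 − Σ_{i<k} C(K,i)C(N−K,n−i)/C(N,n) with BH correction,
default universe N = 18,420 genes and enrichment cutoff q < 0.01.

Function prediction uses edge length 1 − weight (weights are
relatedness in [0, 1] after rank normalization onto a reference score
distribution; edges with weight < 0.6 are removed, weight exactly 0.6 is
retained). All shortest paths between every pair of annotated genes are
enumerated; a query gene interior to such a path receives the deepest
common ancestor(s) of the path's annotated genes' term sets, where the
level of a term is the length of its *longest* path to the root (well
defined on multi-parent DAGs). The depth rule is implemented literally —
an ancestor is assigned when its level is below the threshold (default
3) — with an `invert_depth_rule` option assigning deep (specific)
ancestors instead; the literal rule keeps only near-root generic terms,
which contradicts the usual intent of shortest-path annotation transfer,
so both readings are exposed and neither is claimed as canonical. L0
counts a gene whose predicted term is among its known terms; L1 counts a
direct-parent match; the two rates are independent fractions of all
query genes.

## Synthetic data

Expression uses a latent-factor Gaussian model: x_g = baseline +
sd·(√ρ·f_m + √(1−ρ)·ε), giving expected within-module PCC ρ and
between-module PCC 0 analytically. Knowledge resources plant the same
module structure: with probability equal to the coherence parameter a
gene carries its module's ontology term block, organelle label,
species-presence pattern (bits flipped at rate 0.1) and pathway-clique
membership; otherwise it draws random annotations. Modules come in three
kinds — coexpressed+coherent ("both"), coexpressed only, coherent only —
so labeled pair sets can plant exactly the signal a comparison needs;
negatives always pair genes across modules. Defaults (300 genes, 100
samples, ρ = 0.8, coherence = 0.9, 21 species) are the study conditions
used by the acceptance runner; the examples use smaller instances of the
same generator. Every generator is a pure function of its spec and seed.

What the generator does *not* emulate: microarray/RNA-seq noise shapes
(heteroskedasticity, counts), batch effects, realistic GO topology
(thousands of terms, multiple namespaces with cross-links), annotation
evidence codes, or real gene identifiers. Passing tests therefore
demonstrate correctness of the algorithms and the direction of the
methodological claims under planted structure, not performance levels on
real compendia.

## Problem sizes and determinism

The bundled experiment runs use 10 seeds × 2,000 pairs for the
mixed-signal tournament, 2,000 pairs for the null cross-validation,
1,000 genes × 20+20 samples for the null up-regulation calibration and
20 seeded runs of the 60-gene network pipeline — sizes chosen so the
whole reproduction finishes in minutes on a single core while keeping
the binomial/win-count assertions well separated from their thresholds.
All randomness flows through explicitly passed `numpy` generators seeded
from a single integer; no global RNG state is used, and repeated runs
are bit-identical.
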