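# Methods

## Hypervector algebra

The package uses the Multiply–Add–Permute (MAP) vector-symbolic
architecture over integer vectors of dimensionality *d* (default 10 000).
Atomic symbols are bipolar (±1) vectors with i.i.d. uniform components; at
*d* = 10 000 the cosine of an independent pair is approximately normal with
standard deviation 1/√d = 0.01, so random symbols are quasi-orthogonal.
Binding is the element-wise product (self-inverse on bipolar input),
bundling the element-wise integer sum, and permutation a cyclic rotation;
permutation distributes exactly over both. All vector arithmetic is
integer-exact — no floats are stored in vectors — so bundling and
retraining are bit-for-bit reproducible given the seed. Cosine similarity
is computed in double precision; a comparison involving an all-zero vector
(class vectors can cancel during retraining) returns 0 with a warning
rather than raising, so prediction never crashes.

## Level vectors and quantization

Scalar values are represented by an ordered family of *L* level vectors.
The family starts from a random bipolar base; each subsequent level flips
the sign of *N* = ⌊*d*/2*L*⌋ positions. Flip positions are consumed in
consecutive disjoint blocks of one global random index permutation, so a
position flips at most once across the family (*N*(*L*−1) ≤ *d*/2
guarantees feasibility) and the similarity law

cos(ℓᵢ, ℓⱼ) = 1 − 2*N*|i−j|/*d*

holds exactly for every pair, which the tests verify to 1e−12. The
flip-position policy was a genuinely open design point (any random choice
preserves adjacent similarity on average); the disjoint-block construction
was chosen because it makes the similarity law exact and testable. *L* = 2
(binary data) follows the same formula with no special-casing: *N* = *d*/4
and adjacent cosine 0.5. Requesting *L* ≥ 2 with *d* < 2*L* is an error
(zero flips would collide levels).

Quantization maps [min, max] onto levels with uniform right-closed bins:
index 0 for x ≤ min, otherwise ⌈(x − min)/w⌉ − 1 with w = (max − min)/L,
capped at L − 1. With range [0, 100] and L = 100, the values 0.1 and 1.0
deliberately share level 0 — nearby magnitudes collapsing onto the same
level vector is intended behaviour, not a defect. The range is the *global*
min/max of the training portion of each cross-validation fold (one level
set per dataset, not per feature); fitting on train only avoids test-set
leakage. Out-of-range test values are clamped with a warning.

## Sample encoding

A sample is encoded as Σ_f ρ^{p_f}(ℓ(x_f)): each feature's level vector
rotated by the feature's position and bundled. Under feature subsets the
position defaults to the feature's *original* column index in the full
table. This keeps encodings additive across elimination rounds — the
encoding of a subset equals the full encoding minus the rotated level
vectors of the removed features, exactly — which the selection evaluator
exploits to derive candidate encodings by integer subtraction instead of
re-encoding (the tests assert exact agreement with a from-scratch
evaluator). Subset-relative positions would carry the same discriminative
content but forfeit the incremental identity.

## Classifier and retraining

Class vectors are the bundles of their training samples' encodings.
Retraining iterates over training samples in dataset order (no shuffling);
each misclassified sample's vector is subtracted from the wrongly predicted
class vector and added to the true one, which conserves the element-wise
sum of all class vectors — an invariant checked after every retrain call.
Convergence is equality of consecutive integer error counts (not a
tolerance on rates), with a hard cap of *R* passes (default 10) guarding
against oscillation. Prediction ties are broken by the first class in
declared (sorted) label order, for determinism.

Cross-validation uses seeded class-stratified folds
(scikit-learn's `StratifiedKFold`, shuffle on), so small imbalanced strata
cannot produce empty-class folds; the fold plan is a pure function of
(labels, k, seed) and is shared by every candidate subset within a
selection run, making candidate accuracies directly comparable. The
reported accuracy is the arithmetic mean of fold accuracies. Per-class
precision/recall/F1 use one-vs-rest counts; zero-denominator ratios are
reported as 0 and flagged.

## Backward variable elimination

Accuracies in the wrapper are percentages. The acceptance band is
*relative*: cutoff = best × (1 − u/100), compared without rounding
(display flooring only), e.g. best 93% at u = 5% gives 88.35, displayed 88.
Each iteration removes *every* feature whose exclusion scored at or above
the band — multi-feature removal per iteration — rather than only the
single best; with u = 0 and distinct accuracies this degenerates to classic
one-feature-per-step elimination. Termination: (i) initial model below the
threshold *T* (nothing removed); (ii) no candidate reaches *T*;
(iii) an iteration's best accuracy falls below the *previous* iteration's
best by more than the uncertainty band — the iteration is rejected, its
removals are not applied; (iv) features exhausted. The banded decrease rule
(rather than any strict decrease) is what makes the documented five-feature
walkthrough self-consistent: an iteration scoring 90% after one scoring 93%
continues at u = 5% (90 ≥ 88.35), while a later 75% stops the run
(75 < 85.5). The comparison is against the previous accepted iteration's
best, not a global best — the two coincide in every case exercised here.

Each evaluated candidate subset counts once toward `models_evaluated`
(its k fold-models are detailed in the trace). The suboptimal frontier
scans *all* evaluated models — including the rejected final iteration's —
for the fewest-feature model strictly above the accuracy floor (default
70%), breaking size ties by higher accuracy, then earliest evaluation.
Forward selection is available as a library helper (`forward_select_order`)
but is not part of the primary workflow.

## Preprocessing of microbial profiles

Profile tables are parsed at species level only (lineages whose lowest rank
is `s__`, no strain `t__` suffix), plus the reserved `unclassified` row.
"Detected" means RA strictly > 0, matching the binarization rule
(1 iff RA > 0). Operations are pure and conserve per-sample total RA to
1e−9: a removed species' abundance is added to `unclassified`, never
discarded. The filter order is cross-study intersection (keep species
detected in every study) → low-abundance (maximum RA across samples below
the threshold, default 1%; the maximum is the most permissive reading of
"very low abundant" and is configurable) → low-prevalence (detected in
strictly fewer than the threshold percent of samples, default 5%). Age
stratification uses adult = age ≤ 65, senior = age > 65; adenoma samples in
metadata are dropped with a warning.

## Differential-abundance statistics

Per species: prevalence per class (percent of samples with RA > 0), log2
fold change log2(mean_case/mean_control) with explicit ±inf/NaN sentinels
when a class mean is zero (no silent pseudocount), and a two-sided Wilcoxon
rank-sum test via `scipy.stats.mannwhitneyu` — normal approximation with
tie correction by default, exact p-values available through
`method="exact"` since neither convention is canonical at these sample
sizes. Benjamini–Hochberg q-values are the step-up
q_i = min_{j≥i}(p_j·m/j) clipped at 1, implemented in-package and
cross-checked in the tests against statsmodels on random p-vectors.
Significance is p ≤ 0.05 and q ≤ 0.2 by default; the |log2FC| ≥ 1 cut is a
reporting filter, not part of the test.

## Synthetic data

The binary generator plants `n_informative` features whose per-class
presence probabilities differ (defaults 0.85 in cases vs 0.15 in controls,
background 0.30 everywhere else, 100 + 100 samples, 50 features) —
mirroring the regime in which real discriminative species operate, where
case/control prevalence gaps (e.g. ~46% vs ~10%) carry the signal. The
background prevalence of 0.30 matches the mid-range prevalence typical of
retained species after filtering. The RA generator layers gamma-distributed
abundances on the same presence pattern and pads each sample with an
`unclassified` remainder so columns sum to exactly 100; binarizing it
recovers the presence pattern. Draws are independent Bernoulli per cell:
the generators do not emulate compositional coupling, zero inflation beyond
the presence process, batch/study effects, or correlated taxa — so passing
tests demonstrate correctness of the algorithms under the assumed signal
structure, not performance on real microbiomes.

## Problem sizes and numerical choices

The test suite and reference runs use the defaults above at full
dimensionality (d = 10 000) for the planted-recovery checks (200 samples ×
50 features; the complete elimination run evaluates ~64 candidate models)
and reduced dimensionality (d ≈ 2048–4096) for auxiliary integration
tests, which keeps the whole suite under a minute on one CPU while
exercising the same code paths. Determinism is end-to-end: level vectors,
fold plans, generators, and retraining order all derive from explicit
seeds, and two identical seeded `select` runs produce byte-identical
traces.

## Known limitations

* The wrapper's cost grows with |S|² candidate evaluations; no heuristic
  pruning or distributed evaluation is provided.
* Only dense bipolar/integer hypervectors are implemented (no binary 0/1 or
  sparse variants, no GPU path).
* The classifier gives hard labels only — no calibrated probabilities.
* Quantization is uniform and global; heavily skewed RA distributions may
  occupy few levels (binarization is the recommended representation, and
  empirically the more accurate one).
* The stop-on-decrease comparison uses the previous accepted iteration's
  best accuracy; a run whose accuracy dips and recovers would terminate at
  the dip.
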