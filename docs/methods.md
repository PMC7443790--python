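# Methods

This note documents the models and procedures implemented in `lingbrain`, the
choices made where several defensible options existed, and what the synthetic
data can and cannot establish about behavior on real cohorts.

## Linguistic features

Each subject contributes one plain-text interview transcript, assumed already
restricted to participant speech (a speaker-prefix filter is available but off
by default). Sentences are split on terminal punctuation with an abbreviation
guard; runs of terminators (ellipses, `?!`) collapse into a single boundary.
Tokens are whitespace-delimited with punctuation stripped from their edges.

Three feature families are extracted per subject (44 features total):

* **Amount of speech** — minimum, maximum, mean, and standard deviation of
  words per sentence. All standard deviations in the package are sample
  standard deviations (n − 1), zero for a single observation.
* **Semantic coherence** — a latent semantic analysis space is built from a
  background corpus (by default the analyzed corpus itself): the term–passage
  count matrix (passage = sentence) is weighted (log-entropy by default; tf
  and tf-idf available) and decomposed by truncated SVD; a word vector is the
  corresponding row of `U_k S_k` (default k = 50). A sentence vector is the
  mean of its in-vocabulary word vectors; coherence is the cosine between
  consecutive sentence vectors, summarized by min/max/mean/sd. Pairs in which
  either sentence has no in-vocabulary token are skipped (the cosine is
  undefined there; scoring them 0 would fabricate incoherence) and the skip
  count is reported. The space can be persisted (vocabulary, vectors, manifest
  with a corpus hash) so coherence features are reproducible across runs.
* **Syntax** — relative frequency of each of the 36 word-level Penn Treebank
  part-of-speech tags. The tagger is a deterministic rule/lexicon tagger:
  closed-class words from an explicit lexicon, open-class words from ordered
  morphology rules (numerals, casing, derivational suffixes), and one-token
  left context for infinitives. Tokens outside the word-level tagset pool into
  an `other` bucket that completes the simplex (frequencies sum to 1) but is
  excluded from the analysis feature set. The tagger is built for
  reproducibility and for the synthetic grammar below, not for competitive
  accuracy on open-domain English; on real transcripts a statistical tagger
  would misclassify less, which would shift tag frequencies but not the
  pipeline mechanics.

Cohort-wide, a feature is dropped as degenerate when one value's share of the
sample **strictly exceeds** a threshold (default 0.5); a modal share of exactly
one half is retained. The filter runs on the raw matrix before z-scoring, is
idempotent, and reports what it dropped.

## Connectivity and morphometry

Resting-state input is a node × timepoint panel per subject, with nodes
grouped by a six-network atlas (LAN, DMN, ECN, SAL, SMN, AN; any node
granularity — parcels or voxels — is accepted). Two statistics summarize it:

* **Cohesiveness** (one per network): the mean over all unordered within-
  network node pairs of the Fisher-z transformed Pearson correlation.
* **Integration** (hub-centric): the Fisher-z correlation between the average
  time series of the hub network (LAN by default) and of each other network.

With six networks this yields 6 + 5 = 11 measures per subject. A literal
all-pairs integration (15 pairs, 21 measures) is available via `all_pairs=True`
for atlases where a hub is not meaningful. Correlations are clipped to
|r| ≤ 1 − 1e−7 before `atanh`, so duplicated series produce a large finite
value (≈ 8.4) rather than infinity.

Morphometry arrives as a TSV validated against a named schema — by default 68
Desikan–Killiany cortical thickness features (34 regions × 2 hemispheres, mm)
and 20 subcortical volumes (10 bilateral structures, mm³). Values must be
positive; missing values fail loudly unless mean imputation is explicitly
requested (and then it is logged in the matrix metadata).

## Site harmonization (ComBat)

Imaging blocks (connectivity and morphometry, separately) are harmonized
across acquisition sites with parametric empirical-Bayes ComBat before
z-scoring and sCCA; language and clinical blocks are never harmonized. Per
feature g: a least-squares fit of intercept, batch indicators, and optional
protected covariates; standardization by the pooled residual variance;
per-batch location (normal prior) and scale (inverse-gamma prior) estimated by
method of moments across features and shrunk by iterated conditional
posteriors (tolerance 1e−6, cap 200 iterations). A single-batch fit reduces to
an exact identity transform. The estimator was checked against
`sva::ComBat` (Bioconductor) on a shared fixture: agreement to ~1e−6.

Two properties worth knowing:

* EB shrinkage intentionally leaves per-feature *empirical* batch moments
  slightly unequal when the true batch effect is shared across features (the
  shrunken estimate is closer to the truth than the per-feature sample
  moment). Batch-effect removal should therefore be judged on group
  statistics, which is how the tests measure it.
* Grand means are preserved only up to the shrinkage scale (≈ 0.01 σ at the
  tested sizes), exactly as in the reference implementation.

Covariates to protect (e.g. diagnosis, age) are configurable; the default is
none.

## Sparse canonical correlation analysis

Blocks are z-scored column-wise (sample sd; constant columns are an error —
the degenerate filter runs first). For z-scored X (n × p1) and Y (n × p2), a
mode is a pair of unit-norm weight vectors with ‖u‖₁ ≤ c1, ‖v‖₁ ≤ c2
maximizing the penalized covariance u′X′Yv (the penalized matrix
decomposition objective); the reported canonical correlation r is the Pearson
correlation of the scores Xu and Yv. Note the objective is covariance, not
correlation — the two optima can differ visibly at strongly binding budgets,
and the package is deliberately faithful to the PMD convention.

Implementation details that matter:

* **Projection.** The update u = S(a, λ)/‖S(a, λ)‖₂ needs the smallest λ ≥ 0
  with ‖u‖₁ ≤ c. The ratio ‖S‖₁/‖S‖₂ is non-increasing in λ and piecewise
  algebraic with breakpoints at the sorted |a|, so λ is found exactly by
  solving a quadratic on the correct piece; a bisection fallback guards
  degenerate geometry, and tied maxima at c = 1 (where no soft-threshold point
  is feasible) return the one-hot at the lowest tied index. The solver is
  vectorized across columns, which is what makes the permutation null
  affordable.
* **Iteration.** Alternating updates on M = X′Y until the maximum weight
  change is below 1e−8 (cap 500), initialized from the leading singular pair
  of M **and** from a one-hot at the largest |M| entry; the start with the
  larger final objective wins. With binding budgets the alternating scheme is
  only locally convergent and the basins disagree on roughly 10% of random
  instances, which single-start implementations silently mis-solve.
* **Sign convention.** (u, v) are jointly flipped so the largest-|weight|
  entry of u is positive; r is unchanged.
* **Sparsity selection.** A 10 × 10 grid, linear in [1, √p] per side; the
  point with maximal r wins, ties broken toward the sparser model
  (smaller c1 + c2), then lexicographically.
* **Inference.** Rows of Y are permuted (permuting one side suffices to break
  the cross-block association); for every permutation the full grid is
  re-searched and the maximum r over the grid recorded, so the p-value
  p = #(permuted max > observed)/n_perm is corrected for the sparsity
  selection. The (k+1)/(n+1) estimator is reported alongside as
  `permutation_p_plus_one` for users who need strictly positive p-values.
  Default n_perm = 10,000; fewer than 100 is refused outside test mode.
* **Further modes.** The cross-product is deflated by the extracted rank-1
  component at the mode-1 sparsity (no re-search per mode, so the mode-1 null
  is untouched); each further mode's unadjusted p compares it against
  same-order modes from permuted data.
* **Indicators.** Binary metadata (diagnosis, handedness) can be appended to
  the language block as ordinary columns, z-scored with the rest; diagnosis is
  coded CHR = 1 / HI = 0.

All solver randomness sits behind one integer seed; a full analysis
serializes to JSON byte-identically across reruns.

The batched engine advances every (permutation × grid point) problem in
lock-step with a compacting working set, so the calibration experiment
(200 replicates × 200 permutations × 100 grid points) runs in minutes on one
core rather than days.

## Synthetic data

The generator produces complete studies with known ground truth; defaults
mirror a two-site case–control cohort of 46 CHR and 22 healthy subjects.

* **Transcripts** are sampled from six part-of-speech templates (declarative,
  question, fragment, conjunctive, subordinate, interjection-initial) over a
  synthetic vocabulary of pronounceable pseudo-stems partitioned into topics,
  with real English closed-class words. Content words carry unambiguous
  morphology (`-ed`, `-ing`, `-ly`, `-ful`) so the rule tagger resolves them
  deterministically. Consecutive sentences share a topic with probability
  1 − drift, which is the knob that moves LSA coherence; sentence lengths are
  Poisson around a target mean (default 8 words, 40 sentences — scaled to
  desk-size runs rather than full half-hour interviews). What this does *not*
  emulate: real lexical statistics, disfluencies, tagger error, interviewer
  contamination — so passing recovery tests demonstrates pipeline
  correctness, not clinical validity.
* **Linked blocks** plant one sparse mode: latent s, t with corr(s, t) = ρ,
  X = a·s·w_x′ + E. The effect-size convention is a = √k for a k-sparse unit
  weight vector, i.e. each active feature carries signal at the noise level
  (per-feature SNR 1). This is the weakest regime in which support recovery
  at the tested sizes is achievable at all: with a = 1 the planted mode sits
  below the noise spectral edge of X′Y (leading noise singular value ≈ 1.4 vs
  signal 0.7 at n = 200, p = 100) and no estimator can find it. Optionally the
  noise is projected off the planted directions, making the mode's canonical
  correlation exactly ρ. "Support" in recovery checks means the k largest
  |weights| — max-r grid search deliberately overselects, so the nonzero set
  is the wrong recovery target.
* **Time-series panels** follow a one-factor model per network,
  node = √w·f_net + √(1−w)·ε, so the expected within-network pair correlation
  is w; non-hub factors are correlated with the hub factor at a level
  calibrated to hit a target hub-to-network mean-series correlation after
  noise attenuation of the averaged series (unreachable combinations are
  rejected).
* **Morphometry** uses plausible per-feature scales (thickness 2.5 ± 0.15 mm;
  structure-specific volumes, CV 8%) with an optional planted latent loading,
  floored at 10% of the feature mean so values stay positive.
* **Metadata** includes diagnosis, site, Edinburgh-style handedness, and 19
  ordinal clinical items (5 positive, 6 negative, 4 disorganized, 4 general)
  with higher CHR severity.

All generators are pure functions of (parameters, seed).

## Numerical and degenerate-input conventions

Pearson correlations use mean-centered series with the n − 1 covariance
convention (the choice cancels in r). Zero-variance nodes, constant features,
unseen batch labels, misaligned subject sets, and already-z-scored blocks all
raise named errors rather than propagating NaNs. Ties are broken by index
order throughout. Rank-deficient semantic spaces reduce k with a warning.
Fully deflated cross-products freeze the current iterate rather than dividing
by zero.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale, chosen so the whole
suite completes in minutes while every statistical check retains power: the
permutation calibration uses n = 60, 10 + 10 features, 200 replicates × 200
permutations; recovery uses n = 200 with 100 features per block; ComBat checks
use 2 × 200 subjects × 30 features (500 for the null-change audit); the
end-to-end study uses the default 68-subject cohort with 40-sentence
transcripts, 20-node networks at T = 200, and 300-permutation analyses.

## Known limitations

* The rule tagger is adequate for the synthetic grammar and common English
  function words; rare tags (FW, LS, PDT, RP, SYM, POS) are essentially
  unreachable on synthetic text and will be dropped by the degenerate filter.
* LSA spaces built from small own-corpus backgrounds are noisy; for real
  studies a larger background corpus should be supplied and persisted.
* The hub-centric integration reading (11 measures) is one reconstruction of
  the measure set; the all-pairs option covers the literal "each pair"
  reading.
* Parametric ComBat only (normal/inverse-gamma priors); no longitudinal or
  GAM variants, no reference-batch mode.
* Permutation inference permutes whole rows and therefore assumes exchangeable
  subjects; site structure is handled by harmonizing beforehand, not by
  restricted permutations.
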