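# Methods

## The allele-fraction matrix

The unit of analysis is the SNVM: rows are SNV features identified by
(chromosome, 1-based position, reference allele, variant allele) — the same
position with two different variant alleles is two features, because allele
fractions are allele-specific — and columns are samples. Entry (i, j) is
the allele fraction of SNV i in sample j.

Cell semantics are three-valued and deliberate:

* **AF value** — the variant was called and coverage met the threshold;
* **0** — coverage met the threshold but no variant was called: an
  observed absence, which participates in group comparisons and box-plot
  distributions;
* **NA** — coverage below the threshold (default 10 reads): no
  information, excluded from standardization, univariate tests and allele
  count tables.

Input call files are BED-style (0-based start); positions are converted to
1-based internally and in all reports. Depth can come from a per-record
column or from a separate per-locus per-sample coverage table; when only
the record's own depth is available, record-less cells are treated as
sub-threshold (NA), since their coverage is unknown.

Sub-models restrict features by ANNOVAR-style region class (a request for
`exonic` also matches `nonsynonymous_exonic`, which is a subset) and/or to
known RNA-editing sites, and by a minimum number of samples with nonzero
observed AF (`min_nonzero`, typically 3–6 depending on cohort size).

## Sparse PLS-DA

For two groups, the centered dummy response has rank one, so PLS-DA
reduces to a sequence of rank-one problems: the dense component direction
is w ∝ X_stdᵀ y_c, with y_c the centered indicator of the second group.
Sparsity retains exactly K features by soft-thresholding at the (K+1)-th
largest |w|: survivors are shrunk by that threshold and the vector
renormalised to unit length. Ties at the boundary keep the lower feature
index (stable ordering); a survivor whose shrunk magnitude would be
exactly zero is held at a tiny sign-preserving value so the exact-K
contract holds. One component is the default (a two-class discriminant
needs one direction, and the ranking uses a single loading vector);
additional components deflate X by regression on the score and repeat.

Standardization is per feature over observed entries (mean 0, sd 1,
sample sd with ddof=1); constant features standardize to zeros and can
never be selected.

**Missingness.** Training is NA-tolerant: every inner product is a sum
over observed entries rescaled by (terms in the full sum)/(terms
observed), the NIPALS convention, which reduces exactly to the ordinary
inner product at 0% NA. Prediction requires complete data, so test NAs
are imputed — after standardization with training parameters — by the mean
of the two training-group means of that feature; a group with no observed
training value falls back to the other group's mean. The asymmetry is
intentional: training missingness is information the fit can route
around, test missingness must be filled with the least-committal value.

**Prediction.** The continuous score of a sample is the predicted
centered-dummy difference (group_B minus group_A); positive votes
group_B, exact zeros go to the more prevalent training group. AUC is
always computed on the continuous score, never on hard labels.

## Tuning, evaluation, significance

* **K selection.** Nested CV: fifteen repeats of stratified 10-fold outer
  CV; in each outer-training set, a stratified 10-fold inner CV scores
  every grid K by pooled held-out AUC; the inner-best K (ties → smallest,
  for parsimony) is recorded, giving 150 values. The optimum is the
  rounded argmax of a Gaussian KDE over those values, with Silverman's
  rule-of-thumb bandwidth (0.9·min(sd, IQR/1.34)·n^{-1/5}) on a 512-point
  grid spanning the data range ± 3 bandwidths. The KDE mode is used
  instead of the raw histogram mode because the grid is coarse and the
  selected values noisy.
* **Evaluation.** Fifteen fresh stratified 10-fold CVs at the tuned K.
  Held-out scores are pooled within each repeat before the AUC is taken
  (fold-level AUCs can be undefined when a small fold holds one class);
  accuracy and per-group sensitivities come from the pooled hard labels.
  The 95% CI is mean ± 1.96·sd/√(repeats) over the repeat-level AUCs — the
  simplest estimator consistent with repeat-level variability.
* **Permutation test.** Each of 1000 tests permutes the labels uniformly,
  draws a fresh stratified fold split, runs one 10-fold CV at the tuned K
  and records the pooled AUC; p = #(AUC_perm ≥ AUC_true)/1000, displayed
  as "<1/n" when the count is zero.

A caveat worth knowing: pooled CV AUC under the null has dataset-level
variance well above the binomial floor — training-set feature selection
and the pooling of fold scores with heterogeneous scales inflate it — so
individual null datasets at small n can stray far from 0.5 even though the
estimator is unbiased. The permutation test is immune to this (its null
is built from the same estimator), which is exactly why it, and not the
raw AUC, carries the significance claim.

## Ranking and univariate comparators

The final model is trained on all samples at the tuned K; its selected
SNVs are ranked by |loading| (descending, ties by feature order). Two
univariate tests annotate — but never reorder — the ranking:

* **Fisher 2×4**: per locus, samples with adequate coverage contribute to
  the count of each detectable allele (reference detectable iff AF < 1,
  variant iff AF > 0, so a heterozygous sample counts twice); the exact
  two-sided p conditions on both margins and sums the probabilities of
  all margin-preserving tables no more probable than the observed one,
  using exact integer combinatorics. This test sees only differential
  allele *abundance*.
* **Wilcoxon rank-sum** on the AF values (zeros in, NAs out): sees
  differential *magnitude*. Exact null for tie-free combined n ≤ 25,
  normal approximation with continuity and tie correction otherwise.

The Friedman rank-sum test (features as blocks, ranking methods as
treatments, within-block midranks, standard tie correction, chi-square
with methods−1 df) quantifies whether the multivariate ranking disagrees
systematically with the univariate ones. Note that the statistic is zero
whenever the column rank sums balance — a pure reversal of one method
against identical others is such a case — matching the standard definition
(and `scipy.stats.friedmanchisquare`).

ASE enrichment consumes an external gene/sample table of allele-specific-
expression significance calls: observed = significant/testable pairs over
the genes hosting selected SNVs; the null draws 1000 uniform gene subsets
of the same size from the calling universe; p is the fraction of subsets
at or above the observed fraction and the fold is observed over the null
mean (undefined, and flagged, when the null mean is zero).

## The synthetic generator

The generator emulates what the modeling assumes about real data: two
groups (default 40 samples each), 500 zero-inflated Beta AF features
(background nonzero rate 0.30, Beta(5, 5) — heterozygous-like, centred at
0.5), of which 10 are informative. Effects come in the two modes a
discriminant can exploit: an *abundance* shift (+0.45 to the nonzero
probability in group B) and a *magnitude* shift (nonzero AF means 0.35 vs
0.65 at concentration 10); the default applies both. Depths are drawn so
that a cell is NA iff depth < threshold and the marginal NA rate is
exactly the requested 0.10 (sub-threshold depths uniform below the
threshold, adequate depths threshold + Poisson around a mean of 60).
Observed AFs are quantised to reads/depth. Features are grouped three per
gene; genes hosting informative SNVs are ASE-significant in 60% of
samples against a 10% background, giving the enrichment analysis real
structure to find.

What the generator does **not** emulate: linkage between nearby SNVs,
shared-gene correlation structure, alignment and calling artifacts,
reference bias, batch effects, or any coupling between expression level
and coverage beyond the global depth distribution. Tests passing on this
generator therefore demonstrate correctness of the machinery and
recoverability of planted signal under clean conditions — not performance
on patient cohorts.

## Numerical and design choices

* Inner-CV selection criterion is AUC (the headline metric and the
  permutation statistic); accuracy is available but not default.
* Fold stratification everywhere: small unbalanced cohorts otherwise
  produce single-class training splits.
* The permutation test's observed statistic in calibration settings is a
  single-CV AUC, exchangeable with the permuted draws; a multi-repeat mean
  would not be.
* Degenerate inputs: all-zero Fisher tables, fully-NA Wilcoxon groups and
  single-class AUCs raise; constant features are flagged and zeroed; a
  region subset with no surviving features is reported as skipped, not
  fatal.
* All randomness flows through `numpy.random.default_rng` seeded from one
  integer; the entire select → evaluate → permute → rank → enrich pipeline
  is bit-reproducible given that seed, and the metrics JSON is written
  with sorted keys so reruns are byte-identical.
* Problem sizes in the test suite and the acceptance script (cohorts of
  10–40 per group for recovery and end-to-end checks, 200 per group for
  the null-calibration band where CV sampling noise must fit within
  ±0.1, 100×200 permutation calibration) are chosen so each check
  exercises the property it targets at desk scale.

## Known limitations

Two groups only; SNVs only (no indels or multi-allelic sites); no strand
awareness; MBASED-style ASE calling is consumed, never computed; the
mean-of-means imputation is deliberately simple and can shrink test
scores toward zero when missingness is heavy; heatmap clustering
(average linkage, Euclidean, NA as imputed midpoint for distances only)
is cosmetic and not part of any inference.
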