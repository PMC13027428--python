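# Methods

This note documents the statistical procedures implemented in
`outliersuite`, the defaults they use, the design decisions taken where
several formulations were defensible, and what the synthetic study
conditions do and do not establish.

## Detection battery

All nine detectors run on every dataset and are recorded in the
detection matrix; applicability masks (Dixon outside n = 3–30, Rosner
below n = 25) turn a method into a guaranteed non-flag, never a veto.
Gating of the parametric methods happens at consensus time, not
detection time, so the full detection matrix is always available for
inspection.

* **IQR fences.** Quartiles use linear interpolation (numpy's default,
  "type-7"). The fence multiplier k = 1.5 is the classical Tukey value.
  Vectors shorter than 4 yield no flags with a warning.
* **Z-score.** Two-sided, sample SD (n − 1). A zero-SD feature yields no
  flags.
* **MAD rule.** The raw median absolute deviation is used unscaled by
  default; the Gaussian-consistency constant 1.4826 is available as
  `mad_scale`. When MAD = 0 the rule degenerates and any value different
  from the median is flagged, with a warning — on small qPCR panels a
  half-constant control column should not silently disable the rule.
* **Mahalanobis distance.** Covariance from all samples (ddof = 1);
  flag when D² exceeds the χ²(0.975, p) quantile. A covariance that
  fails a Cholesky factorization is ridged by adding eps·trace/p
  (eps = 1e−8) to the diagonal, and the regularization is recorded.
* **LOF.** Classic local outlier factor (scikit-learn backend),
  Euclidean metric, k = 20 neighbours (clamped to n − 1), cut 1.5.
  Exact duplicates receive LOF 1. k and the cut follow the original
  LOF literature's recommended range; both are configurable and logged.
* **Isolation Forest.** 100 trees, subsample min(256, n), anomaly score
  s(x) = 2^(−E[h(x)]/c(ψ)), cut 0.6 (0.5 is the score of an average
  point). Fully seeded.
* **Grubbs.** Two-sided single-outlier test; the critical value is
  computed from the Student-t quantile at α/(2n) with n − 2 df. Argmax
  ties break to the lowest sample index for determinism.
* **Dixon Q.** Ratio variant chosen by n (r10 for n ≤ 7, r11 for 8–10,
  r21 for 11–13, r22 for n ≥ 14); both extremes are tested and the
  larger ratio compared with the published two-sided critical value.
  The critical table is tabulated at α = 0.05 only (the battery's
  default); other levels raise an explicit error rather than
  interpolating unpublished values.
* **Rosner / generalized ESD.** Up to ⌈0.10·n⌉ candidate removals; the
  flagged set is every removal up to the last i with R_i > λ_i, with
  λ_i from the Student-t distribution.

Univariate and test flags aggregate to the sample level by the
any-feature rule; the open question of whether a method should be
counted per (method, feature) pair is resolved as counting methods,
which keeps the consensus criteria interpretable.

## Normality gate

Shapiro–Wilk and Anderson–Darling are both applied per feature. The
dataset-level gate is the fraction-of-variables rule: the cohort is
"Gaussian" when ≥ `gate_fraction` (default 5%) of features pass both
tests at α = 0.05. Anderson–Darling is a univariate test; applying it
per variable with a dataset-level fraction rule is the formulation this
package adopts, with a Mardia-style multivariate skewness test exposed
separately for diagnostics. Below n = 8 both tests are unreliable and
every feature is marked non-parametric with a warning. The gate decides
whether Z joins the C2 pool and Mahalanobis the C3 pool. A stricter
per-variable gating of Z (only flags on features that individually pass
Shapiro–Wilk) can be recovered from the per-feature report that the
pipeline serializes.

C2's "at least two univariate non-parametric methods" is read as *both*
IQR and MAD when those are the only two members of the pool, and as any
2 of {IQR, MAD, Z} when the gate admits Z — the only reading under which
"at least two" is not vacuous.

## Group comparison

The Mann–Whitney U statistic is reported for the outlier group; the
p-value uses the normal approximation with tie correction and a 0.5
continuity correction (an exhaustive-permutation mode exists for tiny
tie-free groups). Rosenthal's r = |Z|/√N uses the total sample count N.
Benjamini–Hochberg FDR is applied across the feature panel. Effect-size
labels: |r| ≥ 0.5 large, 0.3–0.5 medium, 0.1–0.3 small-to-medium,
< 0.1 small. χ² association is Pearson without Yates correction (the
uncorrected statistic is what the package's reference checks reproduce);
φ = √(χ²/n) for 2×2 tables and Cramér's V otherwise; the Monte-Carlo
p-value resamples tables with both margins fixed (default 10 000
replicates); Fisher's exact test is available for 2×2 tables.

## Robust PCA

Sequential projection pursuit with a grid search over coordinate planes:
each component is the unit direction maximizing the MAD (scaled by
1.4826 so robust eigenvalues are variance-comparable) of the projected,
median-centered data. The candidate direction starts at the best
coordinate axis and is rotated inside the plane it spans with each basis
vector, scanning 10 grid angles whose span halves over 10 refinement
sweeps, with repeated passes at each scale until no improvement. After
each component the space is deflated to the orthogonal complement. All p
directions are pursued so explained fractions are relative to the total
robust dispersion; whether to report robust or classical proportions is
genuinely open, and the robust proportions are reported with a
classical option (`scale_estimator="SD"` reproduces classical PCA up to
the median centering, which the tests verify). Component signs are fixed
by making the largest-magnitude loading positive. With the SD objective
the pursuit recovers the classical subspace to well under 1°; the MAD
objective trades a few degrees of sampling wobble on clean Gaussian data
for bounded influence under gross contamination.

## Networks

Edges require both |r_s| > r_cut (0.5 by default; 0.8 suits very small
marker sets) and p < 0.05, with tie-corrected Spearman coefficients and
t-approximation p-values (exact permutation optional below n = 10). No
multiple-testing correction is applied at the edge level by default — a
BH option exists — because the deltas of interest are descriptive
topology comparisons, not edge-wise inference. Centrality is
degree/(n_nodes − 1); isolated and constant variables stay in the node
set with centrality 0 so group deltas are defined on a common node set.

## Clustering

The Hopkins statistic uses plain nearest-neighbour distance sums (no
d-th powers) with uniform probes drawn in the per-feature min–max box
and m = max(5, ⌈0.1·n⌉) probes; this variant is ~0.5 on spatially random
data by construction, which the tests calibrate over 20 seeds. VAT is
the canonical Prim-style MST traversal started at an endpoint of the
largest dissimilarity, lowest-index tie-breaks. K selection runs seeded
K-means (k-means++, 10 restarts) for k in 2–10 (2–6 is a better range
for very small cohorts) and reports WSS, silhouette,
Calinski–Harabasz and Davies–Bouldin; when the indices diverge the
silhouette-optimal k is the recommended default, and the full table is
always emitted. Hierarchical clustering is complete linkage on Euclidean
distances with the merge tree retained and exported as a Newick string.
By default cluster analysis runs on the standardized matrix of the
outlier subgroup; a whole-cohort mode exists because with very few
outliers (e.g. 5 of 39) either scope is defensible.

## Prediction and stability

The random forest uses 50 trees, depth ≤ 7, min-split 3, min-leaf 1,
√p features per split, Gini criterion, and a seeded stratified 80/20
split (93 samples give the 74/19 split). AUC is computed as the
Mann–Whitney rank statistic with midranks over out-of-sample vote
fractions. Training refuses outright when the minority class has fewer
than 8 samples: with so few positives any supervised learner memorizes
them, so the pipeline skips the stage with an explanatory notice
instead.

Bootstrap stability redraws n samples with replacement, reruns
gate + detectors + consensus, and scores each original sample by
flagged/presence over the iterations in which it appears at least once
(duplicates count once toward presence); the cohort mean averages over
samples with presence ≥ 1. Conditioning on presence is a design choice —
the alternative (dividing by all B iterations) deflates stability by the
~1/e absence rate and conflates sampling with detection.

## Synthetic study conditions

The generator draws log-normal features (Gaussian copula for a
correlated marker block, latent Pearson ρ = 2·sin(π·ρ_s/6) to hit a
target Spearman ρ_s) and plants an outlier subpopulation by adding a
log-scale mean shift δ (in units of the feature's log-SD) with a
variance inflation factor on a marker subset. Presets:

* `clinical_like` — 93 × 11, base log-SD 0.15, a 5-marker correlated
  block at ρ_s = 0.5, 45% planted outliers, each hyper-expressing its
  own random 4-marker subset at δ = 4 with variance inflation 2;
  balanced two-level and three-level design factors.
* `invitro_like` — 39 × 6, 5 planted outliers (12.8%) with one
  hyper-elevated and one suppressed marker at δ = 4.

The defaults balance two requirements that real heavy-tailed expression
data cannot satisfy simultaneously: planted extremes must be recoverable
(sensitivity ≥ 0.9, specificity ≥ 0.8 on average over seeds) while an
unplanted null keeps consensus prevalence below 15%. Tukey fences flag a
substantial fraction of *any* strongly log-normal sample (at log-SD ≈ 1
more than a third of null samples trip the IQR + MAD pair — which is
precisely the regime in which nearly half of a real cohort can be
flagged), so the base skew is kept mild (log-SD 0.15) and the planted
shifts carry the signal. Consequently, passing recovery tests shows the
consensus machinery is correct and well-calibrated under moderate skew
with planted heterogeneous extremes; it does **not** show that a ~47%
prevalence on a real heavy-tailed cohort consists mostly of "true"
outliers — on such data the fences themselves are generous, and that is
a property of the method, not of this implementation. The generator also
does not emulate qPCR technical noise, plate effects, or censoring at
the detection limit.

Simulation sizes used by the checks (10 seeds for recovery and the null
control, 20 seeds for the Hopkins calibration, B = 200 bootstrap
iterations) are chosen so the whole verification runs in well under a
minute while keeping Monte-Carlo error far below the asserted margins;
B = 1000 reproduces the same stability picture and remains the
pipeline-level default for real analyses via `--iterations`.

## Numerical conventions and degenerate inputs

* Sample SD uses the n − 1 denominator everywhere.
* Constant features: standardized to all-zero (warning), marked
  non-parametric, excluded from network edges but kept as isolated
  nodes, MAD fallback as above.
* Ties: argmax ties in Grubbs/Rosner and VAT break to the lowest index;
  AUC uses midranks; rank ties in Mann–Whitney/Spearman use the standard
  tie corrections.
* Determinism: every stochastic step (Isolation Forest, K-means,
  Hopkins probes, Monte-Carlo tables, bootstrap, train/test split)
  takes an explicit seed; reruns are byte-identical.
* I/O: full double precision decimal text; delimiter auto-detected from
  {comma, tab} with an explicit override.

## Limitations

* Dixon critical values are tabulated for α = 0.05 only.
* The Mahalanobis ridge makes D² well-defined for p ≥ n but not
  well-conditioned; for p approaching n a shrinkage covariance would be
  preferable.
* LOF and Isolation Forest cutoffs (1.5, 0.6) are sensible defaults,
  not calibrated p-values; on cohorts where the outlier fraction is
  large the multivariate detectors lose power because the "outliers"
  form their own dense region.
* The consensus is transductive: labels apply to the fitted cohort, and
  `ConsensusOutlierDetector.predict` returns the fitted labels rather
  than scoring unseen samples.
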