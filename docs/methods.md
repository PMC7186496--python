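# Methods

`sahpanel` implements a gene-level inference chain for early prediction of
subarachnoid hemorrhage (SAH): moderated differential expression, Fisher's
exact pathway enrichment, a three-module key-gene screen, and a boosted
heterogeneous ensemble classifier. Because the deposited animal data are
not redistributable, the package ships a synthetic generator that emulates
the two intervention experiments — a 5-vs-5 microarray arm (SAH vs.
sham-operated control) and a five-group RNA-seq arm (LCN2 siRNA vs. vehicle
siRNA at day 1 and day 3, plus untreated control, 5 animals each) — with
planted ground truth, so every stage is testable end to end.

## Synthetic data

**Chip arm.** Rows are probes; a probe→gene annotation table (a few genes
carry two probes, some probes are unmapped) exercises the annotation step.
Per-probe baselines are uniform on log2 [4, 12] — mimicking array intensity
spread without modeling probe chemistry — with i.i.d. Gaussian noise of
scale `sigma` (default 0.25 log2 units) and planted group shifts. Planted
effects come in three tiers chosen to reproduce the screening structure of
the study design: a differential background (default 2,900 genes at
|log2 FC| = 0.6, i.e. mostly passing a 1.5-fold filter but mostly failing a
2-fold filter), 47 strong-effect genes at 2.5, and, inside the 9-gene
cross-arm biomarker panel, a 3-gene strongest subset at 3.5. With n = 5 per
group the standard error of an estimated log2 FC is
`sigma * sqrt(2/5) ≈ 0.16`, so tier membership — not sampling noise —
decides which filters a gene passes; this is a power choice made once, not
a quantity fitted to any test outcome.

**RNA-seq arm.** Counts follow a log-normal/negative-binomial hierarchy:
per-gene baseline log2 mean uniform on [3, 10]; disease effects added in
all four SAH groups; an siRNA-specific response set (default 60 genes)
added only in the active-siRNA groups, producing the small
treatment-vs-vehicle contrasts; per-observation log-normal jitter `sigma`;
gamma-Poisson sampling with dispersion 0.1 (variance `mu + 0.1 mu²`, a
typical bulk-RNA-seq value). The biomarker panel is planted differential
in both arms and both time points; in a pipeline run the chip arm's panel
is passed to the RNA-seq generator so the two arms agree.

**Randomness.** One root seed; every quantity draws from a named substream
(`SeedSequence([seed, crc32(name)])`), so adding a draw never perturbs
existing ones and identical configurations are bit-reproducible.

**What the generator does not emulate:** probe-level chemistry and
normalization artifacts, batch effects, library-preparation biases,
covariates (sex, litter), and correlated co-expression modules (genes are
independent given their group means). Passing recovery tests therefore
demonstrates the correctness of the inference chain under its stated
assumptions, not performance on real tissue data.

## Differential expression

One testing engine serves both dialects: count matrices are transformed to
log2(CPM + 0.5) with per-sample library-size normalization (a deliberate,
documented stand-in for a count-model fit, keeping a single engine), and
log-scale matrices are tested directly.

The statistic is an empirical-Bayes moderated t: gene-wise residual
variances `s²` (df `d`) are shrunk toward a prior `s0²` with prior df `d0`,

    s̃² = (d0·s0² + d·s²) / (d0 + d),    t = Δmean / (s̃·sqrt(1/na+1/nb)),

referred to a t distribution with `d + d0` df. The prior is estimated by
matching moments of `log s²` (digamma/trigamma inversion); non-positive
excess spread yields `d0 = ∞` (a z-test against `s0`). `prior_df=0`
recovers the ordinary pooled t. The implementation is cross-checked against
the reference Bioconductor implementation in the test suite.

Selection uses a linear-scale fold-change threshold (1.5 ⇒ |log2 FC| ≥
log2 1.5) and a p threshold (default 0.05 on raw p; the original text
filters on p-value while its volcano plot shows FDR, so both raw and
BH-adjusted filters are exposed and neither is asserted as the original's
choice). Benjamini–Hochberg adjustment is always reported. RLE QC
(per-gene deviation from the across-sample median, summarized per sample)
and a volcano table (−log10 FDR capped at 320 when the FDR underflows)
round out the stage.

## Pathway enrichment

With `N` measured genes (the universe is *all* measured genes, not the
annotation union), `n` in the pathway, `N_f` differential and `n_f`
differential-in-pathway, the hypergeometric pmf is computed in log space.
Two tails are offered: the standard upper tail (default; exact against
rational arithmetic to 1e−12 for all tables with N ≤ 60) and an
"as-printed" convention — twice the partial lower sum from x = 1 to n_f,
capped at 1 — preserved for fidelity to a published formulation even
though it is not a proper tail probability. The report filter is raw
p < 0.001; a BH column is emitted for reference but not used by the
filter.

## Key-gene screen

1. **Disease-arm screen** (`stage1_select`): strict moderated-t filter
   (FC ≥ 2, p < 0.05), SVM-RFE ranking, t/F tests on the top 100 ranked
   probes, intersection of the two routes, then probe→gene mapping with
   de-duplication. By default the RFE runs on the strict-filter survivors
   rather than the whole matrix: with 10 samples against ~29k standardized
   probes, hundreds of noise probes separate 5-vs-5 by chance and a
   whole-matrix margin ranking is a lottery among near-equivalent
   features; restricting the elimination to the fold-change candidates is
   where the ranking is informative (`rfe_on="all"` restores the literal
   variant).
2. **Intervention-arm screen**: t/F tests of the stage-1 genes in each
   active-siRNA-vs-control contrast (both time points), then the plain
   set intersection across contrasts.
3. **Dimension reduction**: sparse PCA over the intersection genes; the
   union of nonzero-loading genes is the candidate panel; an optional
   user-supplied allow-list (the package's explicit replacement for manual
   literature curation) yields the final panel.

**SVM-RFE.** Features are standardized; each iteration scores surviving
features by `DJ(i) = ½a'Ka − ½a'K(−i)a` with the dual coefficients `a`
frozen from the full fit (the classic approximation; no per-candidate
retraining), removes the `step` lowest (ties broken by feature id), and
repeats until `k_keep` survive. For the linear kernel `DJ(i) = ½w_i²`, an
identity the tests verify numerically; an RBF kernel is available (the
original names no kernel; linear is the default). `step` may be a fraction
for geometric elimination on large matrices.

**t/F routing.** A two-sided F test of variance equality routes each gene
to the pooled or Welch t; a gene is significant when its routed t-test
p < α (a stricter both-tests-significant rule is a flag).

**Sparse PCA.** The elastic-net reformulation in covariance form:
alternating soft-thresholded projections `b_j = soft(S a_j, λ)` with a
Procrustes SVD update of the orthonormal `A`, to a 1e−8 change tolerance
(non-convergence returns the best iterate, flagged). λ = 0 recovers
ordinary PCA loadings (verified to 1e−6); when λ is unspecified a
descending grid picks the smallest penalty whose support holds at most
`max_genes` genes (default 5, mirroring the 9→5 reduction of the study
workflow), i.e. maximal explained variance subject to the support budget.
Components default to 2; the original states neither the component count
nor the penalty.

## Ensemble classifier

Three weak-learner families — logistic regression, a linear
maximum-margin classifier, and Gaussian naive Bayes — are each boosted by
adaptive reweighting: `D_1(i) = 1/n`; per round, fit under `D_t` (all
three families consume per-sample weights natively: the margin and
logistic solvers weight their loss, the naive model weights its
sufficient statistics), record the weighted error `ε_t` and coefficient
`α_t = ½ ln((1−ε_t)/ε_t)`, multiply weights by `exp(±α_t)` and
renormalize. A round with `ε_t ≥ 0.5` is discarded and stops the loop; a
perfect round is kept with `α` capped at `½ ln((1−ε_min)/ε_min)`,
`ε_min = 1/(2n)`. T defaults to 10.

Prediction: internal labels ±1 (0↔−1, 1↔+1), vote margin
`Σ_t α_t h_t(x)` with `sign(0) → +1`. The disease probability of a
boosted model is the α-weighted average of its weak learners' class-1
probabilities (margin learners contribute a logistic squashing of their
decision value); a logistic-of-margin alternative was considered and
rejected as less interpretable. Fusion: the mean of the three
probabilities thresholded at 0.5 (boundary inclusive) by default; the
literal three-term sum is available and is decision-equivalent at three
times the threshold (asserted in tests). The mean is the only reading
under which 0.5 is a meaningful midpoint for a score that otherwise lives
on [0, 3].

Evaluation pools confusion counts over leave-one-out folds for n ≤ 30
(the study had 25 samples) or stratified 5-fold otherwise; ROC sweeps the
threshold over pooled fused scores with trapezoid AUC; the un-boosted base
families are evaluated side by side. Single-class training folds are
skipped with a warning.

**Benchmark.** The ensemble-vs-base comparison uses a dedicated generator
(`simulate_benchmark`): 3 informative + 20 noise genes, n = 200, with an
equicorrelated background (ρ = 0.5, emulating sample-level technical
variation) and an inflated disease-class scale (×1.8 on informative genes,
emulating the greater biological heterogeneity of disease samples). With
spherical Gaussian classes every linear learner is near-optimal and the
comparison degenerates to ties; under this covariance structure the
optimal boundary is curved and the learners genuinely differ. The tested
claim is the qualitative one: median ensemble accuracy over 20 seeds is at
least each base family's median.

## Numerical and degenerate-input choices

- Flat gene (zero variance, zero difference): t = 0, p = 1, not an error.
- Zero-total sample in the CPM transform: error naming the sample.
- Volcano ordinate capped at 320 when the adjusted p underflows to 0.
- Hypergeometric terms in log space (gammaln); outside-support pmf is 0.
- Trigamma inversion by Newton iteration, tolerance 1e−10.
- RFE ties broken by feature id (ascending removed first), making the
  ranking permutation-equivariant.
- All stochastic stages derive their generators from the run seed; a
  re-run with the same configuration reproduces byte-identical artifacts
  (manifest checksums are compared in tests).

## Problem sizes

Defaults mirror the emulated study: 28,944 chip genes × 10 samples;
25,000 RNA-seq genes × 25 samples; replicate counts in tests and the
acceptance script (10–20 end-to-end replicates, 20 benchmark seeds) were
chosen to make stochastic properties stable while keeping a full run in
tens of seconds.

## Known limitations

- The count transform is a pragmatic substitute for a dedicated count
  model; very low counts are handled by the pseudocount, not by a
  dispersion fit.
- The moderated-t prior assumes a single variance population (no robust
  down-weighting of outlier variances, no intensity trend).
- SVM-RFE freezes the dual coefficients per iteration; exact
  leave-one-feature-out retraining would be quadratically more expensive
  and is not implemented.
- The sparse-PCA penalty search is a one-dimensional grid, not a
  cross-validated choice.
- Probabilities from the margin family are a monotone squashing, not
  calibrated probabilities; fusion consumes them as scores.
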