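# Methods

## Signatures

Each of the three signatures is the geometric mean of its regulator
group's expression, computed in log space for numerical stability:
`value_s = exp(mean_g ln(x_gs + ε))`. Expression units are treated as
opaque linear quantities and are never rescaled on load; the geometric
mean is homogeneous of degree one, so any global rescaling passes through
unchanged. When the matrix contains zeros, ε defaults to half the smallest
positive value in the matrix ("auto"), keeping signatures strictly
positive; with an explicit ε = 0 a zero-containing gene is rejected rather
than silently producing a zero signature. A `log_transform` switch applies
log2(x+1) before averaging for users who prefer log-scale summaries; the
default is the raw-scale geometric mean.

Pairwise signature correlations are Pearson (product-moment) or Spearman
(Pearson on average ranks) with two-sided t-approximation P values. A
zero-variance input yields a flagged degenerate report instead of NaN. No
multiplicity correction is applied within the 3×3 signature grid.

## Stratification taxonomy

Median dichotomization labels a sample high iff its value is strictly
above the per-cohort median; ties at the median go to low, which makes the
split deterministic and reproducible. Cohorts are always stratified with
their own medians — cutoffs are never transferred or pooled between
cohorts. The seven schemes (W, R, E, WE, RE, WR, WRE) partition the cohort
by construction; the WRE scheme collapses the W/R pair to the count of
highs (dL/sH/dH) crossed with the E level, giving six groups. The
low-m6A-indication set is {W^L, R^L, E^H, W^L E^H, R^L E^H, W^L R^L,
WR^dL E^H}; the high set is its mirror image; every other composite label
is intermediate. Note the eraser orientation: *high* eraser expression
indicates *low* m6A.

As an alternative to the median, `best_cutoff_scan` scans every candidate
threshold that leaves both groups at least 10% of the cohort (configurable)
and selects the one minimizing the two-group log-rank P. The full
threshold/P curve is exported so users can apply a different selection
rule, and the number of candidates is reported to support a
Bonferroni-style correction of the minimum P — under the null this
corrected P stays above 0.05 in essentially all simulated cohorts.

## Survival analysis

Kaplan–Meier curves use the product-limit estimator (via lifelines); the
reported median is inf{t : S(t) ≤ 0.5} and is +∞ when the curve never
reaches 0.5. The k-group log-rank test is computed directly from the
aggregated event-time tables so per-group observed and expected event
counts can be reported: deaths tied at a time are processed together,
subjects censored at t count as at risk at t, and the statistic is
z'V⁻z over the first k−1 groups with the usual hypergeometric covariance,
referred to χ²(k−1). The implementation is cross-checked against
lifelines' multivariate log-rank test in the test suite. Groups smaller
than 5 trigger a warning, not an error.

## Mutation and clinical associations

Gene screening keeps genes whose mutated-sample fraction is strictly above
the threshold (default 1%) in *both* cohorts. Fold changes between the
low- and high-indication groups of each scheme use Haldane–Anscombe
smoothing, FC = ((m_low+α)/(n_low+2α)) / ((m_high+α)/(n_high+2α)) with
α = 0.5, so genes unmutated in one group stay finite; intermediate-
indication samples are excluded. Cross-cohort calls are UP iff FC > 1 in
both cohorts and DN iff FC < 1 in both; the consensus call requires a
configurable fraction of schemes (default 4/7) to agree.

Contingency tests: 2×2 tables use the two-sided Fisher exact test in the
sum-of-small-point-probabilities convention (this is the convention that
reproduces the published gastric-cancer clinical tables to four decimals);
larger tables use Pearson chi-square without continuity correction, with
a flag when any expected count is below 5 and an optional margin-fixed
Monte-Carlo exact test for such sparse tables. Missing ("n/a") values are
excluded per variable, not per sample, and age is dichotomized at 60
years. The Lauren association between the extreme WRE corners is worth a
note: on the published counts, the diffuse-vs-intestinal 2×2 Fisher exact
test gives P = 0.0006 while the full 3×2 chi-square gives 0.0018; both
routes are available via the per-variable test override. Continuous
markers (TMB) are compared with the two-sided Welch t-test.

## Enrichment engine

Differential expression is a per-gene Welch t-test (high vs low group)
with a configurable DEG threshold (default P < 0.05); genes constant in
both groups are flagged degenerate rather than crashing. The GSEA engine
ranks genes by signal-to-noise ratio, (μ_hi − μ_lo)/(σ_hi + σ_lo), with
each σ floored at 0.2·|μ| (absolute floor 0.2 when μ = 0) to avoid
division blow-ups; ties are broken lexicographically by gene symbol so the
ranking is deterministic. The enrichment score is the weighted
Kolmogorov–Smirnov running sum (hit increments ∝ |score|^p with p = 1 by
default, uniform miss decrements); ES is the running-sum value of largest
magnitude. The null is phenotype-label permutation with a seeded
generator: NES divides ES by the mean magnitude of same-sign permuted ES
of the same set, nominal P is the (add-one) fraction of same-sign
permuted ES at least as extreme, and FDR q pools signed NES across all
sets and permutations. With p = 0 the ES is invariant under strictly
monotone score transforms, which the tests exercise.

## Synthetic cohort design

The generator draws one latent standard-normal m6A level per sample and
derives every layer from it:

- **Expression.** Regulator log-expression is l·f (writers/readers) or
  −|l|·f (erasers) plus a block-shared and an independent Gaussian term;
  values are log-normal around configurable linear-scale medians (default
  100, σ = 0.5). Defaults: within-block correlation 0.6, W–R correlation
  0.4, W/R–E correlation −0.4. The single-factor construction guarantees
  the observed sign pattern (writers/readers positively intercorrelated,
  both negative against erasers) and positive definiteness is checked
  constructively, with an error naming the offending parameters.
- **Survival.** Exponential event times with baseline scale 30 months;
  the lowest latent tertile's hazard is multiplied by `hr_low_vs_high`
  (default 2.5). Censoring is independent and uniform over a window
  solved numerically so the marginal censored fraction matches
  `censor_rate` (default 0.3) at the mean hazard.
- **Mutations.** Seven driver genes (CDH1, AR, GLI3, SETBP1, RHOA, MUC6,
  TP53) with baseline mutation probabilities 0.10–0.30 and a default odds
  multiplier of 3 in low-latent samples; 60% of CDH1 mutations in
  low-latent samples carry the p.D254Y protein change. Thirty passenger
  genes mutate independently at 5%.
- **Clinical.** Diffuse Lauren histology, advanced T/N/M/stage and MSI-H
  probability shift along the (negated) latent level through logistic /
  softmax links; TMB is log-normal with a positive latent coefficient
  (TMB and MSI-H track *high* m6A, mirroring the eraser-low association);
  EBV is an independent Bernoulli label. Age and gender are independent.
- **Background genes.** Forty "ONCOG" genes load negatively on the latent
  factor (so the high-m6A contrast is negatively enriched for them,
  collected in the ONCOGENIC_SPIKE gene set); the remaining background
  genes are independent noise.

All randomness flows from one root seed through named substreams
(expression, survival, mutations, clinical, gene sets), so regeneration
is byte-identical. The generator emulates the statistical *structure* of
real proteomic/transcriptomic tumor cohorts, not their marginal
distributions: real protein intensities are heavier-tailed, missingness
is not simulated, and mutation co-occurrence beyond the shared latent
factor is absent. Passing recovery tests therefore demonstrate that the
pipeline detects the designed effects at the designed sizes, not that it
would find identical effect sizes in real cohorts.

`recovery_report` runs the pipeline on a generated cohort (plus an
independent replicate for the cross-cohort check) and verifies: (a) the
WR^dH E^L corner outlives WR^dL E^H by KM median, (b) all spiked drivers
receive consensus UP calls across two replicates, (c) the extreme-corner
log-rank P < 0.05, and (d) the spiked set's NES is negative in the
high-m6A contrast. Cohorts below 100 samples are flagged underpowered. At
the default design these checks jointly pass in ≈94% of seeds.

## Problem sizes and numerical choices

Simulation-backed tests use 12–100 replicates at cohort sizes 80–600 and
100–1000 permutations, chosen to bound Monte-Carlo error well below the
asserted margins while keeping the default suite quick. Exact oracles
(enumeration, hand computation, brute-force recomputation) are asserted at
1e-9 to 1e-12; stochastic checks assert pass fractions with slack for
binomial noise. Degenerate inputs (all-identical values, zero variance,
empty groups, zero margins, all-censored data) raise typed errors or
flagged results as documented per function, never NaNs.

## Known limitations

- The best-cutoff scan optimizes the log-rank P directly; it is not a
  time-dependent ROC analysis, and the selected cutoff inherits the
  optimism of any minimum-P search (hence the exported scan curve and
  Bonferroni count).
- Cox modeling, competing risks and interval censoring are out of scope.
- The FDR q of the enrichment engine uses the classic signed-pool
  estimator, which can exceed nominal accuracy for very small collections
  of sets.
- Multiple-testing correction across gene-level mutation screens is
  deliberately not applied.
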