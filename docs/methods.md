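# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical conventions, and the design choices behind `methpair`.

## 1. The quantity being estimated

For each CpG the target is the correlation between two measurements of the
same individual under one of three paired designs: *longitudinal* (two
blood draws roughly ten years apart), *tissue* (whole blood vs buccal
swabs collected at the same visit), and *platform* (the same blood DNA
assayed on 450K and EPIC arrays).  A high pairing correlation means the
CpG ranks individuals consistently across the two measurements — the
relevant notion of stability/reliability for epidemiological use; it does
not require the level itself to be unchanged (a uniform shift with age,
for example, leaves the correlation at 1).

## 2. Estimation model

Individuals come from twin families, so pairs are not independent across
individuals.  The package estimates the per-CpG correlation as the slope
of a Gaussian identity-link GEE of the z-scored second measurement on the
z-scored first, with an exchangeable working correlation over families:

- Working covariance per family *i* of size nᵢ: `Vᵢ = φ[(1−α)I + αJ]`.
- Moment updates (Liang–Zeger): `φ = Σe²/(N−p)` and
  `α = Σᵢ Σ_{j<k} eᵢⱼeᵢₖ / (φ·[Σᵢ nᵢ(nᵢ−1)/2 − p])`, iterated with the
  weighted least-squares solve until the max coefficient change is below
  `tol` (default 1e−6) or `max_iter` (default 100) is reached.
- Sandwich (robust) covariance `B⁻¹MB⁻¹` for inference; the naive
  model-based SE is also reported.  P-values are two-sided normal Wald
  statistics on the robust SE — robust because the family clustering is
  the reason for using GEE at all; the naive-SE p-value is emitted
  alongside for comparison.
- Clusters of size 1 contribute to the coefficients and the sandwich but
  have no within-cluster pairs, hence do not enter α's numerator.  With
  all clusters singletons the fit reduces exactly to OLS, and on z-scored
  inputs the slope equals Pearson's r (verified to 1e−8 in the tests).

Numerical details worth knowing:

- α is clamped to the positive-definiteness range
  `(−1/(max nᵢ − 1), 1)` with a 1e−3 safety margin; clamping exactly at
  the boundary makes `1+(nᵢ−1)α = 0` and the closed-form inverse
  singular.  A clamp sets a warning flag on the fit.
- When the pair-count correction makes α's denominator non-positive
  (possible only on degenerate toy data, e.g. two pairs and two model
  parameters), the denominator is floored at 1.
- Per-cluster sums are accumulated with segment operations, so one fit
  costs O(N) per iteration regardless of the number of families; the full
  per-CpG loop over a 2,000-probe panel at 200 pairs takes ~1.5 s on one
  core.

Per probe, individuals with either measurement missing are dropped, the
remaining pairs are re-standardized (so the slope≡correlation identity
survives missingness pruning), and probes with fewer than `min_pairs`
(default 10) analyzed individuals are emitted with missing estimates.
Pearson's r and the one-way random-effects ICC(1,1)
`(MS_between − MS_within)/(MS_between + MS_within)` are computed on the
same re-standardized pairs as comparators.

Classification: *significant* ⇔ robust-Wald p < α/n_tests (Bonferroni,
α = 0.05, n_tests = CpGs tested); *strong* ⇔ estimate > 0.50, strictly.
Boundary values (estimate exactly 0.50) are not called strong.

## 3. Probe QC conventions

Filters run in a fixed order so stage tallies are disjoint and
unambiguous: (1) per-entry value masking — zero intensity, detection
p > 0.01, or bead count < 3, all read strictly so boundary values pass;
(2) probes with success rate < 0.95 across samples removed (exactly 0.95
kept); (3) mask-list removal; (4) X/Y removal.  A probe that is both
masked and on a sex chromosome is counted once, under the mask stage.
The chain is idempotent, and the report identity
`n_out = n_in − Σ dropped` is checked on every run.

Sample-level QC (array-control metrics, sex prediction, relationship
verification) is out of scope; a sample exclusion list can be applied
upstream by subsetting the sample sheet.

## 4. Preprocessing

Technical residualization regresses each probe on dummy-coded sample
plate and array row by OLS and keeps the residuals; probes with fewer
observed samples than model parameters are flagged and set all-missing.
Residualization is applied within each measurement set separately (all
first-measurement samples together, all second-measurement samples
together) because plate/row layouts differ between assay batches — the
grouping is a package choice; pooling both members into one design matrix
would also be defensible.  Cell-composition covariates are deliberately
not adjusted: differences in cellular composition are one of the
biological sources of (dis)similarity the correlation is meant to
capture.  Z-scoring uses the n−1 denominator (the slope≡correlation
identity is invariant to a common scaling either way).

PCA diagnostics compute sample-space PCs of the probe-centered,
per-probe-mean-imputed matrix and report, per PC, a signed Pearson
correlation for numeric covariates and the multiple correlation
coefficient (√R² over the covariate's dummies) for categorical ones,
plus explained-variance fractions.  On synthetic data with a plate shift,
plate–PC correlations drop after residualization, mirroring the standard
batch-effect check.

## 5. Synthetic twin-family generator

No public data accompanies the analysis, so the generator is a
first-class component.  Per probe *j* and individual *i*, on the z scale:

    T_ij = √f·F_{fam(i),j} + √(1−f)·I_ij          (latent trait)
    y_k  = √ρ_j·T_ij + √(1−ρ_j)·e_k,   k = 1, 2   (paired measurements)

with F, I, e standard normal.  This single-factor construction makes
corr(y₁, y₂) = ρ_j exact by construction and the within-family trait
correlation equal to f, tunable independently.  MZ and DZ twins share the
same family factor — consistent with the exchangeable working
correlation, which treats all within-family pairs alike; zygosity is
recorded in the sample sheet but not used generatively.

Each y is mapped to a beta value via `sigmoid(μ_j + s_j·y)`, where
(μ_j, s_j) come from a three-component logit-normal mixture emulating the
characteristic bimodal beta-value density: hypomethylated (weight 0.40,
μ = −2.8 ± 0.55, s ≈ 0.45), intermediate (0.15, μ = 0 ± 0.9, s ≈ 0.60)
and hypermethylated (0.45, μ = +2.8 ± 0.55, s ≈ 0.45).  Plate and row
shifts (Gaussian level effects, sd 0.2 and 0.1 logit units) are added on
the logit scale before the sigmoid; output is clipped to [0, 1], so
extreme logits can produce exact boundary values, which downstream code
must tolerate (and the QC/standardization paths do).

Default study conditions: 197 longitudinal, 58 tissue and 83 platform
pairs drawn from families of two parents plus an MZ twin pair; the
per-probe true correlation law is a mixture of a point mass at 0
(weight 0.35, unstable CpGs), a uniform component on [0, 1] (0.55) and a
point mass at 0.9 (0.10, highly reliable CpGs), giving a right-skewed
distribution with most mass at low-to-moderate correlations.  QC-failure
rates default to 0.2% (detection), 0.2% (bead count) and 0.1% (zero
intensity) per entry.  `n_probes` defaults to a 20,000-CpG panel:
per-probe estimates do not depend on panel width, and tests/validation
use 1,000–5,000-probe panels for speed.  Pair-interval heterogeneity
(the spread of years between longitudinal draws) is not modeled; ages are
metadata only.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: raw-intensity artifacts and normalization
(inputs are assumed already normalized and comparable across samples),
cell-composition differences between tissues, age trends in methylation,
genotype-driven effects (mQTL tables are simulated separately), and
probe-probe correlation (all probes are generated independently given the
sample layout).

## 6. Parameter identification and validation experiments

The generator defines ρ on the z/logit scale.  Mapping through the
bounded sigmoid attenuates beta-scale product-moment correlations
slightly (≈ −0.01 to −0.02 at moderate ρ with the default mixture) — a
property of the bounded scale, analogous to regression dilution, not an
estimator defect.  The validation experiments in
`methpair.experiments` therefore analyze logit-transformed values, where
ρ is the true correlation; the pipeline itself analyzes beta values, as
array workflows do.  Measured on the logit scale at 200 individuals and
2,000 probes, mean estimator bias is ≈ −0.002 at ρ ∈ {0.2, 0.5, 0.8}.

Null calibration: with ρ = 0 in 50 families of 4, the robust-Wald test
rejects at ≈ 0.067–0.072 for nominal 0.05.  This mild anticonservatism
is the well-known small-sample behavior of the plain (uncorrected)
sandwich with ~50 clusters; statsmodels' GEE reproduces the identical
rejection rate on the same data.  No small-sample correction (e.g.
Mancl–DeRouen) is applied, matching the estimator the analysis chain
specifies; the calibration test pools three replicates (15,000 probes) to
report the rate with Monte-Carlo error ≈ 0.002.

GEE–Pearson concordance: on beta-scale twin-family data (200 pairs,
2,000 probes, heterogeneous ρ), the across-probe correlation between GEE
estimates and Pearson's r exceeds 0.999 — the two agree except where
family weighting matters, which is the qualitative pattern expected when
most information is between-family.

## 7. Set arithmetic and rounding conventions

Top-variability strata take the `round_half_up(fraction·M)` probes with
the largest per-probe sample sd (n−1), ties broken by probe id so the
selection is invariant to row order.  Half-up rounding (never bankers')
is used for all reported percentages (one decimal) and per-associated-CpG
means; it is the only rule consistent with reproducing a 75,926-probe
decile from 759,263 probes *and* a 38,681-probe decile from 386,805.
Overlap summaries default the denominator to min(|a|, |b|) when comparing
two same-fraction strata but the denominator is configurable and recorded
in the output, since different comparisons legitimately use different
baselines.

Trait enrichment uses the 2×2 table (a, q−a, k−a, N−q−k+a) for a query
of size q against a catalog of k hits in a universe of N: one-sided
hypergeometric tail `P[X ≥ a]` for p, odds ratio `ad/bc` with a Woolf
95% CI on the log-OR, and the Haldane–Anscombe 0.5 correction when any
cell is zero (the p-value always uses the uncorrected table).  The OR
path is verified against exact rational enumeration of the
hypergeometric pmf for every consistent table with N ≤ 20 plus sampled
tables up to N ≤ 60.

mQTL prevalence summaries count a CpG as cis-associated when it has ≥ 1
cis association and trans-associated when ≥ 1 trans (a CpG can be both);
probes absent from the annotation table count as unassociated.  The
synthetic mQTL generator raises association probability linearly with a
per-probe reliability score, emulating the empirical pattern that
reliably measured CpGs carry more detectable genetic signal.

## 8. Known limitations

- The exchangeable working correlation ignores zygosity differences
  (MZ vs DZ); a kinship-structured working correlation might be more
  efficient but would not change consistency, and the robust variance is
  valid regardless.
- Exact slope symmetry under swapping the two measurements is an OLS
  property; under cluster weighting the two regression directions differ
  at O(10⁻²) in small samples.  The reported estimate fixes measurement
  A as the predictor (timepoint 1, blood, 450K).
- The plain sandwich slightly over-rejects with few clusters (§6); at
  Bonferroni thresholds the effect is stronger in the extreme tail, so
  family-clustered discovery counts at small cluster numbers should be
  read with that in mind.
- Percentages are reported at one decimal; the underlying counts are
  always available in the outputs, and invariants are re-checked from
  counts, never from rounded values.
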