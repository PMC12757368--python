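# Methods

This document records the statistical model behind each module, the
parameter choices, how the synthetic data generator earns its realism, the
numerical decisions, and the known limitations.

## 1. Consensus differential screening (`diff_consensus`)

**Imputation.** Array matrices may contain missing beta values. A probe
with any observed value is imputed by k-nearest-neighbour regression over
probes: the distance between two probes is the root-mean-square difference
over the samples both observe, donors are the `k = 10` nearest probes with
complete rows, and the imputed value is their mean in the target sample.
Probes missing everywhere are dropped with a warning. This is the standard
probe-wise kNN scheme used for methylation arrays; it is hand-rolled
because the pipeline needs a deterministic, dependency-light variant with
an explicit complete-donor contract.

**Moderated t.** For each feature, group means and a pooled variance `s²`
(df `d = n₁ + n₀ − 2`) are combined with an inverse-chi-square variance
prior: posterior variance `s̃² = (d₀·s₀² + d·s²)/(d₀ + d)`, statistic
`t = Δ/√(s̃²(1/n₁ + 1/n₀))`, two-sided p from a t distribution with
`d + d₀` df. The prior `(d₀, s₀²)` is estimated by method of moments from
the spread of the pooled variances: with `cv²` the squared coefficient of
variation of `s²`, `d₀ = (2d − 4 + 4·cv²·d)/(cv²·d − 2)` (clamped to be
positive, infinite when variances are essentially homogeneous) and
`s₀² = mean(s²)(d₀ − 2)/d₀`. Setting `prior_df = 0` recovers the classical
pooled t exactly — the unit tests pin this against `scipy.stats.ttest_ind`.
Features constant across all samples get `t = 0`, `p = 1` and a flag.

**Selection rules.** DEGs: `p < 0.05`, at most the top 1000 per direction
by p (ties broken by |t|, then id). DMPs: `|Δmean| ≥ 0.1`,
`sd_control < 0.2`, `sd_case < 0.3`, top 1000 per direction by |Δ|. The
`0.1` is a *minimum* absolute difference: a maximum-difference reading
would select the noise floor and contradict the ranking by largest |Δ|.

**Consensus.** A feature is selected when at least `min_datasets = 3`
datasets select it *in the same direction*; features selected in opposite
directions anywhere are recorded as conflicting and never selected.

## 2. WGBS differential methylation (`wgbs_dmr`)

**Smoothing.** The smoothed methylation at a CpG is the coverage-weighted
mean of raw fractions over same-chromosome CpGs within ±250 bp (window
500 bp), i.e. the pooled ratio `Σ n_meth / Σ n_total` over the window,
computed with cumulative sums in O(n).

**Beta-binomial Wald test.** Per site (restricted to sites covered in at
least one sample of each group):

- Group methylation `π_g` = coverage-weighted mean of the *smoothed*
  per-sample fractions; `Δ = π_case − π_control`.
- Per-site dispersion `φ̂` by method of moments from the *raw* per-sample
  fractions around each group's raw pooled ratio, using
  `E[(x/n − π)²] = π(1−π)(1/n + φ(n−1)/n)`; both groups' estimates are
  pooled, clipped to `[0, 0.99]`. Raw (not smoothed) residuals are used so
  that a regional methylation gradient does not inflate the dispersion.
- Shrinkage toward the chromosome-wide median:
  `φ = (m·φ_med + n·φ̂)/(m + n)` with prior weight `m = 20` samples.
- Effective coverage per sample `n/(1 + (n−1)φ)` (the beta-binomial
  variance inflation); group weight `w_g` is its sum. The standard error
  uses the *pooled* proportion: `se = √(π̄(1−π̄)(1/w_case + 1/w_ctrl))`,
  so with one sample per group, high depth and `φ = 0` the statistic is
  exactly the classical pooled two-proportion z — the acceptance suite
  pins this equivalence at depth 10⁴.
- `wald = Δ/se`, two-sided normal p.

Using smoothed means with raw-count-based standard errors makes the test
slightly conservative under the null (observed false-positive rate ≈ 0.002
at α = 0.01), which is the desired direction for a discovery screen.

**DMP/DMR calling.** DMPs: `p < 0.01` and `|Δ| > 0.2`. DMRs: per
chromosome, consecutive DMPs stay in one candidate run while the gap is
≤ 1 kb and the sign of Δ matches; runs need more than five DMPs and a
Stouffer-combined region p (`z̄√k` on the per-DMP one-sided z-scores)
below 0.05. Region bounds are the first/last member positions (1-based
inclusive; BED export converts to 0-based half-open).

**Augmentation.** Each parent sample is replayed 7 (controls) or 20
(cases) times; each replicate thins the methylated and unmethylated counts
independently per site with `Binomial(count, 0.5)`. This preserves the
per-site methylation fraction in expectation while giving replicates
independent binomial noise, mimicking resampling reads from the same
library. 3 + 3 parents yield the canonical 21 + 60 sub-samples;
`thin_fraction = 1` reproduces parents exactly.

## 3. Feature integration (`feature_integration`)

Gene loci are the padded (±2 kb) span of a gene's annotated probes.
Model regions are the DMRs overlapping loci of genes in the DEG ∩ DMG
intersection (interval intersection via an interval tree, checked against
a quadratic oracle in the tests). Region features: WGBS = pooled ratio
`Σ n_meth / Σ n_total` over CpGs inside the region (group-mean imputation
for uncovered samples); array = unweighted mean beta of probes inside the
region. Regions no probe covers cannot be projected and are dropped from
*both* platforms so the feature spaces stay aligned. Because the simulator
places probes exactly on CpG positions, the two representations of the
same region agree closely (tested to < 0.05).

## 4. Classifier and statistics (`classifier`)

**Split.** Stratified: per class, `round(0.6666·n)` (round-half-up)
samples train; 21/60 → 14 + 40 train, 7 + 20 validation.

**Network.** Three hidden layers (16, 8, 4) with logistic activations and
a sigmoid output, trained by full-batch gradient descent on mean binary
cross-entropy plus an L2 penalty (`λ = 1e-4`, learning rate 0.5, 2000
epochs, deterministic Gaussian initialization). Features are standardized
with *training* means/SDs, frozen into the model and applied to any scored
matrix after re-aligning columns by region id. The hand-rolled
implementation keeps the model fully inspectable and dependency-free; the
tests verify monotone loss, perfect separation of separable data, and
column-permutation invariance.

**Statistics.** ROC AUC via mid-rank Mann-Whitney U (ties count ½;
checked against scikit-learn). Mann-Whitney: for combined n ≤ 12 the
p-value is exact by enumerating all assignments of the pooled mid-ranks,
`p = P(|U − μ| ≥ |U_obs − μ|)` — identical samples give p = 1 and complete
3v3 separation gives p = 0.1; larger samples use the normal approximation
with tie and continuity corrections (checked against scipy). Spearman is
Pearson on mid-ranks with the t approximation. Benjamini-Hochberg step-up
(checked against statsmodels) and a two-sided Fisher exact test
(hypergeometric tail summation, checked against scipy) complete the
toolbox.

## 5. Immune profiling (`immune_profiling`)

**Deconvolution.** NNLS of each bulk profile on the signature matrix over
shared markers (rank-checked), coefficients normalized to the simplex.
Noiseless mixtures are recovered to machine precision; RMSE ≈ 0.005 at
noise SD 0.02.

**ssGSEA.** Per sample, genes are ranked by expression; the score is the
integrated difference between the weighted in-set ECDF (weights
`rank^0.25`, normalized) and the uniform out-of-set ECDF. The
implementation uses the closed form
`ES = Σ_{g∈S} w_g(N − mpos_g + 1) − mean_{g∉S}(N − mpos_g + 1)` with
mid-rank positions, which equals the running-sum definition exactly in
expectation over tie orderings; constant expression scores exactly 0. The
tests include a brute-force running-sum oracle on tie-free data.

**ORA / GSEA.** Over-representation via the hypergeometric upper tail
(`sf(k−1)`) with BH adjustment and an odds-ratio effect size; pre-ranked
GSEA uses the weighted Kolmogorov-Smirnov running sum with gene-set
permutation p-values (+1 guard).

## 6. Synthetic data (`synthetic_data`)

**Array cohorts.** Beta values are drawn from a Beta distribution
reparameterized by (mean, precision = 30) — the canonical model for
methylation fractions, giving the characteristic U-shaped marginal and
heteroscedastic noise (variance largest at intermediate methylation).
Baselines come from Beta(2, 2) restricted by rejection sampling to means
where the planted shift ±Δ stays inside [0.02, 0.98], so planted effects
are never silently truncated. Cases shift planted probes by ±0.3
(hypo-dominant: 25 hypo / 15 hyper by default, matching the
hypomethylation excess seen in lupus cfDNA).

**WGBS cohorts.** Per-sample, per-site methylation probabilities follow
the same Beta model (precision 100); read depth is Poisson(30) clamped to
≥ 1; counts are Binomial(depth, p), giving genuine beta-binomial
overdispersion. Planted DMRs are 8-CpG blocks isolated by ≥ 400 bp margins
so 500 bp smoothing never mixes block and background.

**Activity and expression.** Each sample's disease-activity score is
`2 + 30·(mean planted-probe deviation) + N(0, 1)` clipped at 0, coupling
activity to the methylation signal strength as disease activity couples to
cfDNA pathology. Expression shifts planted genes opposite to their
methylation (hypomethylated → up-regulated), with effect `4×` the
methylation effect on the log scale.

**Multi-omics study.** One shared layout: 60 genes on 2 chromosomes, 8
CpGs per gene (~30–70 bp apart), 3 probes per gene placed *on* CpG
positions; 10 hypo + 6 hyper planted genes are concordant across all
platforms (arrays, transcriptomes, WGBS DMR blocks, activity). This makes
cross-platform recovery a meaningful test rather than a coincidence of
independent generators.

## 7. Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are drawn below 2³¹.
- Smoothing and interval work use cumulative sums / interval trees
  (O(n log n)), not per-site loops.
- The logistic is computed as `0.5(1 + tanh(z/2))` for stability; training
  raises (with the epoch) if the loss turns non-finite.
- Sorts use mergesort wherever order ties into results, making every
  output independent of input permutation (tested for sample order,
  dataset order and feature order).
- p-values are clipped to [0, 1]; `−log10(p)` in BED export is capped at
  300.

## 8. Limitations

- The simulator plants block-shaped DMRs with clean margins; real cfDNA
  methylation has fragment-length effects, cell-type mixture drift and
  batch structure that are not modeled. Recovery rates here are upper
  bounds.
- The beta-binomial Wald test pairs smoothed means with raw-count standard
  errors; this is deliberately conservative and will lose power relative
  to a full likelihood treatment at small Δ.
- With only 3 + 3 WGBS parents, augmented sub-samples are not independent;
  validation AUC on sub-samples is optimistic relative to new patients,
  which is why the pipeline also validates on an independent array cohort
  and reports the activity correlation there.
- The moderated-t prior assumes a common variance prior across features;
  strong variance heterogeneity (e.g. mixed probe types) would violate it.
- The network is small and full-batch; it is adequate for ≤ a few hundred
  features, not for genome-wide input.
- ssGSEA normalization divides by the global score range, so scores are
  comparable within one matrix but not across matrices.
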