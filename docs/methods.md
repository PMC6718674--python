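# Methods

## The within-pair model and its inference

The unit of analysis is the twin pair. For feature *g* and pair *j* the
response is `r_gj = log2((v_dep + c) / (v_ctrl + c))` with offset `c = 1e-6`
for methylation betas (zero is representable) and `c = 1` for TPM (matching
the `log2(TPM+1)` scale of the expression filter). The model is a linear
mixed model with fixed covariates and a random intercept per array batch;
pairs are the observations, and batch is a pair-level factor because both
twins of a pair are hybridized on one chip.

Covariate coding. Twin-varying covariates (BMI, smoking, alcohol, income,
education, and the sensitivity set ACE/PTSD/antidepressant use) enter as
raw within-pair differences: their zero means "co-twins equally exposed",
so α keeps the interpretation of the mean fold change at equal exposure,
and an effect that is actually carried by an exposure difference is
absorbed by its covariate when that covariate is added (this is what makes
sensitivity reruns informative). Pair-shared covariates (age, sex) have no
meaningful zero and are mean-centered.

Estimation. The random-intercept fit is REML, profiling the variance ratio
λ = σ_b²/σ². With one grouping factor, each batch block of
V = I + λZZᵀ inverts in closed form (Sherman–Morrison per block), so the
profiled criterion needs only per-batch sums; λ is found by bounded scalar
minimization and compared against the λ = 0 boundary. With fewer than 3
batches, or when the REML estimate is zero, the fit is ordinary least
squares (logged, and flagged `ols` in the results).

Testing. Wald *t* per coefficient. The default degrees of freedom are a
Satterthwaite approximation computed from the expected REML information
matrix of (σ², σ_b²) — the lmerTest approach. The simpler residual
convention df = n_pairs − n_fixed is available (`df_method="residual"`)
but is measurably anti-conservative at realistic batch counts: plugging an
estimated variance ratio into a residual-df *t* test ignores the
uncertainty of σ̂_b², and at 79 pairs / 20 batches / σ_b = 0.1 the null
rejection rate at nominal 0.05 is ≈ 0.062 versus ≈ 0.048 for
Satterthwaite. Multiple testing is Benjamini–Hochberg step-up with an
optional external test count m (used when a stated family, e.g. the
candidate-region total, exceeds the rows supplied).

## Region calling

Candidates are maximal runs of retained same-chromosome probes with
inter-probe gaps ≤ 1000 bp (the bandwidth scale of kernel-based DMR
callers); singletons are dropped. "Correlation among probes" is the mean
of all pairwise Pearson correlations of beta values across samples
(`corr_method="min"` selects the strictest pairwise reading instead — the
definition is not canonical in the field). Region p combines probe-level
evidence by signed Stouffer: z_g = sign(α_g)·Φ⁻¹(1 − p_g/2), Z = Σz/√k.
Stouffer respects effect direction and probe count but assumes independent
probes; within correlated regions it is anti-conservative, which is
acceptable for ranking and is corrected for multiplicity at the candidate
level (BH with m = number of scored candidates). The DMR criteria
(≥ 5 probes, peak p < 0.01 strict, correlation ≥ 0.30, q < 0.05) are
re-asserted on every reported region. Peak-probe ties break by larger |α|,
then by genomic position. Percent differences are means over pairs of
(β_dep − β_ctrl), ×100, averaged over probes (region mean) or taken at the
peak probe.

## Cis integration

Probe–gene pairs require |probe − TSS| ≤ 5 kb, strand-aware (negative
offset = upstream in the gene's reading direction). The statistic is the
partial Pearson correlation of probe beta and log2(TPM+1) given the seven
standard covariates (residualize both on [1, C] via QR, correlate
residuals). Significance thresholds come from a permutation null:
expression sample labels are shuffled B times (shuffling one matrix
suffices under exchangeability and keeps covariates attached to the
methylation samples), all cis-pair partial correlations are pooled, and
the α/2 and 1−α/2 quantiles give (lower, upper). A `tail="one-sided"`
switch implements the literal one-tail fifth-percentile reading.

A caveat the synthetic experiments exposed: twin samples are exchangeable
only as pairs. Full sample-label shuffling treats all 2n samples as
exchangeable, and when both methylation and expression carry substantial
pair-level variance the permutation threshold is slightly too small — the
realized null exceedance for truly uncoupled pairs runs above the nominal
5%. This is a property of the procedure itself, reproduced faithfully;
sign-structure experiments are therefore constructed so planted couplings
dominate the cis-pair list (sparse background probe spacing).

The TSS-offset profile is the mean partial correlation in 500-bp offset
bins across ±window. Robustness to the phenotype appends the
depressed-indicator to the covariates and reports the fraction of
previously significant pairs still beyond the thresholds.

## Networks

Nodes are nominally associated features (raw p < 0.001); region nodes
carry the mean beta of their probes per sample. Adjacency is unsigned,
`|r|^β`, with β the smallest integer in 1..12 whose weighted-degree
distribution reaches a scale-free fit R² ≥ 0.8, else 6 (the WGCNA
convention). Modules are average-linkage clusters of 1 − TOM cut
statically at height 0.99 — TOM dissimilarities concentrate near 1, and
the conventional static-cut level for TOM dendrograms (not 0.75, which
leaves planted 60-node blocks at r = 0.7 unmerged at power 6) — with
clusters under the minimum size dissolved. The hub maximizes mean
within-module adjacency; ties break by node id.

Differential connectivity of a node set is the difference in mean binary
degree (adjacency ≥ 0.1) between the two group networks. Its null
respects the paired design: each pair's depressed/nondepressed labels are
flipped independently with probability ½, both group matrices and networks
are rebuilt (including soft-power reselection when the power is not
pinned), and the two-sided p is (1 + #{|null| ≥ |obs|})/(B+1).

## Replication and enrichment

The replication scan is an unpaired logistic regression of case status on
each feature value plus covariates (statsmodels MLE, Wald p); separated or
non-converged fits are flagged and excluded from FDR. Region replication
takes each region's minimum converged probe p, BH-corrects over the number
of regions, and requires a concordant coefficient sign. Overlap enrichment
is a two-sided Fisher exact test on the background of genes present in
both the methylation annotation and the retained expression set; both the
odds ratio and the observed/expected fold are reported because "X times
more likely" is ambiguous between them.

## Synthetic cohorts: what they emulate and what they do not

The generator draws pairs with shared age (Uniform 18–70) and sex
(Bernoulli 0.684), twin-varying lifestyle covariates, and chip batches of
4 pairs (default 20 batches ≈ 79 pairs, the EPIC chip layout). Methylation
is logit-normal: a per-probe baseline (clipped so baselines stay below
~0.8 — a planted increase in the beta ratio must be realizable without
saturating at 1), a per-pair deviation shared by co-twins, and, within
planted blocks, a shared per-pair factor whose loading is delta-method
corrected so the realized probe–probe beta correlation matches the target
within ±0.1. The within-pair signal — planted α, covariate effects, batch
intercept (log2-ratio scale, as the model assumes), residual noise
(SD 0.2) — is applied as an exact symmetric multiplicative shift:
log2 β_dep/ctrl = log2(baseline) ± d/2, so the planted fold change is exact
up to rare clipping. Expression is log-normal on the log2(TPM+1) scale with
a pair random effect (SD 1.0) and sample noise (SD 0.5); cis couplings
replace part of a gene's variance with the coupled probe's standardized
betas to hit the target correlation, and pin the gene's TSS at the
configured strand-aware offset.

Not emulated: bimodal high-methylation probes (baselines are capped below
saturation), probe-type chemistry and normalization artifacts, count noise
in RNA-seq, cell-composition heterogeneity, genuine biological pathway
structure. Passing tests therefore demonstrate statistical correctness of
the machinery under the assumed model, not robustness to those real-data
features.

## Problem sizes and numerical choices

Test and acceptance experiments run at the cohort scale of the design
(79 pairs; 200 pairs for correlation-recovery experiments) with
500–2000 features, B = 100–500 permutations for thresholds and B = 200 for
connectivity — sizes at which every Monte-Carlo band used in the tests was
derived. Degenerate inputs: zero-variance probes contribute correlation 0
with a warning; constant covariates are dropped with a warning; constant
or separated replication features are flagged, not fatal; empty candidate
or DMR sets propagate as empty tables. Floats serialize with 6 significant
digits; all randomness flows from one integer seed through named
substreams, and stage outputs are cached by input-content hash (timings go
to the log only, so reruns are byte-identical).

## Known limitations

* The Satterthwaite df uses the expected information at the REML optimum;
  at very small batch counts (3–5) it remains approximate.
* Stouffer region p ignores within-region probe correlation (ranking
  statistic; family-level error is controlled at the region level).
* The permutation threshold inherits the full-exchangeability assumption
  discussed above.
* Static tree cut is deterministic but cruder than dynamic hybrid cutting
  for modules of heterogeneous density.
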