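# Methods

## Phenotype and model

For a gene with n isoforms and expression x₁…x_n in a sample, the
phenotype is the splicing-ratio vector p_i = x_i / Σ x_j on the simplex.
A pseudocount c is added to every expression value before forming
ratios, p_i = (x_i + c) / Σ (x_j + c), so samples with no detectable
expression still have a defined (uniform) composition; c defaults to
0.01 expression units — small against the 0.01-RPKM gene-expression
floor below, and configurable.

The simplex constraint leaves n−1 degrees of freedom, so the n ratios
cannot be tested as if independent.  Writing q_i = √p_i puts the sample
on the unit sphere (Σ q_i² = 1, radius exactly 1), and the polar angles
φ_k = arccos(q_k / √(q_k² + … + q_n²)), k = 1…n−1, are unconstrained
coordinates in [0, π/2] — the *converted splicing components*.  Isoforms
are ordered per gene by decreasing mean √-ratio across retained samples
(the transform operates on q, so q's mean is the natural ordering
statistic; ties break lexicographically on isoform id for determinism).
The inverse transform (q₁ = cos φ₁, q_k = cos φ_k ∏_{j<k} sin φ_j,
q_n = ∏ sin φ_j) is implemented for testing and round-trips to 1e−10.

Numerical edge cases: the arccos argument is clamped to [−1, 1]; a zero
trailing tail (q_k…q_n all zero, unreachable after the pseudocount but
possible on raw input) defines φ_k = 0.

The angles are unconstrained *coordinates*; their statistical
independence under arbitrary ratio distributions is an approximation.
We therefore do not assert distributional independence anywhere —
instead the consequence that matters (the χ² calibration of the
combined statistic) is measured directly under simulation (below).

## Association testing

All components of all genes are stacked into Φ (t × l, t = Σ(n_g − 1)).
Rows of Φ and of the genotype matrix V (codes 0/1/2, NA allowed) are
standardized to mean 0 and unit sum of squares over their shared
non-missing samples, making every component-variant Pearson correlation
an inner product and a block of tests one matrix product Φ·Vᵀ.

* **ANOVA model (default)**: genotype as categorical.  The one-way
  ANOVA F with df (L−1, N−L) — L the genotype groups present, N the
  shared samples — is recovered from the same inner products via the
  categorical-regression identity F = (R²/(L−1)) / ((1−R²)/(N−L)), with
  R² the squared projection of the standardized component onto an
  orthonormalized group-indicator basis (QR of the centered indicators).
  This equals textbook group-mean ANOVA to rounding error, verified
  against an independent oracle in the tests.
* **Linear model**: genotype as dose; t = r√((N−2)/(1−r²)), two-sided p
  (the standard choice in eQTL work; the dose model has no preferred
  direction a priori).

Missing data: rows are grouped by missingness pattern and each
(component-pattern × variant-pattern) block is standardized and
evaluated over its shared mask, so the batched path equals per-pair
scalar computation exactly — the property the whole speed argument
rests on, asserted to 1e−9 in the acceptance suite.  Pairs with fewer
than `min_shared_samples` (default 6) shared samples, a single genotype
group, or a constant component are skipped.

## Combination and FDR

Component p-values map to z = Φ⁻¹(1 − p) (p floored at 1e−300).  This
one-sided map makes z exactly standard normal whenever p is uniform —
which is precisely what s = Σ z_i² ~ χ²_{n−1} needs; t² and F carry no
usable sign for a sum of squares, so no signed variant is used.  The
composite p-value is the upper χ² tail at s with df equal to the number
of components actually combined (components skipped for zero variance
reduce the df and flag the pair).

Gene-level p-values across the *whole* run are converted to q-values:
Storey's estimator with the smoother π̂₀ (cubic spline through
π₀(λ) = #{p>λ}/(m(1−λ)) on λ = 0.05…0.95, evaluated at λ = 0.95,
clipped to (0,1]), falling back to π₀ = 1 — i.e. Benjamini–Hochberg —
for fewer than 100 p-values or a degenerate fit.  FDR is computed after
pooling all chunks, never per chunk, because q-values depend on the
full p distribution.

## Preprocessing filters

Applied in order; survivor counts at every stage are logged:

1. pseudocount and ratios (above);
2. *isoform activity*: an isoform is active iff its **mean** ratio
   across samples exceeds 0.05 (default); inactive isoforms are dropped
   and columns renormalized; genes need ≥2 active isoforms.  Activity is
   judged on the mean, not per sample, because a per-sample rule would
   make the component dimension sample-dependent, which the transform
   cannot represent;
3. *splicing variability*: genes below 0.01 (default) are dropped.
   Variability is the mean squared Hellinger distance of the samples to
   their Hellinger centroid (element-wise mean of the √-ratio vectors,
   renormalized to the sphere) — consistent with the distance the
   reference test uses, and invariant to column permutation and
   replication;
4. *per-gene sample filter*: samples whose total gene expression is at
   or below 0.01 RPKM (default) are dropped for that gene;
5. *variant groups*: genotype groups smaller than 5 samples (default)
   are masked to NA; variants with fewer than 2 surviving groups are
   dropped.

Missing expression cells are rejected at parse time rather than
imputed; genotype hard calls only (no dosages), biallelic VCF records
only (multi-allelic records are skipped with a warning).

## Reference Anderson test

The per-pair oracle computes the Hellinger distance
d_H(a,b) = √Σ(√p_ia − √p_ib)² and the decomposition SS_B = SS_T − SS_W
with the pairwise-distance identity SS = (1/N)Σ_{a<b} d²(a,b) applied
overall and per group; the centroid route (embedding mean of √p, not
renormalized) is kept as a cross-check and agrees to 1e−9.  The pseudo
F-ratio F = [SS_B/(L−1)] / [SS_W/(N−L)] is assessed by label
permutation, p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), seeded and
reproducible; permutation replaces the approximate analytic null some
implementations use because it is exact and reproducible, at the price
that oracle p-values have resolution 1/(n_perm+1).  A Bartlett test on
per-sample distances to the group centroid is reported as a
group-dispersion homogeneity warning; no PCA-based dispersion filtering
is applied.

## Simulator

Dirichlet is the canonical simplex distribution and directly produces
the compositional phenotype, so each gene's ratio vector is
Dirichlet(α_g) with α depending on the sample's genotype at that gene's
single causal variant: homozygote groups favour opposite isoforms
(first/last concentration multiplied by the `concentration_ratio`),
heterozygotes get the mean α.  Null genes use one α for everyone.
Genotypes are i.i.d. HWE draws at the configured allele frequency;
total gene expression is Gamma with mean `gene_expression_scale`
(default 10 RPKM) and squared coefficient of variation
`noise_overdispersion` (default 0.5); isoform expression is total ×
ratios.  Defaults: 200 samples, 20 genes (10 sQTL), 3 isoforms/gene,
allele frequency 0.3, concentration ratio 5, base concentration 2 —
moderate sample size and effect strength for a population RNA-seq
cohort.

What the simulator does *not* emulate: linkage disequilibrium between
variants, quantification noise correlated across isoforms, population
stratification, covariates, or sample-dependent isoform sets.  Passing
tests demonstrate the statistical machinery is correct and calibrated
under the generative model, not that real-data p-values are immune to
those artefacts — on real data the permutation oracle on top hits and
the Bartlett homogeneity warning are the intended safeguards.

## Validation studies (tests/test_acceptance.py, scripts/acceptance.py)

Study sizes are chosen to give stable estimates on a single core:

* transform round-trip: 10⁴ Dirichlet vectors, 2–8 isoforms; error
  < 1e−10, radius < 1e−12;
* engine equivalence: 200 random instances (t,k ≤ 7, l ≤ 50, 8% NA,
  both models) against scalar oracles; agreement < 1e−9;
* null calibration: 1000 effect-free genes × 100 variants, n = 200
  (10⁵ pairs); KS distance from U(0,1) < 0.05 and type-I error at
  α = 0.05 within 3 binomial SEs;
* power: 60 genes (half causal at concentration ratio 5), n = 150;
  ROC-AUC of composite p-values vs ground truth > 0.9;
* oracle concordance: 150 genes with effects spanning ratios 1–6,
  cis candidate pairs (each gene vs its own variants) with fast-path
  p < 0.1, permutation oracle at n_perm = 1000; Spearman ρ > 0.5.  The
  candidate-pair design mirrors how single-pair oracles are actually
  deployed (on candidate or reported associations): among all-vs-all
  null pairs both methods produce independent uniform p-values and no
  correlation is expected or informative;
* SS identity and route agreement on 100 random instances, < 1e−9;
* exact filter bookkeeping on a constructed fixture; chunking
  invariance for chunk sizes 1, 37 and all-in-one.

## Chunked execution

Variants are split into chunks (default 1000) tested independently —
results are bit-identical whatever the chunk size, and chunks may run
concurrently (`n_workers`); merging sorts by (gene, variant) and
recomputes FDR on the pooled p-values.  An optional `--cis-window`
restricts reported pairs by distance to the gene body (requires a gene
annotation TSV); the default is all-vs-all, which is the point of the
fast path.

## Known limitations

* Component F/t p-values assume approximately normal within-group
  component distributions; angles are bounded, so calibration relies on
  group sizes large enough for group-mean normality (the group-size
  floor of 5, and in practice tens of samples).  The null-calibration
  study measures the net effect.
* The composite χ² treats component z's as independent; dependence
  between a gene's angles under non-Dirichlet data would make the test
  conservative or liberal — again measured, not assumed.
* The oracle's permutation p-values have resolution 1/(n_perm+1);
  rankings among very strong hits saturate at that floor.
* Small expression values near the pseudocount are dominated by it,
  pushing compositions toward uniform; the gene-expression sample
  filter is the guard.
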