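# Methods

This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic cohorts do and do not emulate.

## Study design being modeled

A cohort of patients each contributes one normal sample, one pre-treatment
needle biopsy, and several (default 3) spatially separate tumor samples
taken at surgery after a course of therapy. Biopsy and nephrectomy samples
are the "pre" and "post" conditions of all treatment contrasts. A separate
two-patient control design (the *hypoxia preset*) pairs samples taken just
before and after renal-artery ligation with no treatment effect, isolating
the effect of the sampling procedure itself.

## Synthetic cohorts

### Methylation counts

Fragment counts per methylation core are negative binomial
(gamma–Poisson), with per-observation mean

    mu_gi = R_i * b_g * 2^(u_{g,p(i)} + treat_i * logFC_g)

where `R_i` is the library size, `b_g` a lognormal relative core abundance
(normalized to sum 1), `u_{g,p}` a per-(core, patient) normal effect on the
log2 scale, and `logFC_g` the injected treatment effect on designated target
cores. Counts are drawn as Poisson(Gamma(1/α, α·μ)) at dispersion α.

Defaults and rationale:

- **n_cores = 1200, n_target_genes = 48** — one promoter core per target
  gene plus background cores (60% promoter-annotated), enough loci for
  stable variance-trend and prior estimation while keeping a full
  differential-methylation run under 0.1 s.
- **library_size_range = (300k, 600k)**, biopsies scaled to 25–50% of a
  nephrectomy-range draw — biopsies are systematically shallower, which is
  exactly the situation the precision weights exist to handle. Mean
  coverage is a few hundred fragments per core.
- **nb_dispersion = 0.01** (biological CV ≈ 0.1). The treatment contrast is
  within-patient (patient fixed effects absorb between-patient variation),
  so the residual dispersion is at technical/within-tumor scale. Together
  with the library depths this pins the sampling noise of the estimated
  logFC at roughly ±0.06, so a 0.87 injected effect is estimated within
  ±0.15 in ≥ 95% of seeds — the calibration the generator is specified to
  meet. Real archive data have no published per-core coverage
  distributions; these defaults are chosen for testability, not fidelity to
  any deposited series.
- **patient_effect_sd = 1.0** (log2): strong patient identity, matching the
  observation that a patient's samples cluster together on the methylome.
- **treatment_logfc = {"VHL": 0.87}** by default: the study condition the
  cohort emulates is a single consistently hypermethylated target promoter
  of that magnitude (log2, post minus pre). Our sign convention is
  post-minus-pre; positive means hypermethylated after treatment.

### Variants

Per patient, somatic variants are planned as truncal (all tumor samples),
shared (a random subset of ≥ 2, not all), and private (one sample), with
Poisson-distributed counts (defaults 5 / 3 / 2; germline 10). Each call
carries genotype, GQ, allele depths, a 21-bp reference context, and
consequence/damaging annotations. A configurable 10% of somatic calls
violates exactly one quality filter (low GQ, low VAF, or homopolymer
adjacency) so the filters are exercised; 5% leak into another patient's
normal, making them non-tumor-specific. Passing variants' categories,
presence sets and per-sample private counts are recorded as ground truth.

### BAF and coverage

One SNP panel (150 SNPs per simulated chromosome) serves all patients;
allele counts are binomial at Poisson depth (default mean 200). Inside
injected LOH segments the tumor allele fraction moves to 0.5 + shift
(default segment: a 20-Mb region at shift 0.25, echoing recurrent
chromosome-3p LOH at sub-clonal magnitude — never fully to 0 or 1). Tumor
binomial draws use inverse-CDF sampling so that records outside a segment
are bit-identical whatever the segment parameters. Per-amplicon coverage
(6 targets per gene) is lognormal around a shared per-target baseline, with
Poisson(1)-many single-copy gene events per tumor sample (log2 ratio −1 or
+0.585).

### What the generators do not emulate

Raw reads, capture chemistry, mapping artifacts, GC effects, correlated
neighboring cores, subclonal VAF structure within a sample, sex chromosomes,
or real genome annotation. Tests passing on these cohorts certify the
statistical machinery under its stated assumptions, not performance on any
particular archive dataset.

## Differential methylation engine

Pipeline: promoter/coverage core filter (promoter flag AND mean count ≥ 1,
boundary inclusive) → log2 CPM with the half-count offset → quantile
normalization → OLS residual trend (lowess of √sd vs average log2 count,
span 0.5, minimum 50 loci else unit weights) → per-observation weights
(predicted sd)⁻⁴ → weighted least squares per core → empirical-Bayes
variance shrinkage → moderated t with d₀ + d degrees of freedom → BH FDR
restricted to target cores.

Numerical conventions:

- **Design matrix**: intercept + patient fixed effects + treatment
  indicator (blocked, the default, since samples are patient-matched); an
  unblocked two-group design is available by flag. The two-patient hypoxia
  preset has 1 residual df per core under blocking; the heavy prior
  shrinkage (d₀ estimated from ~700 filtered cores) is what makes that
  design testable at all.
- **Prior estimation**: moments of log s² with digamma/trigamma inversion;
  Newton iterations for the trigamma inverse; `d₀ = ∞` branch (all
  s̃² = s₀²) when the observed log-variance spread is below its sampling
  floor.
- **Quantile normalization ties**: the default breaks ties by stable sort
  order, which makes every column's sorted vector *exactly* identical —
  the post-condition the pipeline guarantees. The microarray convention
  (tied values share the mean of their rank-means) is available as
  `ties="average"` but sacrifices exactness of that invariant.
- **Quantile categories**: linear-interpolation quartiles over all samples
  of a region; left-closed intervals (a value exactly at a boundary goes
  up); all-equal regions collapse to the lowest category; per patient the
  pre value is the biopsy value and the post value the mean over
  nephrectomy samples (averaging happens only here — the linear model sees
  every nephrectomy sample as a replicate observation).
- **Gene-level reporting**: FDR is computed across target cores; the
  per-gene table keeps each gene's smallest-p core and additionally reports
  a BH adjustment over those per-gene p-values, since either family could
  be the one a reader wants.

### Calibration and its limits

On Gaussian and negative-binomial null cohorts the moderated p-values are
uniform (KS) with near-nominal bulk tails. In the far tail (p < 0.002) a
residual ~1.5–2× excess remains: with d₀ estimated large, mild variance
heterogeneity that the lowess trend does not absorb is shrunk onto a common
prior, slightly fattening extreme statistics. Practically: with 48 targets
tested at FDR 10%, about 1 cohort in 6–8 shows one null target alongside a
true strong hit, and about 1 in 8–10 null cohorts shows a single false
positive. This matches the binomial expectation under uniform nulls (a
second BH rejection needs a null p ≤ 2·0.1/48 ≈ 0.004) and is a property of
the moderated-t approach itself, not of this implementation.

## LOH segmentation

Mirrored deviations d_j = |BAF_j − 0.5| (phase is unobservable from
unphased SNPs) are segmented per chromosome by recursive binary splitting:
take the split maximizing the two-sample Welch t between flanks while its
p-value is below α = 0.01, with both flanks ≥ min_snps = 10 points. Because
the greedy search cannot place a split closer to a block edge than the
minimum segment size, a refinement pass then relocates each breakpoint to
the best split between its neighbors (minimum 2 points) and drops
breakpoints that stop being significant — standard changepoint practice
that removes a 5–15 SNP boundary bias present in ~5% of tracks. Segments
with mean deviation ≥ 0.15 and ≥ min_snps SNPs are flagged LOH; adjacent
LOH segments merge; mean deviation < 0.45 marks the call sub-clonal
(allele fraction not shifted fully to 0 or 1). Sub-clonal LOH is reported
but excluded from phylogenetic profiles by default, mirroring the analysis
convention for unphased multi-region data; a flag re-includes it. This
segmenter is the package's own documented algorithm, simpler than the
HMM-based exome CNV tools used historically for this task; the downstream
analyses only consume segment calls and counts.

## CNV calling

Per-target coverages of tumor and matched normal are each divided by their
sample median (making calls invariant to global scaling), log2 ratios are
averaged per gene, and thresholds assign states (loss < −0.4,
gain > +0.3). Zero-coverage normal targets are masked. This is a
deliberately simple documented stand-in sufficient for segment counts and
presence/absence features.

## Phylogenies and concordance

BioNJ follows the published description: Q-criterion pair selection,
two-point branch lengths, and reduction d(u,k) = λ(d(i,k) − ℓᵢ) +
(1−λ)(d(j,k) − ℓⱼ) with λ minimizing the variance of the reduced distances
under a variances-proportional-to-distances model, clamped to [0, 1].
Determinism: Q ties break toward the lexicographically smallest pair of
subtree labels (a subtree is labeled by its smallest leaf). Negative branch
estimates are clamped to zero with the deficit moved to the sibling edge.
On additive matrices the reconstruction is exact to < 10⁻⁹; on ultrametric
matrices it coincides with plain NJ.

Branch labeling places a driver on the unique edge whose bipartition equals
its presence set; drivers present in all leaves label the trunk; drivers
matching no edge are returned as homoplasy/inconsistent.

Concordance on a cohort dendrogram: a patient is *complete* when some
cluster's leaf set equals exactly the patient's tumor samples, *partial*
when some cluster of ≥ 2 leaves is a proper subset of them (and complete
fails), *none* otherwise; single-sample patients are trivially complete and
flagged. The mutation dendrogram uses Manhattan distance + complete
linkage (consistent with the per-patient distance choice; configurable),
the methylome dendrogram Euclidean + complete linkage on the 1000
largest-variance loci.

## Known limitations

- The far-tail calibration excess described above bounds how often a single
  injected effect is the *only* FDR < 0.1 target (~80–85% of cohorts, with
  the remainder carrying one extra null target).
- The CNV caller has no segmentation along the genome within a gene and no
  purity/ploidy model; log-ratio thresholds are nominal single-copy values.
- Sharing classification treats presence as binary non-reference genotype;
  it does not model VAF-based clonality, and a patient with a single tumor
  sample is classified truncal (the all-samples rule takes precedence).
- The Wilcoxon exact path enumerates all group assignments and is intended
  for group sizes ≤ 10 (as configured); larger groups use the tie-corrected
  normal approximation.
- Real-data mode consumes VCF/TSV/BED inputs with annotations already
  attached (consequence, SIFT/PolyPhen labels); no annotator or aligner is
  run.
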