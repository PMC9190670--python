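# Methods

`pedmeth` analyzes promoter DNA methylation in pediatric tumor cohorts
against a multi-cohort normal baseline. This note documents the models,
the tunable parameters, the synthetic-data generator, and the numerical
and design choices a maintainer would want to know about. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Scales and transforms

Array methylation is summarized per CpG probe as a beta value
β = M_signal / (M_signal + U_signal) ∈ [0, 1]. Statistical testing uses
M-values, M = log2(β / (1 − β)), which unlink the variance from the mean
near the boundaries. Betas are clamped to [1e−6, 1 − 1e−6] before the
logit so that 0 and 1 stay finite; the inverse transform
β = 2^M / (2^M + 1) restores betas exactly (round-trip error < 1e−12 on
the clamped domain, verified on 10^6 random values).

## Preprocessing and filters

Inputs are probe × sample beta matrices (TSV), a probe → (gene, TSS
distance) annotation, per-sample metadata (cohort/batch, sex, condition,
tumor type), tumor gene expression, annotated somatic variants (VCF 4.2
with a VEP-style CSQ field) and RNA fusions (BEDPE).

1. **Promoter window** — only (probe, gene) pairs with TSS distance
   ≤ 300 bp are kept. The boundary is inclusive; the window is a
   parameter (`window_bp`).
2. **Gene summarization** — per gene and sample, the arithmetic mean of
   its probes' values. Probes annotated to several genes contribute to
   each gene independently.
3. **Invariant-category filter** (differential track only) — probes whose
   per-sample level category (low < 0.2 ≤ medium ≤ 0.6 < high, applied to
   each individual beta) is identical across every sample of every cohort
   carry no contrast and are dropped.
4. **Expression-correlation filter** (differential track only) — per
   probe, the Spearman correlation between its M-values and its gene's
   tumor expression across shared tumor samples; Benjamini–Hochberg (BH)
   across probes; adjusted p < 0.05 with either sign retains the probe.
   Both signs are accepted because promoter methylation is usually but
   not universally repressive; probes with no expression row or a
   constant vector are removed and tallied separately.
5. **Cross-cohort divergence filter** — probes differentially methylated
   (FDR < 0.05 and |log2 FC| ≥ 2, sex-adjusted moderated model below)
   between *any* pair of normal cohorts are dropped as
   cohort-idiosyncratic.
6. **Batch correction** — the pooled normal matrix is logit-transformed,
   adjusted with the parametric empirical-Bayes location–scale algorithm
   (ComBat), and mapped back through the inverse logit so betas stay in
   (0, 1). Features are standardized against fitted batch means and
   pooled variance; per-batch per-feature location (γ) and scale (δ)
   effects are shrunk toward their batch-wise distributions via
   normal / inverse-gamma priors fit by moments, then removed. Only the
   parametric prior is implemented. Two caveats a user should know:
   shrinkage leaves O(1/√n) per-feature residual batch noise (the
   systematic shift is removed), and per-feature grand means move by
   O(1/n) rather than being exactly preserved — the reference
   implementation (sva::ComBat) behaves identically, and our
   implementation matches it to 1e−3 on shared fixtures
   (`tests/test_r_oracles.py`).
7. **PCA QC** — first two sample-space principal components with batch
   labels, plus a separation statistic (between-batch spread of PC1
   centroids over mean within-batch spread) used only for reporting.

Filter tallies are `FilterReport`s whose chained input/output counts are
asserted consistent.

## Baseline categorization

Per cohort, a gene's **level** is low / medium / high by the median beta
across samples (low < 0.2, high > 0.6, strict inequalities: boundary
medians are medium) and its **variance** is low / high by the
coefficient of variation (sample SD over mean of betas; CV < 0.5 is low,
a CV of exactly 0.5 is high). CV is computed on the beta scale — on the
M scale it is ill-defined near 0. A zero-mean vector is assigned CV 0 by
convention (unreachable after clamping, but guarded).

Across cohorts a gene is **consistent** when its (level, variance) pair
agrees in all cohorts, **semiconsistent** in all but one, and
**inconsistent** otherwise; the 4-cohort rule generalizes to any cohort
count as all / all−1 / fewer. Modal categories use a fixed tie-break
order (low < medium < high crossed with low < high) so results are
deterministic. The normal → tumor change table reports, per ordered
category pair, the number and percentage of genes moving between modal
categories, plus aggregate counts of level increases (low→medium,
medium→high) and variance low→high moves. Percentages for display are
rounded half-up (`categorize.percent`); the table itself stores raw
ratios.

## Differential methylation

Per feature, ordinary least squares of M ~ intercept + group + sex; the
group coefficient is the log2 fold change (a difference of group means on
the M scale is already a log2 ratio). Sex enters as a binary covariate;
samples with unknown sex are dropped with a logged count, and a design
where group and sex are collinear is rejected. Residual variances s² with
d degrees of freedom are shrunk toward a scaled inverse-chi-square prior:
s̃² = (d₀·s₀² + d·s²)/(d₀ + d). The hyperparameters (d₀, s₀²) are
estimated by moment-matching the log variances (digamma/trigamma moments
of log s², with a Newton inversion of the trigamma function); when the
observed spread of variances is no larger than sampling alone explains,
d₀ = ∞ and the moderated t reduces to a z-statistic. The moderated t has
d₀ + d degrees of freedom, two-sided p-values, BH adjustment across
features, and a feature is **significant** iff FDR < 0.05 *and*
|log2 FC| ≥ 2. `moderated=False` gives the ordinary OLS t (the d₀ = 0
limit) for oracle comparisons. The implementation matches
limma::lmFit/eBayes to 1e−5 on shared fixtures.

Tumor-vs-normal contrasts run each tumor type against the batch-adjusted
normal pool (probe and gene level), recording per feature the number of
types in which it is significant. Pairwise tumor contrasts fit separate
two-group models for each of the C(T, 2) pairs — simpler than one joint
multi-group fit and directly interpretable — and report features
significant in any pair together with the maximal-|log2 FC| pair.

## Aberrant methylation

Per gene, the reference is the mean and SD (n−1) of the batch-corrected,
gene-level normal betas. A tumor is **hypermethylated** for a gene when
z = (value − mean)/SD > 3 and **hypomethylated** when z < −3 (strict;
k = 3 is a parameter). Calling operates on the beta scale — z-scores are
scale-equivariant but a scale must be fixed, and betas keep the reference
interpretable; the CLI exposes `--scale` for M-value calling. Genes with
zero reference SD are excluded from the callable set and from proportion
denominators, with a logged count. Per-tumor proportions of hyper/hypo
genes, class-stratified rates (oncogene / tumor suppressor / other ×
hyper / hypo / mutation, as fractions of gene×tumor pairs), and the
one-sided Welch t-test of "oncogene mean M > tumor-suppressor mean M" in
normals complete this stage.

## Mutation events

A variant is damaging when (1) its impact is HIGH, or (2) its impact is
MODERATE and SIFT calls it deleterious or PolyPhen-2 calls it damaging or
probably_damaging. LOW/MODIFIER variants are never damaging, even with
damaging SIFT/PolyPhen annotations — rules (1)–(2) are treated as
exhaustive. SIFT/PolyPhen strings are matched case-insensitively on the
token before any parenthesized score; the CSQ subfield names are
configurable (`CsqDialect`) since annotation layouts vary by tool. No
minor-allele-frequency filter is applied. A gene is *mutated* in a tumor
when it has ≥ 1 damaging SNV/indel or participates in ≥ 1 RNA fusion;
fusions hit both partner genes. Records outside the gene/sample universe
are ignored with a logged count.

## Mutual exclusivity

The statistic is the number of (gene, tumor) pairs carrying both a
mutation and an aberrant-methylation event (hyper OR hypo), restricted to
genes with ≥ 5 events of each type (inclusive). The null shuffles each
gene's methylation-status vector across tumors independently — preserving
every gene's event count, the quantity the ≥ 5 filter conditions on —
while mutations stay fixed; 10,000 permutations by default. The empirical
p-value is left-tailed with the add-one convention,
p = (#{null ≤ observed} + 1)/(N + 1), so small p indicates mutual
exclusivity; p is bounded in [1/(N+1), 1] and deterministic given the
seed. For a single gene the shuffle null is exactly hypergeometric, which
provides an enumeration oracle. The count statistic is discrete, so at
very small scales the p-value is conservative (stochastically above
uniform); calibration checks therefore use instances large enough for the
statistic to take many distinct values. Directional variants test
oncogene-mutation × hypomethylation and tumor-suppressor-mutation ×
hypermethylation on the corresponding gene classes with the same
machinery.

## Synthetic data generator

The generator produces the study conditions every recovery and
calibration suite runs on. Defaults: 2,000 genes × 2 promoter probes,
4 normal cohorts × 30 samples, 3 tumor types × 40 tumors — desk scale.

* **Archetypes.** Each gene draws a (level, variance) archetype —
  fractions 0.65 low/low, 0.17 medium/low, 0.15 high/low, 0.015 low/high,
  0.015 medium/high — with a baseline beta inside the category band
  (low 0.06–0.13, medium 0.28–0.45, high 0.72–0.88). Noise is
  logistic-normal: Gaussian on the M scale, mapped through the inverse
  logit so betas respect [0, 1]. Low-variance genes use an M-scale SD
  equivalent to beta SD 0.02; high-variance genes use σ_M = 1.5
  (low level) or 2.2 (medium level), calibrated so realized CVs sit well
  above 0.5 while medians stay in band. The high/high archetype is
  omitted by default: with bounded betas and a median above 0.6,
  logistic-normal noise cannot reliably produce CV ≥ 0.5, matching this
  category's near-absence in real cohorts.
* **Cohort structure.** Per (cohort, gene) batch shifts ~ N(0, 0.3) on
  the M scale; sex ~ Bernoulli(0.5) with M-scale sex effects
  ~ N(0, 0.5) on a random 5% gene subset; per-probe offsets (SD 0.15 M)
  and per-probe-per-sample jitter (SD 0.05 M); an extra beyond-window
  probe for ~25% of genes exercises the promoter filter.
* **Tumors.** Drawn from the same generative model (no tumor batch
  shift by default — tumors are compared against the corrected normal
  pool). Planted aberrations are *regime replacements*: the tumor's gene
  value is re-drawn at reference mean ± 4 reference SDs with residual SD
  0.25 × reference SD, modeling a switch to a new methylation regime.
  An additive shift on top of full tumor noise would cap 4-SD recall
  near 0.84 by construction; replacement makes "planted 4 SD" mean what
  it says, and recall/false-call criteria test the caller, not the
  generator's noise budget. Per tumor, round(frac × n_genes) genes are
  shifted (defaults: 5% hyper, 10% hypo), restricted to genes whose
  reference band keeps the target inside (0, 1). Each tumor type also
  gets 5 type-specific differential genes with a fixed +4 M shift.
* **Expression.** For a random half of genes, tumor expression is a
  negative linear function of the gene's methylation M plus noise; the
  rest is independent — exercising both outcomes of the
  expression-correlation filter.
* **Events.** Mutations are Bernoulli per gene × tumor (default rate
  0.03, near observed pediatric gene×tumor mutation rates); placement is
  independent of, excluded from, or restricted to aberrant cells
  according to `cooccurrence_mode`. 10% of events are emitted as fusions
  (partner genes outside the analysis universe so the planted truth
  matrix equals the parsed matrix exactly), and 20% of SNVs are annotated
  to fail the consequence filter. Events are written as per-sample
  VCF/BEDPE through the package's own writers so parsers run end to end.

Everything is deterministic given `seed`; truth tables record planted
archetypes, aberrations, differential genes and events, sufficient to
score every downstream caller.

**What passing these suites does and does not show.** The generator
reproduces the statistical *structure* the analysis assumes —
archetype-driven baselines, batch shifts, sex effects, rare planted
aberrations, rare mutations with a controllable dependence. It does not
emulate array chemistry (type I/II probe bias, detection p-values),
cell-type composition shifts, copy-number contamination of methylation
signal, or correlated probe blocks beyond the shared gene noise. Green
suites demonstrate the pipeline's statistical machinery is calibrated and
recovers planted truth under its own model; they do not certify
performance on raw array data, which additionally depends on upstream
normalization quality.

## Numerical choices and degenerate inputs

* Epsilon clamp 1e−6 before logits; strict inequalities at every category
  and z-score threshold; modal-category ties broken by the fixed order.
* Trigamma inversion by Newton iteration (50 iterations max, relative
  tolerance 1e−8); ComBat EB iteration to relative change < 1e−4.
* Zero residual variance features get finite moderated t via s̃² > 0 when
  d₀ > 0; zero reference SD genes are flagged and never called aberrant;
  constant vectors in the expression filter are removed as degenerate.
* Empty gene lists, singleton batches, single-sample references and
  fully confounded designs are hard errors with specific messages.
* Problem sizes in the test and acceptance suites (2,000 genes, 4 × 30
  normals, 3 × 40 tumors, 5,000-feature differential runs, 200-replicate
  mutex calibration at 500 permutations, 20-replicate power runs at
  10,000 permutations) are the package's default desk-scale study; they
  complete in well under a minute each on one core.

## Known limitations

* Non-parametric ComBat priors, surrogate-variable analysis and
  random-effect models are out of scope.
* The differential model assumes independent samples and a common
  variance per feature across groups (moderated pooled-variance t).
* Gene-level tests use means of probe M-values; alternative summaries
  (median, weighted by probe quality) are not implemented.
* Copy-number events are not integrated into the mutation matrix.
* The mutual-exclusivity permutation preserves per-gene event counts but
  not per-tumor totals; tumor-level mutational burden structure is
  therefore not part of the null.
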