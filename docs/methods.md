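# Methods

`oomt` implements a joint analysis of single-cell transcriptomes (scRNA-seq)
and methylomes (scBS-seq) from the same cells, built around the statistical
problem posed by germinal-vesicle oocytes from reproductively young vs. aged
female mice: sparse binary methylation calls per cell, a strongly bimodal
methylation landscape, and modest cohort sizes (~30 methylomes and ~45
transcriptomes per age group).  This note records the models, the stand-ins,
the numerical choices, and what the synthetic benchmark does and does not
show.

## Methylome representation and quantification

A cell's methylome is a table of strand-resolved calls: chromosome, 1-based
position, context (CpG / CHG / CHH) and methylated / unmethylated counts.
scBS-seq typically observes each site at most once per cell, so counts are
usually (1,0) or (0,1); the simulator's `reads_per_site` option produces
deeper, pseudobulk-like tables.  All intervals (domains, gene bodies, gDMRs,
CpG islands) are 0-based half-open BED coordinates; a 1-based call at
position *p* belongs to `[start, end)` iff `start < p <= end`.  The
conversion lives in one place (`methylome.pos_to_offset` and the searchsorted
logic of `quantify_regions`).

Global and regional methylation are **call-weighted**: 100·Σm/Σ(m+u).  For
single-read calls this is identical to a per-site average, which is why the
per-call convention was chosen; with `reads_per_site > 1` deeper sites weigh
more.  A region or context with zero calls is *missing* (NaN or an
`UndefinedValueError`), never 0% — sparse coverage must not masquerade as
hypomethylation.

QC follows the standard scBS-seq discard rules: mapping efficiency < 10%
(an upstream alignment metric, supplied via the samplesheet and checked only
when present), fewer than 500,000 CpGs covered, global CpG methylation above
50%, and X-chromosome CpG-island methylation of 10% or more.  The X-CGI rule
detects somatic (granulosa-cell) contamination: CGIs on the inactive X are
heavily methylated in female somatic cells, while oocyte X chromosomes are
reactivated and their CGIs essentially unmethylated; oocytes sit below 10%
and granulosa cells above 20%, so the 10% cut sits inside the gap.

Group comparisons of per-cell summaries use the two-sided Wilcoxon rank-sum
test: exact enumeration when the pooled sample is at most 20 without ties,
otherwise the tie-corrected normal approximation.

## Consensus DMR calling

Single-cell coverage (3–30% of CpGs) is too sparse to test cells
individually, so cells are merged into pseudobulks.  Per *combination*, each
age group is shuffled and partitioned into `floor(n/group_size)` disjoint
pseudobulks of exactly `group_size = 10` cells (3 per group at 30/32 cells);
the `n mod group_size` leftover cells are dropped for that combination,
different cells each time.  One hundred such combinations are drawn.

Differential methylation is tested per genomic domain (the hyper/hypo/
intermediate tiling is the test unit; sub-domain windows are out of scope)
with a weighted logistic regression: a binomial GLM of the methylation
proportion on an age indicator, observations weighted by their call totals.
With a single binary covariate the MLE is available in closed form — the
fitted group log-odds are the pooled empirical log-odds, and the Wald
variance is `1/m_y + 1/u_y + 1/m_a + 1/u_a` — so the per-domain test is a
vectorised closed-form computation; the test suite verifies it against an
independent IRLS fit to 4 significant figures and against the log-odds-scale
two-proportion z-test in the saturated case.  Wald rather than
likelihood-ratio p-values are used (standard for binomial GLMs with few
observations).  Complete separation (a group entirely at 0% or 100%) falls
back to Haldane–Anscombe smoothing (+0.5 per pooled cell) and is flagged.

A domain is *tested* in a combination only if every pseudobulk of both
groups carries at least `min_calls = 10` calls in it.  Within each
combination, p-values across tested domains are Benjamini–Hochberg adjusted;
a domain is a **consensus DMR** if q < 0.05 in at least 95% of the
combinations in which it was tested (untested combinations never enter the
denominator; domains tested in under half the combinations are excluded with
an `insufficient_testing` flag).  The direction is the sign of the mean
effect (aged − young, percentage points, on pooled proportions).

Two structural consequences are worth noting.  Because the GLM pools
pseudobulks within a group, the randomised combinations differ only through
the leftover-cell rotation and the per-pseudobulk coverage filter; the
consensus therefore mainly protects against calls that hinge on particular
cells or marginal coverage, exactly the failure mode the procedure targets.
And because the test is binomial, cell-to-cell biological variability beyond
binomial sampling makes it anti-conservative; the synthetic benchmark keeps
that variability small (1pp per cell per domain, see below), so the
calibration results bound the behaviour under those conditions only.

DMR sets are annotated by domain class with a two-sided exact binomial test
per class against the class share of tested domains.  As a transparent
stand-in for Bayesian methylome imputation/clustering, cells are assigned to
age groups by nearest-centroid classification on their DMR methylation
vectors, with a missing-aware distance (RMS difference over co-observed
DMRs, at least 3 required) and a leave-one-out mode; the validation claim is
reproduced as a recovery property on synthetic data, not as a reimplementation
of the published model.

## Transcriptome analyses

Counts are normalised with median-of-ratios size factors (restricted to
genes expressed in every cell, rescaled to geometric mean 1; total-count
scaling as a flagged fallback) and transformed as log2(normalised + 1)
throughout.  Transcript diversity is the per-cell count of genes with at
least one read.

**Chromatin state.**  GV oocytes are NSN (transcriptionally active,
immature) or SN (silent, competent).  Cells are classified by Ward
hierarchical clustering (Euclidean) on z-scored log-normalised expression of
an SN signature — genes at least two-fold overexpressed in SN oocytes — cut
at two clusters; the cluster with higher mean signature expression is SN.
Cells are pre-sorted lexicographically so the dendrogram, and hence the
labels, are invariant to input order.

**Differential mean.**  A two-sided rank-sum test per gene on normalised
counts with BH adjustment, plus log2 fold change of normalised means
(pseudocount 1).  This is a deliberately simple, assumption-light stand-in
for NB-GLM machinery; the DEG set can equally be supplied as an input file
so downstream stages do not depend on it.

**Differential variability.**  Per gene and group, the NB2 dispersion α
(variance = μ + αμ²) is estimated by maximum likelihood on normalised
counts; since the NB2 mean MLE is the sample mean, only log(1/α) needs
optimising, done with a few vectorised Newton steps (the implementation is
checked against brute-force likelihood maximisation).  The statistic is the
Wald-standardised difference of log dispersions (aged − young), using the
observed-information variances.  α is mean-decoupled, so no mean-trend
regression is needed.  Significance comes from seeded group-label
permutations with the null **pooled across genes** — the standardised
statistic is exchangeable between genes, and pooling gives p-value
resolution of ~1/(genes × permutations), which BH across thousands of genes
requires (a per-gene null at 50–1000 permutations cannot reach the BH
threshold at all).  q < 0.10 is the conventional cut.  An earlier design
used a moment-based residual-CV² statistic; it was abandoned because the
sample CV² of heavy-tailed NB data is biased low at n ≈ 43 cells, capping
power far below what the dispersion signal supports.  Genes expressed in
fewer than 5 cells per group are excluded.

**Heterogeneity, trajectory, subgroup.**  Within-group heterogeneity is
summarised as all pairwise Euclidean distances on log-normalised expression
of a gene subset (typically the DV genes), compared between groups by
rank-sum.  The maturation trajectory (aged NSN → young-like aged NSN →
young NSN → SN) is tested by per-gene linear regression of log-normalised
expression on the ordered cluster index (t-test on the slope, Bonferroni),
with maternal-effect-gene enrichment as a one-sided rank-sum test on the
p-value ranks.  The young-like subgroup is found by Ward-clustering aged
cells into two groups on log-normalised DEG expression and flagging the
cluster whose centroid is nearer the young centroid (ties flag both, so
aged cells indistinguishable from young are all young-like).  PCA uses the
top 2,000 variable genes on z-scored log-normalised counts, with per-PC
simple-regression p-values against covariates; it replaces technical-noise
PCA decomposition, and embedding-based clustering is replaced by Ward
clustering on PC scores.

## Integration

Gene-body methylation is quantified per (gene, cell) with at least
`min_calls = 5` calls (else missing).  Coupling is the Pearson correlation
(two-sided t-based p) between a gene's log-normalised expression and its own
gene-body methylation across cells with both measurements, requiring
`min_cells = 10`; both thresholds are configurable choices where no
published value exists.  DMR–gene overlap is half-open interval intersection
of at least 1 bp.  Concordance across genes is the Pearson correlation
between expression log2 fold change (normalised means) and the group-merged
methylation difference in percentage points.

## The synthetic-data generator

The generator is the benchmark's definition of "truth" and emulates the
study's statistical structure:

- **Landscape**: alternating hyper / inter / hypo / inter domains with
  log-normal sizes (σ = 0.5, a shape choice — only the medians, 20.9 kbp
  hyper and 24.9 kbp hypo, are constrained by the oocyte methylome;
  intermediate domains default to a 10 kbp median).  Rates are uniform
  within class bounds (hyper 75–100%, hypo 0–25%, inter 25–75%).
  Unmethylated domains are made CpG-denser (spacing multipliers 0.7 / 1.0 /
  1.2 for hypo / inter / hyper around a 100 bp mean), as CpG islands are;
  this places call-weighted global methylation near 40%, inside the 30–45%
  band real oocytes show.
- **Cells**: each CpG site is covered independently with a per-cell
  coverage fraction drawn uniform on 3.4–29.9%; a covered site carries one
  binary call with probability = domain rate + per-cell per-domain Gaussian
  noise (default sd 1pp — residual biological/technical variation beyond
  binomial sampling; the published data constrain only that it is small) +
  a global aged shift (default −1pp, direction from the observed global
  reduction; the magnitude is configurable because only a significant
  rank-sum test, not an effect size, is reported).
- **Planted DMRs**: directions drawn first (loss of methylation in aged
  with probability 0.88), then domains sampled preferentially where the full
  ±20pp shift is realisable — methylation loss needs methylation to lose —
  with clipping (and the effective delta recorded) only when the feasible
  pool is exhausted.  gDMRs are age-invariant overrides: 19 maternal
  (90–98%), 3 paternal + 2 secondary (1–6%); X-CGI intervals are
  oocyte-like hypomethylated domains.
- **Non-CpG methylation**: CHH sites (400 bp mean spacing) with rate
  proportional to the local CpG rate (scale 0.06 → ~2% global), raised 25%
  in aged cells; proportionality realises the observed positive CpG/non-CpG
  coupling.
- **Expression**: NB2 counts with lognormal baseline means (median ~33
  counts — deep Smart-seq2-style libraries detecting most genes per cell),
  lognormal gene dispersions around 0.3, lognormal size factors (log-sd
  0.2).  Planted structure: 100 DE genes (|lfc| = 1, 53.6% down in aged),
  300 DV genes (dispersion ×3 in aged; ~15% of genes, matching the observed
  DV fraction), a 100-gene SN signature (×2 in SN cells; marker-panel genes
  get a baseline-mean floor of 5 counts, as curated panels are
  well-expressed by construction), 50 maternal-effect genes with a monotone
  trajectory trend, and 20 transcription-coupled genes whose gene-body
  methylation is an affine function (base 0.5, slope 0.15 per z-unit) of
  their own log expression in the same cell — these genes acquire concordant
  expression and methylation differences, emulating transcription-driven
  DMRs.  SN cells default to 12 young + 8 aged of 42/45; a young-like
  fraction of aged cells (default 16/45) lacks the DE/coupled effects; aged
  (non-young-like) cells silence a random ~6% of genes to emulate reduced
  transcript diversity.

**What passing tests show, and what they do not.**  The generator draws
calls from exactly the binomial model the DMR test assumes (plus small
Gaussian rate noise), expression from exactly the NB2 family the DV test
fits, and coupling as an exact affine relation plus sampling noise.
Calibration and recovery results therefore demonstrate correctness of the
implementations and adequacy of the procedures *under the assumed models*;
they do not establish robustness to real-data features the generator omits:
bisulfite conversion errors, mapping bias, batch effects, zero-inflation or
ambient contamination in expression, covariance between coverage and
methylation state, or domain-boundary misspecification.

## Problem sizes and numerics

Benchmark runs use a 8–20 Mb single-chromosome genome (≈450–1100 domains,
comfortably above the ≥200-domain regime the calibration property is stated
for), 30+32 methylomes and 42+45 transcriptomes, 2,000 genes, 100
combinations for DMR calling and 50 label permutations for the DV test —
sizes chosen so a full acceptance run completes in minutes on one core while
leaving every test in its asymptotic regime.  All randomness flows through
`numpy.random.Generator` seeds; identical config + seed gives byte-identical
outputs.  Ties in hierarchical clustering are made order-independent by
lexicographic pre-sorting; PCA signs follow the largest-loading convention;
BH uses the step-up form with enforced monotonicity; coverage-file percent
columns are validated against counts to half a percentage point.

## Known limitations

- The binomial GLM ignores pseudobulk-replicate overdispersion; with strong
  cell-to-cell variability the caller would need a quasi-binomial scale or
  beta-binomial model (switchable in principle, not implemented).
- The rank-sum DE stand-in is less powerful than NB-GLM machinery at these
  sample sizes (~75% recovery of |lfc| = 1 effects vs the ~80%+ a parametric
  test would reach); it is kept for robustness and transparency.
- Nearest-centroid DMR classification ignores coverage-dependent precision
  of per-cell DMR estimates.
- The generator plants domain-constant effects; DMRs narrower than a domain
  are not modelled, consistent with the domain-level test unit.
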