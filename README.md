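# oomt — oocyte methylome + transcriptome ageing analysis

`oomt` is a tested, reusable implementation of a joint single-cell
transcriptome (scRNA-seq) and methylome (scBS-seq) analysis of germinal-
vesicle oocytes from reproductively young vs. aged females — the setting in
which both data types are profiled from the *same* cells, methylation calls
are sparse and essentially binary (each CpG observed at most once per cell,
3–30% of sites covered), and the methylome is strongly bimodal:
hypermethylated domains (75–100%) over transcribed gene bodies alternating
with hypomethylated domains (0–25%), median sizes ≈ 20.9 / 24.9 kbp.

It is aimed at epigenomics researchers who need the analysis stages as
library functions or shell commands, and a synthetic benchmark with planted
ground truth to validate them against.

## What it implements

- **Methylome handling** (`oomt.methylome`) — Bismark-style coverage-file IO,
  the scBS-seq QC rules (mapping efficiency < 10%, < 500,000 CpGs, > 50%
  global methylation, and X-chromosome CpG-island methylation ≥ 10% as a
  granulosa-contamination flag), global / per-domain / gene-body / gDMR
  quantification, pseudobulk merging, and Wilcoxon group comparisons.
- **Consensus DMR calling** (`oomt.dmr_consensus`) — the centrepiece.  Cells
  are repeatedly partitioned into randomised pseudobulks of 10 per age
  group; each genomic domain is tested per combination with a weighted
  logistic regression (binomial GLM of methylation on age, observations
  weighted by call totals — solved in closed form and verified against an
  IRLS oracle), BH-adjusted within the combination; domains significant at
  q < 0.05 in ≥ 95% of 100 combinations are high-confidence DMRs:

  ```
  q_d < 0.05  in ≥ 95 of 100 randomised pseudobulk combinations
  logit Pr(methylated) = β₀ + β₁·aged,   weights = calls per pseudobulk
  ```

  plus domain-class enrichment and a nearest-centroid, missing-aware
  classifier that re-assigns cells to age groups from their DMR methylation.
- **Transcriptome analysis** (`oomt.transcriptome`) — median-of-ratios size
  factors, transcript diversity, NSN/SN chromatin-state classification from
  an SN-overexpression signature (Ward clustering, 2 clusters), Fisher's
  exact test of SN proportions, PCA with covariate associations,
  differential mean (rank-sum) and differential variability (per-gene NB
  maximum-likelihood dispersion, permutation-calibrated), within-group
  pairwise-distance heterogeneity, ordered-cluster trajectory regression
  with maternal-effect-gene enrichment, and young-like subgroup detection.
- **Integration** (`oomt.integration`) — per-cell gene-body methylation,
  expression–methylation Pearson coupling, DMR–gene overlap, and the
  cross-gene correlation between expression fold change and methylation
  difference.
- **Synthetic data** (`oomt.synthetic_data`) — a generator that emulates the
  study's statistical structure (bimodal landscape, sparse binary calls,
  NB expression with planted DE/DV/signature/coupled genes, young-like
  subgroup) and records every planted effect in a `GroundTruth` object.
  See `docs/methods.md` for the model and its limits.

## Worked example

```python
from oomt import SimulationConfig, simulate_paired_dataset
from oomt import call_consensus_dmrs, classify_chromatin_state
from oomt import gene_body_methylation, expr_meth_correlation
from oomt.transcriptome import log_normalize

# a small synthetic study: 30+32 methylomes, 42+45 transcriptomes,
# 50 planted DMRs and 20 expression-coupled genes
cfg = SimulationConfig(seed=1, n_true_dmrs=50, aged_shift_pp=0.0,
                       genome_length=8_000_000)
ds = simulate_paired_dataset(cfg)

dmrs, summary = call_consensus_dmrs(
    ds.methylomes, ds.domains, ds.cells("young"), ds.cells("aged"), seed=1
)
states = classify_chromatin_state(ds.counts, ds.truth.signature_genes)

logn = log_normalize(ds.counts)
meth = gene_body_methylation(ds.methylomes, ds.gene_bodies, min_calls=5)
gene = ds.truth.coupled_genes["gene"].iloc[0]
res = expr_meth_correlation(logn.loc[gene], meth.loc[gene], gene=gene)
```

This prints (via the obvious `print` calls):

```
consensus DMRs: 67 (85% lose methylation in aged); 50/50 planted recovered
chromatin states: 20 SN / 67 NSN
coupling at g01619: r = 0.74 (p = 1.3e-11, 60 cells)
```

All 50 planted DMRs are recovered.  Of the 17 additional calls, 16 are the
gene bodies of planted transcription-coupled genes — those genes differ in
expression between age groups, their gene-body methylation follows their
expression, so their domains are genuinely differentially methylated; the
caller finds them without being told.  The classifier recovers the 20
planted SN cells exactly, and the per-cell coupling at a planted gene is
strongly positive.

## Command line

The same stages are available as a CLI:

```bash
oomt simulate --config sim.yaml --out data/ --seed 1
oomt meth-qc   --samplesheet data/samplesheet.tsv --x-cgi data/x_cgi.bed --out qc.tsv
oomt dmr       --samplesheet data/samplesheet.tsv --domains data/domains.bed \
               --group-size 10 --n-comb 100 --q 0.05 --consensus 0.95 \
               --seed 1 --out-prefix results/run
oomt rna-classify --counts data/counts.tsv --signature signature.txt --out states.tsv
oomt rna-dv    --counts data/counts.tsv --annotations data/annotations.tsv --out dv.tsv
oomt couple    --counts data/counts.tsv --samplesheet data/samplesheet.tsv \
               --gene-bodies data/gene_bodies.bed --out coupling.tsv
```

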