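# macetools

Analysis toolkit for 3′-tag transcriptome sequencing (MACE — Massive
Analysis of cDNA Ends) applied to plant salt-stress time courses. In a
MACE library one sequenced fragment at the transcript 3′ end represents
one transcript copy, giving digital, strand-specific counts — but also
two analysis problems this package addresses head-on: tag pileups often
fall *beyond* the annotated gene end, and the experimental design
(pooled libraries, no biological replicates) rules out standard
dispersion-based differential-expression tests.

The package is aimed at researchers analyzing tag-based expression data
(typically in crops such as hexaploid wheat) who need the complete path
from aligned tags to candidate genes: quantification, responsive-gene
calling, functional enrichment, time-course clustering, integration with
QTL mapping, and qPCR validation statistics — with every stage testable
against synthetic data of known ground truth.

## What it computes

- **3′-end gene-model extension** (`genemodels`). With gene length *L*
  and downstream intergenic distance *D*: no extension when
  *D* ≤ 1000 bp; extension by ⌊0.4·*L*⌋ (capped at *D*) when
  1000 < *D* < 3*L*; extension by *L* when *D* ≥ 3*L*; always capped at
  the chromosome end. Novel transcribed loci are called from clusters of
  unassigned tags (single linkage, gap ≤ 200 bp, ≥ 10 tags).
- **Tag counting** (`tagcounts`). Positional deduplication (one tag per
  chrom/start/strand), sense-strand interval assignment with ambiguous
  tags dropped, CPM normalization, and the *transcriptomic background*
  filter: a gene is kept for a genotype iff its mean CPM ≥ 2.5, a
  threshold chosen so every library loses < 5% of its reads.
- **Replicate-free differential expression** (`diffexp`). Per gene with
  counts *x*ₛ, *x*꜀ and library totals *N*ₛ, *N*꜀, the expression rates
  get Gamma(x+1, rate = N) posteriors; the statistic is the posterior
  quantile of z = log₂(rateₛ/rate꜀) nearest zero at level c = 0.01
  (q₀.₀₁ if positive, q₀.₉₉ if negative, else 0). |value| > 1 calls a
  gene salt-responsive: its fold change exceeds two-fold with 99%
  posterior confidence.
- **GO enrichment** (`enrichment`). Hypergeometric upper tail restricted
  to the transcriptomic background; GE = n·K/N, fold = GA/GE, Bonferroni
  correction, significance at corrected p < 0.001.
- **Time-course profiles** (`profiles`). All (2c+1)^(T−1) integer model
  profiles starting at 0; max-Pearson-correlation assignment;
  permutation significance; LOESS trend curves; turning-point detection
  on smoothed physiological curves.
- **LD blocks and candidate genes** (`qtg`). r² between biallelic
  markers over inbred lines; a block is every same-chromosome marker
  with r² ≥ 0.8 against the focal QTL marker; salt-responsive genes
  overlapping the block interval are candidate quantitative trait genes.
- **RT-qPCR statistics** (`rtqpcr`). Dilution-curve amplification
  efficiency E = 10^(−1/slope) − 1; ΔΔCt relative quantification
  RQ = 2^(−ΔΔCt); one-sided t-tests against the asymmetric thresholds
  (mean > 2.0 ⇒ up, mean < 1.0 ⇒ down); Welch test between genotypes.
- **Synthetic data** (`synth`) and **orchestration** (`pipeline`, CLI).

## Worked example

```python
from macetools.diffexp import ContrastPlan, GfoldParams, classify_responsive, summarize_direction
from macetools.synth import SynthConfig, generate_annotation, generate_counts
from macetools.tagcounts import background_filter

config = SynthConfig(seed=42, genotypes=("synthA",))
models, truth = generate_annotation(config)
matrix, truth = generate_counts(models, config, truth)
filtered, _ = background_filter(matrix, {lib: "synthA" for lib in matrix.libraries})
plan = ContrastPlan.from_metadata(filtered.metadata, "synthA")
results = classify_responsive(filtered, plan, GfoldParams(seed=42))
print(summarize_direction(results))
```

prints

```
           up  down
timepoint
8min        5     5
15min       5     5
```

— the ten genes spiked at |log₂FC| = 3 (five up, five down, constant
across the two stress timepoints; 0 min is the shared control) are all
recovered, and no null gene is called. The `examples/` directory holds
one short script per capability (synthesis, extension, counting,
differential expression, enrichment, profiles, LD/QTG, qPCR), each
printing the numbers it computes and what they mean.

A thin CLI wraps synthesis and the end-to-end pipeline:

```bash
macetools synth --seed 42 --out synth/
macetools run --config pipeline.yaml
```

## Scope

The package consumes aligned tags (BED6/BAM/SAM) and count tables; read
trimming, quality control and alignment are upstream of it. It does not
perform QTL mapping itself (marker positions and focal markers are
inputs), transcript-isoform assembly, or GO-graph ancestor propagation.
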