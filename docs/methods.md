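# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical decisions taken where the
design was genuinely open.

## Gene-model 3′ extension

Tag-based 3′-end sequencing places one read per transcript copy at the
3′ terminus. Annotated gene ends are frequently upstream of the true
polyadenylation site, so tags would otherwise fall into "intergenic"
space and be lost. The conditional extension rule, per gene of length
*L* with downstream intergenic distance *D*:

| condition            | extension *E*    | regime    |
|----------------------|------------------|-----------|
| *D* ≤ `min_gap`      | 0                | none      |
| `min_gap` < *D* < 3*L* | min(⌊0.4·*L*⌋, *D*) | fractional / gap_capped |
| *D* ≥ 3*L*           | *L*              | full      |

with defaults `min_gap` = 1000 bp, fraction 0.40, full multiple 3. The
40% is measured in units of **gene length** (the full-extension clause
is also expressed in gene-size units, so the fractional clause is read
the same way). Two caps are our additions, since an uncapped rule can
produce overlapping models: *E* never exceeds *D* (`gap_capped`) and
never crosses the chromosome end (`chrom_end_capped`). The no-extension
behavior at *D* ≤ 1000 bp is the inferred complement of the two
extending cases. The downstream neighbor is the nearest gene on either
strand occupying any base beyond the 3′ end ("intergenic" is read
strand-agnostically); a neighbor overlapping the 3′ end gives *D* = 0.
Coordinates are 1-based inclusive externally (GFF3); the gap excludes
both genes (gap = next.start − gene.end − 1 on +).

Novel transcribed loci replace reference-guided assembly with a defined
rule: strand-specific single-linkage clustering of deduplicated,
unassigned tag starts with inter-tag gap ≤ 200 bp; clusters of ≥ 10 tags
become loci spanning [min start, max tag end]; loci overlapping an
extended model on the same strand are discarded. The defaults are ours
(the assembly tool this replaces has its own unstated heuristics) and
they recover all injected intergenic clusters at default synthetic
settings. Antisense tag noise near genes can also form clusters; these
are reported as loci on the opposite strand, which matches how
strand-specific assemblers behave on antisense signal.

## Tag processing and the transcriptomic background

Unique alignments are primary records with MAPQ ≥ 20 and no
secondary/supplementary flag (the uniqueness criterion is unstated
upstream; MAPQ 20 is the conventional cutoff). Deduplication keeps one
tag per (chrom, start, strand) — the highest-MAPQ record, ties broken by
smallest read id, so results are independent of input order. Whether
deduplication is applied is a per-experiment-arm option (the study
design deduplicated only one arm); the default is on. Counting assigns a
tag to a gene iff the tag interval overlaps the extended gene interval
by ≥ 1 bp on the sense strand; tags overlapping two or more qualifying
genes are ambiguous and dropped (no fractional assignment). A
conservation identity — input = non-unique + duplicates + assigned +
ambiguous + unassigned — is asserted on every run.

CPM is counts divided by the library's assigned total × 10⁶. The
background filter keeps a gene for a genotype iff its mean CPM across
that genotype's libraries is ≥ 2.5 (boundary inclusive; the source
protocol does not state the boundary). `find_background_threshold`
recovers the threshold from data: the largest value on a candidate grid
whose application removes < 5% of reads in every library. Decile tables
of log₁₀ CPM per library (zeros excluded) support the depth-homogeneity
diagnostic that motivates plain CPM normalization.

## The conservative posterior fold change

For one gene in an unreplicated pair, counts are modeled Poisson with a
uniform prior on the rate, giving independent Gamma(x+1, rate = N)
posteriors per library. The reported statistic is the posterior quantile
of z = log₂(rateₛ/rate꜀) nearest zero at level c (default 0.01): qᶜ if
qᶜ > 0, q¹⁻ᶜ if q¹⁻ᶜ < 0, else 0. It is a signed lower confidence bound
on the magnitude of the log fold change: |value| > 1 means the fold
change exceeds 2 with posterior probability 1 − c. Zero counts need no
special-casing (x = 0 gives a proper Gamma(1) posterior); two zero
counts give a symmetric posterior and value 0 by the interval rule.

Quantiles are evaluated by Monte Carlo (default 20,000 draws) with a
generator seeded from the analysis seed, chunked over genes for bounded
memory; results are deterministic for a fixed seed and stable to ±0.05
log₂ across seeds at that draw count. An exact evaluation via the Beta
transform (G₁/(G₁+G₂) ~ Beta(α₁, α₂), monotone in the ratio) is
implemented as `gfold_statistic_exact` and used as an independent
cross-check route in the tests; the Monte-Carlo path remains the
default implementation so the posterior mean comes from the same draws
and the evaluation generalizes to other functionals. Normalization uses
total assigned counts per library (CPM-consistent) rather than
size-factor schemes; `normalization="none"` disables it. Exact numeric
equality with any external implementation of the same statistic is not
claimed.

Responsive genes per stress timepoint are those with |value| > 1
against the timepoint's paired control (a single early control may
serve several stress points, encoded in the contrast plan built from
library metadata). Summary operations (up/down tallies, Venn region
counts, subgenome percentages) are exact set arithmetic.

## GO enrichment

Per term: N = background genes (annotated or not; restricting the
universe to annotated genes is a config option), K = background genes
with the term, n = selected genes, GA = selected genes with the term,
GE = n·K/N, fold = GA/GE, p = hypergeometric P(X ≥ GA), Bonferroni
m = number of terms with K ≥ 1 after background restriction (only
testable hypotheses are counted). Significant ⇔ corrected p < 10⁻³ ⇔
−log₁₀ > 3 (strict, so p = 10⁻³ exactly is not significant). Annotation
is flat term ids — no GO-graph ancestor propagation. Up- and
down-regulated sets are tested separately in the pipeline; at desk
scale the spiked-term check uses the pooled responsive set, which is
the set the generator enriches.

## Profile clustering, LOESS, turning points

Candidate profiles are all integer trajectories over T timepoints
starting at 0 with per-step change ≤ c — (2c+1)^(T−1) of them, all kept
as candidates (full STEM-style pipelines first reduce to m
representative profiles by profile-profile clustering; reporting
significant profiles directly is a deliberate simplification, flagged
here, since the reduction step's defaults are not part of the specified
procedure). Genes join the max-correlation profile (Pearson; ties to
the lowest index; zero-variance genes unassigned). Significance:
permute every gene's timepoint values independently, re-assign, and
report p = (1 + #{permutation count ≥ observed})/(n_perm + 1). The
permutation p is per-profile; no family-wise control is applied, and
simulation confirms the per-profile level is calibrated (mean fraction
of profiles with p < 0.05 under the null ≈ 0.03).

LOESS is tricube-weighted local linear regression (delegated to
statsmodels' lowess, robustness iterations off), evaluated at the input
times; degree-1 exactness on straight lines holds by construction.
Turning points are sign changes of the first difference of a smoothed
series, endpoints excluded; plateaus inherit the preceding slope sign
so only genuine direction reversals count.

## LD blocks and candidate genes

r² is the squared Pearson correlation of biallelic codes over lines
complete at both markers — for inbred (haplotype-equivalent) lines this
equals the classical (p_AB − p_A·p_B)²/(p_A q_A p_B q_B). Missing data
are handled by pairwise-complete deletion; markers monomorphic on the
complete subset have undefined r² (NaN, never coerced to 0) and are
excluded from blocks. A block is **all** qualifying markers on the
focal marker's chromosome, not only a contiguous run (the selection
criterion is r² alone); the interval spans member positions. Gene–block
intersection uses any-overlap (≥ 1 bp), the more inclusive reading;
both choices are configurable.

## RT-qPCR

Efficiency from a dilution series: E = 10^(−1/slope) − 1 with slope from
least squares of Ct on log₁₀ input (the standard dilution-curve
definition; E = 1 at slope −1/log₁₀2 ≈ −3.3219). ΔΔCt: technical
replicates averaged first, then per biological replicate
ΔCt = Ct_target − Ct_ref, ΔΔCt = ΔCt_stress − ΔCt_control,
RQ = 2^(−ΔΔCt). Regulation calls use one-sample one-sided t-tests on RQ
against the asymmetric printed thresholds — up iff mean ≤ 2.0 is
rejected, down iff mean ≥ 1.0 is rejected — which are disjoint
alternatives, so both cannot fire; zero-variance samples return "ns"
with a warning instead of a degenerate statistic. The two-genotype
comparison is a Welch (unequal-variance) two-tailed t-test; the t
distribution (not a normal approximation) is used throughout.

## The synthetic-data generator

The generator emulates the data-generating process the pipeline is
built for: a compact diploid-style genome (2 chromosomes × 100 genes by
default, lengths 200–3000 bp) with intergenic gaps drawn from a mixture
covering all three extension regimes; true 3′ ends beyond the
annotation for half the genes (offsets 60–400 bp, bounded by the local
gap); 3′-concentrated sense tags with 30% of an affected gene's tags in
the overflow zone, 25% exact positional duplicates, 2% antisense noise,
and 5 intergenic tag clusters as true novel loci (placed in reserved
extra-wide gaps sized so no legal extension can reach them); Poisson
counts (the design has no biological replicates per library, so no
between-replicate dispersion exists to model — a gamma-Poisson
`overdispersion` option exists, default off) over two genotypes × three
timepoints with the first timepoint the shared control, 2×10⁶ reads per
library, 5% of genes spiked at |log₂FC| = 3 with expression 20–200 CPM
(null genes 0.5–500 CPM, log-uniform); 50 GO terms of 40 genes with one
term drawing half its members from responsive genes; 100 inbred lines ×
60 markers in blocks of 10 with founder-copy mutation rate 0.002
(within-block r² ≈ 0.98, between-block ≈ 0); and Ct tables with 3
biological × 3 technical replicates, technical noise SD 0.15 cycles,
constructed so the ΔΔCt route recovers the configured RQ exactly at
zero noise.

Not emulated: read-level sequence/FASTQ simulation, sequencing error,
splice isoforms, polyploid homoeolog cross-mapping, batch effects, and
biological replicate variance. Passing tests therefore demonstrate the
correctness of the implemented rules and statistics under the stated
generative model, not robustness to those real-data complications.

The differential-expression recovery check runs at 10,000 genes (the
smallest size at which nominal and realized CPM agree closely and rate
estimates are tight); pipeline determinism and counting checks run at
the 200-gene default. All randomness flows from explicit seeds through
per-stage independent streams, making every output byte-reproducible.

## Known limitations

- The posterior fold-change statistic matches the cited definition, not
  any particular external implementation's numeric output.
- The novel-locus caller is a tag-cluster heuristic; it does not
  assemble transcript structure.
- Profile clustering reports significant model profiles directly rather
  than merged "clusters of clusters".
- Enrichment assumes flat annotations; ancestor-term inflation would
  require GO-graph input the pipeline does not consume.
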