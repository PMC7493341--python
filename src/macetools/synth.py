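"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a 3'-tag (MACE) salt-stress experiment on an
annotated genome: gene models with controlled intergenic gaps and true
3' ends beyond the annotation, strand-specific tag pileups at 3' termini
with PCR duplicates and antisense noise, intergenic tag clusters acting
as novel transcribed loci, Poisson count matrices with spiked responsive
genes of known log2 fold change, GO annotations with one enriched term,
block-structured genotype matrices for LD analysis, and Ct tables with
known relative expression.  Every random stream is a fixed function of
the seed, so identical configurations give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genemodels import GeneModel, GeneModelSet, write_gff3
from .qtg import GenotypeMatrix, MarkerMap
from .tagcounts import CountMatrix, TagAlignmentSet, write_bed

__all__ = [
    "SynthConfig",
    "TruthTable",
    "SizingError",
    "generate_annotation",
    "generate_tags",
    "generate_counts",
    "generate_go",
    "generate_genotypes",
    "generate_ct_table",
    "write_all",
]


class SizingError(ValueError):
    """Requested genes do not fit in the configured chromosome length."""


@dataclass(frozen=True)
class SynthConfig:
    """All tunable knobs of the synthetic experiment.

    Gaps are drawn from a mixture of uniform components
    ``(weight, lo, hi)`` covering the three extension regimes (below the
    1000-bp floor, the fractional zone, and beyond three gene lengths).
    The count model is Poisson per library (the experimental design has
    no biological replicates per library); ``overdispersion`` switches on
    a gamma-Poisson mixture with that squared coefficient of variation.
    """

    seed: int = 0
    # annotation
    n_chrom: int = 2
    genes_per_chrom: int = 100
    gene_len_range: tuple[int, int] = (200, 3000)
    gap_distribution: tuple[tuple[float, int, int], ...] = (
        (0.30, 100, 1000),
        (0.40, 1500, 6000),
        (0.30, 9500, 20000),
    )
    chrom_length: int | None = None  # None -> sized to fit; else capacity-checked
    utr_extension_frac: float = 0.5  # genes whose true 3' end lies beyond annotation
    utr_offset_range: tuple[int, int] = (60, 400)
    # tags
    n_tags: int = 30_000
    tag_length: int = 50
    tail_overflow_frac: float = 0.30
    duplicate_rate: float = 0.25
    antisense_noise: float = 0.02
    n_novel_loci: int = 5
    novel_locus_span: int = 500
    novel_locus_tags: int = 30
    # counts
    library_sizes: tuple[int, ...] = (2_000_000,)
    genotypes: tuple[str, ...] = ("synthA", "synthB")
    timepoints: tuple[str, ...] = ("0min", "8min", "15min")  # first = shared control
    de_frac: float = 0.05
    de_log2fc_range: tuple[float, float] = (3.0, 3.0)
    de_cpm_range: tuple[float, float] = (20.0, 200.0)
    null_cpm_range: tuple[float, float] = (0.5, 500.0)
    overdispersion: float = 0.0
    # GO
    n_go_terms: int = 50
    genes_per_term: int = 40
    go_spike_frac: float = 0.5  # spiked term's members drawn from responsive genes
    # genotypes / LD
    n_markers: int = 60
    n_lines: int = 100
    ld_block_len: int = 10  # markers per block
    marker_spacing: int = 25_000
    marker_mutation_rate: float = 0.002
    # qPCR
    qpcr_true_rq: tuple[tuple[str, float], ...] = (
        ("synthTarget1", 4.0),
        ("synthTarget2", 0.25),
    )
    qpcr_reference: str = "synthRef"
    qpcr_bio_reps: int = 3
    qpcr_tech_reps: int = 3
    ct_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        fracs = {
            "utr_extension_frac": self.utr_extension_frac,
            "tail_overflow_frac": self.tail_overflow_frac,
            "duplicate_rate": self.duplicate_rate,
            "antisense_noise": self.antisense_noise,
            "de_frac": self.de_frac,
            "go_spike_frac": self.go_spike_frac,
            "marker_mutation_rate": self.marker_mutation_rate,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.gene_len_range[0] < 200:
            raise ValueError("gene lengths must be >= 200 bp")
        if any(size <= 0 for size in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if abs(sum(w for w, _, _ in self.gap_distribution) - 1.0) > 1e-9:
            raise ValueError("gap mixture weights must sum to 1")
        if any(lo <= 0 or hi < lo for _, lo, hi in self.gap_distribution):
            raise ValueError("gap mixture components need 0 < lo <= hi")


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic files.

    Filled incrementally by the generators; every id it references exists
    in the corresponding emitted file.
    """

    gene_status: pd.DataFrame | None = None  # genes x stress timepoints, null/up/down
    gene_log2fc: pd.Series | None = None  # signed, 0 for null genes
    true_three_prime_end: pd.Series | None = None  # strand-aware coordinate
    novel_loci: pd.DataFrame | None = None  # chrom/start/end/strand
    enriched_term: str | None = None
    block_members: dict[str, list[str]] = field(default_factory=dict)
    qpcr_rq: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_status": (
                self.gene_status.to_dict(orient="index")
                if self.gene_status is not None
                else None
            ),
            "gene_log2fc": (
                self.gene_log2fc.to_dict() if self.gene_log2fc is not None else None
            ),
            "true_three_prime_end": (
                {k: int(v) for k, v in self.true_three_prime_end.items()}
                if self.true_three_prime_end is not None
                else None
            ),
            "novel_loci": (
                self.novel_loci.to_dict(orient="records")
                if self.novel_loci is not None
                else None
            ),
            "enriched_term": self.enriched_term,
            "block_members": self.block_members,
            "qpcr_rq": self.qpcr_rq,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng([config.seed, stream])


def _sample_gap(rng: np.random.Generator, config: SynthConfig) -> int:
    weights = np.array([w for w, _, _ in config.gap_distribution])
    idx = rng.choice(len(weights), p=weights / weights.sum())
    _, lo, hi = config.gap_distribution[idx]
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(config: SynthConfig) -> tuple[GeneModelSet, TruthTable]:
    """Non-overlapping sorted gene models with controlled intergenic gaps.

    A configured number of extra-wide gaps is reserved for novel-locus
    placement, sized so that no 3'-extension of a flanking gene can reach
    the locus.  For a random subset of genes the true 3' end is recorded
    beyond the annotated end by an offset bounded by the available gap.
    """
    rng = _rng(config, 1)
    max_len = config.gene_len_range[1]
    novel_gap = 3 * max_len + 2 * config.novel_locus_span + 4000
    # reserve gap slots (chrom index, gene index) for novel loci
    all_slots = [
        (ci, gi)
        for ci in range(config.n_chrom)
        for gi in range(config.genes_per_chrom - 1)
    ]
    if config.n_novel_loci > len(all_slots):
        raise SizingError("more novel loci requested than available intergenic gaps")
    slot_idx = rng.choice(len(all_slots), size=config.n_novel_loci, replace=False)
    novel_slots = {all_slots[i] for i in np.sort(slot_idx)}

    models: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    novel_records = []
    per_chrom_genes: dict[str, list[GeneModel]] = {}
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(1000, 5001))
        genes_here: list[GeneModel] = []
        for gi in range(config.genes_per_chrom):
            length = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(
                id=f"SYNG_{chrom}_{gi + 1:04d}",
                chrom=chrom,
                start=cursor,
                end=cursor + length - 1,
                strand=strand,
            )
            genes_here.append(gene)
            if (ci, gi) in novel_slots:
                gap = novel_gap
                lo = gene.end + 1 + max_len + 1000
                hi = gene.end + gap - max_len - 1000 - config.novel_locus_span
                locus_start = int(rng.integers(lo, hi + 1))
                novel_records.append(
                    {
                        "chrom": chrom,
                        "start": locus_start,
                        "end": locus_start + config.novel_locus_span - 1,
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
            else:
                gap = _sample_gap(rng, config)
            cursor = gene.end + gap + 1
        tail = _sample_gap(rng, config)
        length_needed = genes_here[-1].end + tail
        if config.chrom_length is not None:
            if length_needed > config.chrom_length:
                raise SizingError(
                    f"{chrom}: {config.genes_per_chrom} genes need {length_needed} bp "
                    f"but chrom_length is {config.chrom_length}"
                )
            chrom_lengths[chrom] = config.chrom_length
        else:
            chrom_lengths[chrom] = length_needed
        models.extend(genes_here)
        per_chrom_genes[chrom] = genes_here

    # true 3' ends at or beyond the annotated end, bounded by the local gap
    true_ends = {}
    for chrom, genes_here in per_chrom_genes.items():
        for i, gene in enumerate(genes_here):
            if gene.strand == "+":
                room = (
                    genes_here[i + 1].start - gene.end - 1
                    if i + 1 < len(genes_here)
                    else chrom_lengths[chrom] - gene.end
                )
                anchor = gene.end
            else:
                prev_end = genes_here[i - 1].end if i > 0 else 0
                room = gene.start - prev_end - 1
                anchor = gene.start
            offset = 0
            if rng.random() < config.utr_extension_frac:
                lo, hi = config.utr_offset_range
                offset = int(rng.integers(lo, hi + 1))
                offset = min(offset, max(room - 1, 0))
                if offset < config.tag_length:  # too cramped for an overflow tag
                    offset = 0
            true_ends[gene.id] = anchor + offset if gene.strand == "+" else anchor - offset

    gene_set = GeneModelSet(models=models, chrom_lengths=chrom_lengths)
    truth = TruthTable(
        true_three_prime_end=pd.Series(true_ends).sort_index(),
        novel_loci=pd.DataFrame(
            novel_records, columns=["chrom", "start", "end", "strand"]
        ),
    )
    return gene_set, truth


# ---------------------------------------------------------------------------
# Tags


def generate_tags(
    models: GeneModelSet, truth: TruthTable, config: SynthConfig
) -> TagAlignmentSet:
    """Strand-specific 3'-tag alignments with duplicates and noise.

    Gene-derived tags concentrate in a 3' window; for genes with a true
    end beyond the annotation, ``tail_overflow_frac`` of their tags fall
    between the annotated and the true end.  ``duplicate_rate`` of the
    emitted tags are exact positional copies, ``antisense_noise`` sit on
    the opposite strand, and each true novel locus receives its own tag
    cluster.
    """
    if truth.true_three_prime_end is None:
        raise ValueError("truth table lacks true 3' ends; run generate_annotation first")
    rng = _rng(config, 2)
    n_novel_tags = (
        len(truth.novel_loci) * config.novel_locus_tags
        if truth.novel_loci is not None
        else 0
    )
    n_dup = int(rng.binomial(config.n_tags, config.duplicate_rate))
    n_base = max(config.n_tags - n_dup - n_novel_tags, 0)
    gene_list = list(models)
    alloc = rng.multinomial(n_base, np.full(len(gene_list), 1.0 / len(gene_list)))
    tlen = config.tag_length
    rows: list[tuple] = []

    def emit(chrom: str, start: int, strand: str) -> None:
        rows.append((f"t{len(rows) + 1:07d}", chrom, int(start), tlen, strand, 60))

    for gene, n_g in zip(gene_list, alloc):
        if n_g == 0:
            continue
        true_end = int(truth.true_three_prime_end[gene.id])
        window = max(tlen, min(gene.length, 300))
        has_overflow = (gene.strand == "+" and true_end > gene.end) or (
            gene.strand == "-" and true_end < gene.start
        )
        n_over = rng.binomial(n_g, config.tail_overflow_frac) if has_overflow else 0
        for i in range(n_g):
            if i < n_over:
                if gene.strand == "+":
                    start = rng.integers(gene.end + 1, true_end - tlen + 2)
                else:
                    start = rng.integers(true_end, gene.start - tlen + 1)
            else:
                if gene.strand == "+":
                    start = rng.integers(gene.end - window + 1, gene.end - tlen + 2)
                else:
                    start = rng.integers(gene.start, gene.start + window - tlen + 1)
            strand = gene.strand
            if config.antisense_noise > 0 and rng.random() < config.antisense_noise:
                strand = "-" if strand == "+" else "+"
            emit(gene.chrom, start, strand)

    if truth.novel_loci is not None:
        for locus in truth.novel_loci.itertuples(index=False):
            for _ in range(config.novel_locus_tags):
                start = rng.integers(locus.start, locus.end - tlen + 2)
                emit(locus.chrom, start, locus.strand)

    # exact positional copies of already-emitted tags
    if n_dup > 0 and rows:
        source = rng.integers(0, len(rows), size=n_dup)
        for idx in source:
            _, chrom, start, length, strand, mapq = rows[idx]
            emit(chrom, start, strand)

    frame = pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "length", "strand", "mapq"]
    )
    return TagAlignmentSet(frame)


# ---------------------------------------------------------------------------
# Counts


def generate_counts(
    models: GeneModelSet, config: SynthConfig, truth: TruthTable | None = None
) -> tuple[CountMatrix, TruthTable]:
    """Poisson count matrix with spiked responsive genes of known effect.

    One library per genotype x timepoint; the first timepoint is the
    shared control.  Null genes share a per-gene rate across libraries
    (scaled by library size); responsive genes have their rate multiplied
    by 2^log2fc in every stress library.
    """
    rng = _rng(config, 3)
    genes = [g.id for g in models]
    n = len(genes)
    de_mask = rng.random(n) < config.de_frac
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lo, hi = config.de_log2fc_range
    magnitude = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    log2fc = np.where(de_mask, signs * magnitude, 0.0)

    def log_uniform(rng, lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    base_cpm = np.where(
        de_mask,
        log_uniform(rng, *config.de_cpm_range, n),
        log_uniform(rng, *config.null_cpm_range, n),
    )

    libraries = []
    meta_rows = []
    counts = {}
    i_lib = 0
    for genotype in config.genotypes:
        for tp in config.timepoints:
            lib = f"{genotype}_{tp}"
            size = config.library_sizes[i_lib % len(config.library_sizes)]
            condition = "control" if tp == config.timepoints[0] else "stress"
            rate = base_cpm / 1e6 * size
            if condition == "stress":
                rate = rate * np.power(2.0, log2fc)
            if config.overdispersion > 0:
                shape = 1.0 / config.overdispersion
                rate = rate * rng.gamma(shape, 1.0 / shape, size=n)
            counts[lib] = rng.poisson(rate)
            libraries.append(lib)
            meta_rows.append(
                {"library": lib, "genotype": genotype, "condition": condition, "timepoint": tp}
            )
            i_lib += 1

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id")),
        metadata=pd.DataFrame(meta_rows).set_index("library"),
        state="raw",
    )
    stress_tps = list(config.timepoints[1:])
    status = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "null"))
    if truth is None:
        truth = TruthTable()
    truth.gene_status = pd.DataFrame(
        {tp: status for tp in stress_tps}, index=pd.Index(genes, name="gene_id")
    )
    truth.gene_log2fc = pd.Series(log2fc, index=genes, name="log2fc")
    return matrix, truth


# ---------------------------------------------------------------------------
# GO annotation


def generate_go(
    models: GeneModelSet, truth: TruthTable, config: SynthConfig
):
    """Flat gene->term annotation with one term spiked into responsive genes."""
    from .enrichment import GoAnnotation

    if truth.gene_status is None:
        raise ValueError("truth table lacks gene status; run generate_counts first")
    rng = _rng(config, 4)
    genes = np.array(truth.gene_status.index)
    responsive = np.array(
        truth.gene_status.index[(truth.gene_status != "null").any(axis=1)]
    )
    non_responsive = np.array(
        truth.gene_status.index[(truth.gene_status == "null").all(axis=1)]
    )
    mapping: dict[str, set[str]] = {}
    spiked = "GO:SYN0001"
    k = min(config.genes_per_term, len(genes))
    n_spike = min(int(round(config.go_spike_frac * k)), len(responsive))
    members = list(rng.choice(responsive, size=n_spike, replace=False)) + list(
        rng.choice(non_responsive, size=k - n_spike, replace=False)
    )
    for gene in members:
        mapping.setdefault(str(gene), set()).add(spiked)
    for t in range(2, config.n_go_terms + 1):
        term = f"GO:SYN{t:04d}"
        for gene in rng.choice(genes, size=k, replace=False):
            mapping.setdefault(str(gene), set()).add(term)
    truth.enriched_term = spiked
    return GoAnnotation(mapping), truth


# ---------------------------------------------------------------------------
# Genotypes


def generate_genotypes(
    config: SynthConfig, truth: TruthTable | None = None
) -> tuple[MarkerMap, GenotypeMatrix, TruthTable]:
    """Haplotype matrix of inbred lines with block-structured LD.

    Markers are grouped into consecutive blocks of ``ld_block_len``; all
    markers of a block copy a per-line founder allele, flipped with the
    configured mutation rate, giving r^2 ~ 1 within blocks and ~ 0
    between.  Blocks alternate between chromosomes; positions are evenly
    spaced.
    """
    rng = _rng(config, 5)
    if truth is None:
        truth = TruthTable()
    positions: dict[str, tuple[str, int]] = {}
    geno_rows: dict[str, np.ndarray] = {}
    per_chrom_counter = {f"chr{c + 1}": 0 for c in range(config.n_chrom)}
    n_blocks = (config.n_markers + config.ld_block_len - 1) // config.ld_block_len
    marker_idx = 0
    for b in range(n_blocks):
        chrom = f"chr{(b % config.n_chrom) + 1}"
        founder = rng.integers(0, 2, size=config.n_lines).astype(float)
        block_id = f"block{b + 1:02d}"
        members = []
        for _ in range(config.ld_block_len):
            if marker_idx >= config.n_markers:
                break
            marker_idx += 1
            marker = f"M{marker_idx:04d}"
            per_chrom_counter[chrom] += 1
            positions[marker] = (chrom, per_chrom_counter[chrom] * config.marker_spacing)
            flips = rng.random(config.n_lines) < config.marker_mutation_rate
            geno_rows[marker] = np.where(flips, 1.0 - founder, founder)
            members.append(marker)
        truth.block_members[block_id] = members
    marker_map = MarkerMap(positions)
    frame = pd.DataFrame.from_dict(
        geno_rows,
        orient="index",
        columns=[f"line{i + 1:03d}" for i in range(config.n_lines)],
    )
    frame.index.name = "marker"
    return marker_map, GenotypeMatrix(frame), truth


# ---------------------------------------------------------------------------
# Ct tables


def generate_ct_table(
    config: SynthConfig, truth: TruthTable | None = None
) -> tuple[pd.DataFrame, TruthTable]:
    """Technical-replicate Ct rows consistent with the configured true RQ.

    The reference gene sits at Ct 20 in every condition; each target's
    control Ct is 24 and its stress Ct is shifted by -log2(RQ), so the
    delta-delta-Ct route recovers RQ exactly when ``ct_noise_sd`` is 0.
    """
    rng = _rng(config, 6)
    if truth is None:
        truth = TruthTable()
    tp = config.timepoints[1] if len(config.timepoints) > 1 else config.timepoints[0]
    rows = []

    def add_rows(gene: str, role: str, condition: str, base_ct: float) -> None:
        for rep in range(1, config.qpcr_bio_reps + 1):
            for _ in range(config.qpcr_tech_reps):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "bio_rep": f"rep{rep}",
                        "gene": gene,
                        "role": role,
                        "condition": condition,
                        "timepoint": tp,
                        "ct": base_ct + noise,
                    }
                )

    for condition in ("control", "stress"):
        add_rows(config.qpcr_reference, "reference", condition, 20.0)
    for gene, rq in config.qpcr_true_rq:
        add_rows(gene, "target", "control", 24.0)
        add_rows(gene, "target", "stress", 24.0 - float(np.log2(rq)))
        truth.qpcr_rq[gene] = float(rq)
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# File emission


def write_all(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input and write it under ``outdir``.

    Emits annotation.gff3, tags.bed, counts.tsv, libraries.tsv, go.tsv,
    genotypes.tsv, ct.csv, truth.json and config.json; returns the path
    map.  Identical configurations produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, truth = generate_annotation(config)
    tags = generate_tags(models, truth, config)
    matrix, truth = generate_counts(models, config, truth)
    annot, truth = generate_go(models, truth, config)
    marker_map, genotype_matrix, truth = generate_genotypes(config, truth)
    ct_table, truth = generate_ct_table(config, truth)

    paths = {name: outdir / fname for name, fname in [
        ("annotation", "annotation.gff3"),
        ("tags", "tags.bed"),
        ("counts", "counts.tsv"),
        ("libraries", "libraries.tsv"),
        ("go", "go.tsv"),
        ("genotypes", "genotypes.tsv"),
        ("ct", "ct.csv"),
        ("truth", "truth.json"),
        ("config", "config.json"),
    ]}
    write_gff3(models, paths["annotation"])
    write_bed(tags, paths["tags"])
    matrix.counts.to_csv(paths["counts"], sep="\t")
    matrix.metadata.to_csv(paths["libraries"], sep="\t")
    pairs = [
        (gene, term)
        for gene, terms in sorted(annot.gene_terms.items())
        for term in sorted(terms)
    ]
    pd.DataFrame(pairs).to_csv(paths["go"], sep="\t", header=False, index=False)
    geno_out = genotype_matrix.frame.copy()
    geno_out.insert(0, "chrom", [marker_map.chrom_of(m) for m in geno_out.index])
    geno_out.insert(1, "pos", [marker_map.pos_of(m) for m in geno_out.index])
    geno_out.to_csv(paths["genotypes"], sep="\t")
    ct_table.to_csv(paths["ct"], index=False)
    truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return paths
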