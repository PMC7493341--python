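"""Strand-specific 3'-tag deduplication, counting and background filtering.

Each sequenced tag represents one transcript 3' end, so expression is the
number of distinct tag positions assigned to a gene.  The processing chain
is: drop non-unique alignments (multi-hit flag or low MAPQ), collapse PCR
duplicates to one tag per (chrom, start, strand), assign each tag to the
single extended gene model it overlaps on the sense strand, normalize to
counts per million (CPM), and restrict downstream analyses to a
"transcriptomic background" of genes whose mean CPM within a genotype
clears a threshold chosen to discard <5% of reads in every library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genemodels import GeneModelSet

__all__ = [
    "TagAlignmentSet",
    "AssignmentSummary",
    "CountMatrix",
    "read_alignments",
    "deduplicate",
    "count_tags",
    "build_count_matrix",
    "cpm",
    "background_filter",
    "find_background_threshold",
    "expression_density_summary",
]

_TAG_COLUMNS = ["read_id", "chrom", "start", "length", "strand", "mapq"]


@dataclass
class TagAlignmentSet:
    """Aligned 3'-tags as a DataFrame (read_id, chrom, start, length, strand, mapq).

    ``start`` is 1-based; a tag occupies [start, start + length - 1].
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TAG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"tag table missing columns: {missing}")
        self.frame = self.frame[_TAG_COLUMNS].reset_index(drop=True)
        if len(self.frame) and (self.frame["start"] < 1).any():
            raise ValueError("tag start coordinates must be >= 1")
        if len(self.frame) and (self.frame["mapq"] < 0).any():
            raise ValueError("mapq must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AssignmentSummary:
    """Per-library read bookkeeping; conserves the input read count."""

    n_input: int = 0
    n_nonunique_removed: int = 0
    n_duplicates_removed: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0

    def check_conservation(self) -> None:
        total = (
            self.n_nonunique_removed
            + self.n_duplicates_removed
            + self.n_assigned
            + self.n_ambiguous
            + self.n_unassigned
        )
        if total != self.n_input:
            raise AssertionError(
                f"read conservation violated: input={self.n_input}, accounted={total}"
            )


@dataclass
class CountMatrix:
    """Genes x libraries counts with library metadata and normalization state.

    ``counts`` is a DataFrame indexed by gene id with one column per
    library.  ``metadata`` is indexed by library id with columns
    genotype / condition / timepoint / total (total assigned raw reads).
    ``state`` is ``"raw"`` (non-negative integers) or ``"cpm"``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "cpm"):
            raise ValueError(f"unknown state {self.state!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")
        for col in ("genotype", "condition", "timepoint"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if "total" not in self.metadata.columns:
            self.metadata = self.metadata.assign(total=self.counts.sum(axis=0))

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def genotype_of(self, library: str) -> str:
        return str(self.metadata.loc[library, "genotype"])


# ---------------------------------------------------------------------------
# Alignment input


def read_alignments(
    path: str | Path, min_mapq: int = 20
) -> tuple[TagAlignmentSet, AssignmentSummary]:
    """Read tag alignments from BAM/SAM or BED6.

    Reads flagged as secondary/supplementary or with MAPQ below
    ``min_mapq`` are excluded from the returned set but tallied in the
    summary (``n_nonunique_removed``).  BED scores are interpreted as MAPQ.
    """
    path = Path(path)
    if path.suffix.lower() in (".bam", ".sam"):
        rows, n_removed = _read_bam(path, min_mapq)
    else:
        rows, n_removed = _read_bed(path, min_mapq)
    frame = pd.DataFrame(rows, columns=_TAG_COLUMNS)
    summary = AssignmentSummary(
        n_input=len(frame) + n_removed, n_nonunique_removed=n_removed
    )
    return TagAlignmentSet(frame), summary


def _read_bam(path: Path, min_mapq: int):
    import pysam

    rows = []
    n_removed = 0
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                n_removed += 1
                continue
            if rec.is_secondary or rec.is_supplementary or rec.mapping_quality < min_mapq:
                n_removed += 1
                continue
            rows.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start + 1,  # SAM is 1-based already via pysam 0-based
                    rec.query_length or (rec.reference_end - rec.reference_start),
                    "-" if rec.is_reverse else "+",
                    rec.mapping_quality,
                )
            )
    return rows, n_removed


def _read_bed(path: Path, min_mapq: int):
    rows = []
    n_removed = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED6 line has {len(parts)} fields: {line!r}")
            chrom, start0, end, name, score, strand = parts[:6]
            mapq = int(float(score))
            if mapq < min_mapq:
                n_removed += 1
                continue
            start = int(start0) + 1  # BED half-open 0-based -> 1-based inclusive
            rows.append((name, chrom, start, int(end) - int(start0), strand, mapq))
    return rows, n_removed


def write_bed(tags: TagAlignmentSet, path: str | Path) -> None:
    """Write tags as BED6 (0-based half-open; score column carries MAPQ)."""
    df = tags.frame
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"] - 1,
            "end": df["start"] - 1 + df["length"],
            "name": df["read_id"],
            "score": df["mapq"],
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Deduplication


def deduplicate(tags: TagAlignmentSet) -> tuple[TagAlignmentSet, int]:
    """Collapse PCR duplicates: one tag per (chrom, start, strand).

    The keeper is the highest-MAPQ tag, ties broken by lexicographically
    smallest read id, so the result is deterministic regardless of input
    order.  Returns the deduplicated set and the number removed.
    """
    df = tags.frame
    if df.empty:
        return TagAlignmentSet(df.copy()), 0
    ordered = df.sort_values(
        ["chrom", "start", "strand", "mapq", "read_id"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    kept = ordered.drop_duplicates(subset=["chrom", "start", "strand"], keep="first")
    kept = kept.sort_values(["chrom", "start", "strand", "read_id"]).reset_index(drop=True)
    return TagAlignmentSet(kept), len(df) - len(kept)


# ---------------------------------------------------------------------------
# Counting


def count_tags(
    tags: TagAlignmentSet,
    models: GeneModelSet,
    stranded: str = "sense",
    summary: AssignmentSummary | None = None,
) -> tuple[pd.Series, AssignmentSummary, TagAlignmentSet]:
    """Assign tags to gene models and count per gene.

    A tag is assigned to a gene iff its interval overlaps the gene's
    (extended) interval by at least 1 bp and the strand matches (``sense``)
    or is opposite (``antisense``).  Tags hitting two or more qualifying
    genes are ambiguous and dropped.  Returns (counts indexed by gene id,
    updated summary, the unassigned tag subset) — the latter feeds the
    novel-locus caller.
    """
    if stranded not in ("sense", "antisense"):
        raise ValueError("stranded must be 'sense' or 'antisense'")
    if summary is None:
        summary = AssignmentSummary(n_input=len(tags))
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in models:
        # intervaltree uses half-open intervals; gene occupies [start, end]
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
            g.start, g.end + 1, g.id
        )
    counts = {g.id: 0 for g in models}
    known_chroms = {g.chrom for g in models}
    df = tags.frame
    unassigned_rows = []
    n_assigned = n_ambiguous = n_unassigned = 0
    flip = {"+": "-", "-": "+"}
    for row in df.itertuples(index=False):
        if row.chrom not in known_chroms:
            n_unassigned += 1
            unassigned_rows.append(row)
            continue
        strand = row.strand if stranded == "sense" else flip[row.strand]
        tree = trees.get((row.chrom, strand))
        hits = tree.overlap(row.start, row.start + row.length) if tree else set()
        if len(hits) == 1:
            counts[next(iter(hits)).data] += 1
            n_assigned += 1
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_unassigned += 1
            unassigned_rows.append(row)
    summary.n_assigned = n_assigned
    summary.n_ambiguous = n_ambiguous
    summary.n_unassigned = n_unassigned
    summary.check_conservation()
    gene_ids = [g.id for g in models]
    series = pd.Series([counts[g] for g in gene_ids], index=pd.Index(gene_ids, name="gene_id"))
    unassigned = TagAlignmentSet(pd.DataFrame(unassigned_rows, columns=_TAG_COLUMNS))
    return series, summary, unassigned


def build_count_matrix(
    per_library_counts: Mapping[str, pd.Series], metadata: pd.DataFrame
) -> CountMatrix:
    """Assemble per-library count vectors into a raw CountMatrix."""
    counts = pd.DataFrame(dict(per_library_counts)).fillna(0).astype(int)
    counts.index.name = "gene_id"
    return CountMatrix(counts=counts, metadata=metadata.copy(), state="raw")


# ---------------------------------------------------------------------------
# Normalization and background filtering


def cpm(matrix: CountMatrix) -> CountMatrix:
    """Normalize raw counts to counts per million assigned reads."""
    if matrix.state != "raw":
        raise ValueError("cpm() requires a raw matrix")
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"zero-total libraries: {empty}")
    norm = matrix.counts.div(totals, axis=1) * 1e6
    meta = matrix.metadata.copy()
    meta["total"] = totals
    return CountMatrix(counts=norm, metadata=meta, state="cpm")


def _retained_genes(
    matrix: CountMatrix, grouping: Mapping[str, str], threshold: float
) -> dict[str, pd.Index]:
    """Per-genotype gene sets whose mean CPM >= threshold (>= is inclusive)."""
    cpm_mat = cpm(matrix) if matrix.state == "raw" else matrix
    for lib in cpm_mat.libraries:
        if lib not in grouping:
            raise ValueError(f"library {lib!r} has no genotype mapping")
    retained = {}
    genotypes = sorted(set(grouping[lib] for lib in cpm_mat.libraries))
    for geno in genotypes:
        libs = [lib for lib in cpm_mat.libraries if grouping[lib] == geno]
        mean_cpm = cpm_mat.counts[libs].mean(axis=1)
        retained[geno] = cpm_mat.counts.index[mean_cpm >= threshold]
    return retained


def background_filter(
    matrix: CountMatrix,
    grouping: Mapping[str, str],
    threshold: float = 2.5,
) -> tuple[CountMatrix, pd.Series]:
    """Drop genes below the mean-CPM background threshold per genotype.

    A gene is retained for a genotype iff its mean CPM across that
    genotype's libraries is >= ``threshold``; it stays in the returned
    matrix if any genotype retains it (counts in libraries of genotypes
    that do not retain it are zeroed).  Returns the filtered raw matrix
    and the per-library fraction of raw reads removed.
    """
    if matrix.state != "raw":
        raise ValueError("background_filter() operates on the raw matrix")
    retained = _retained_genes(matrix, grouping, threshold)
    keep_any = pd.Index(sorted(set().union(*[set(v) for v in retained.values()])))
    filtered = matrix.counts.loc[matrix.counts.index.intersection(keep_any)].copy()
    filtered = filtered.reindex(sorted(filtered.index))
    loss = {}
    for lib in matrix.libraries:
        geno = grouping[lib]
        kept = matrix.counts.loc[matrix.counts.index.isin(retained[geno]), lib].sum()
        total = matrix.counts[lib].sum()
        loss[lib] = 1.0 - kept / total if total > 0 else 0.0
        # zero out genes outside this genotype's background
        outside = filtered.index.difference(retained[geno])
        filtered.loc[outside, lib] = 0
    meta = matrix.metadata.copy()
    out = CountMatrix(counts=filtered, metadata=meta, state="raw")
    return out, pd.Series(loss, name="read_loss_fraction")


def find_background_threshold(
    matrix: CountMatrix,
    grouping: Mapping[str, str],
    max_loss: float = 0.05,
    candidates: tuple[float, ...] = (0.5, 1.0, 2.5, 5.0, 10.0),
) -> float:
    """Largest candidate CPM threshold losing < ``max_loss`` of reads in every library."""
    if not candidates:
        raise ValueError("candidate grid must be non-empty")
    best = None
    for cand in sorted(candidates):
        _, loss = background_filter(matrix, grouping, threshold=cand)
        if (loss < max_loss).all():
            best = cand
    if best is None:
        raise ValueError(
            f"no candidate threshold keeps read loss below {max_loss:.0%} in every library"
        )
    return best


def expression_density_summary(matrix: CountMatrix, pseudo: float = 0.0) -> pd.DataFrame:
    """Deciles of log10 CPM per library, for depth-homogeneity diagnostics.

    Genes with zero CPM in a library are excluded from that library's
    distribution (log10 undefined) unless ``pseudo`` > 0 is added first.
    """
    cpm_mat = cpm(matrix) if matrix.state == "raw" else matrix
    probs = np.arange(0.1, 1.0, 0.1)
    rows = {}
    for lib in cpm_mat.libraries:
        vals = cpm_mat.counts[lib].to_numpy(dtype=float) + pseudo
        vals = vals[vals > 0]
        rows[lib] = np.quantile(np.log10(vals), probs) if len(vals) else np.full(9, np.nan)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"d{int(p * 100)}" for p in probs]
    )
    out.index.name = "library"
    return out
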