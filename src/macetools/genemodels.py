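"""Gene-model handling for 3'-tag quantification.

Tag-based 3'-end sequencing concentrates reads at transcript 3' termini,
which frequently lie downstream of the annotated gene end.  To recover
those reads, gene models are conditionally extended on their 3' side as a
function of the gene length ``L`` and the downstream intergenic distance
``D``:

* ``D <= min_gap``                      -> no extension,
* ``min_gap < D < full_multiple * L``   -> extend by ``floor(frac * L)``,
  capped at ``D`` so the extension never reaches the next gene,
* ``D >= full_multiple * L``            -> extend by the full gene length.

Extensions are additionally capped at the chromosome end.  The module also
calls novel transcribed loci from clusters of tags that no (extended) gene
model absorbed, replacing reference-guided transcript assembly with a
deterministic strand-specific single-linkage clustering rule.

Coordinates are 1-based inclusive externally (GFF3 convention); the
downstream gap between two genes is exclusive of both
(``gap = next.start - gene.end - 1`` on the plus strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from gffutils.feature import feature_from_line

__all__ = [
    "GeneModel",
    "GeneModelSet",
    "ExtensionParams",
    "ExtensionResult",
    "GffParseError",
    "read_gff3",
    "write_gff3",
    "downstream_gap",
    "extension_amount",
    "extend_three_prime",
    "call_novel_loci",
]

CONFIDENCE_CLASSES = ("HC", "LC", "novel")


class GffParseError(ValueError):
    """Raised for malformed GFF3 input; carries the offending line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 1-based inclusive interval with strand and confidence."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    confidence: str = "HC"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.id}: end < start ({self.end} < {self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.confidence not in CONFIDENCE_CLASSES:
            raise ValueError(f"{self.id}: unknown confidence {self.confidence!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def three_prime_end(self) -> int:
        """Coordinate of the 3'-most base (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneModelSet:
    """Coordinate-sorted collection of gene models with chromosome lengths."""

    models: list[GeneModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.models = sorted(self.models, key=lambda g: (g.chrom, g.start, g.end, g.id))
        ids = [g.id for g in self.models]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        self._by_id = {g.id: g for g in self.models}

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def by_chrom(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.models if g.chrom == chrom]


@dataclass(frozen=True)
class ExtensionParams:
    """Knobs of the conditional 3'-extension rule (bp and dimensionless)."""

    min_gap: int = 1000
    frac: float = 0.40
    full_multiple: float = 3.0


@dataclass(frozen=True)
class ExtensionResult:
    """Per-gene record of the extension decision.

    ``L`` is the gene length, ``D`` the downstream intergenic gap
    (``math.inf`` allowed as a sentinel), ``E`` the applied extension.
    """

    gene_id: str
    L: int
    D: float
    E: int
    regime: str  # none | fractional | full | gap_capped | chrom_end_capped

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("extension must be non-negative")
        if math.isfinite(self.D) and self.E > self.D:
            raise ValueError("extension cannot exceed the downstream gap")


# ---------------------------------------------------------------------------
# GFF3 I/O


def read_gff3(path: str | Path) -> GeneModelSet:
    """Read gene-level features from a GFF3 file.

    Only ``gene`` features are modeled.  Chromosome lengths are taken from
    ``##sequence-region`` pragmas when present.  Malformed lines raise
    :class:`GffParseError` with the 1-based line number.
    """
    models: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GffParseError(f"line {lineno}: cannot parse GFF3 line: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            gene_id = feat.attributes.get("ID", [f"gene_{lineno}"])[0]
            confidence = feat.attributes.get("confidence", ["HC"])[0]
            try:
                models.append(
                    GeneModel(
                        id=gene_id,
                        chrom=feat.seqid,
                        start=feat.start,
                        end=feat.end,
                        strand=feat.strand,
                        confidence=confidence,
                    )
                )
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: {exc}") from exc
    return GeneModelSet(models=models, chrom_lengths=chrom_lengths)


def write_gff3(gene_set: GeneModelSet, path: str | Path) -> None:
    """Write a GeneModelSet as GFF3 (gene features, confidence attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(gene_set.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {gene_set.chrom_lengths[chrom]}\n")
        for g in gene_set:
            attrs = f"ID={g.id};confidence={g.confidence}"
            fh.write(
                f"{g.chrom}\tmacetools\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Downstream gap and extension rule


class _ChromIndex:
    """Sorted per-chromosome arrays for O(log n) downstream-gap queries."""

    def __init__(self, genes: list[GeneModel]):
        import numpy as np

        by_end = sorted(genes, key=lambda g: g.end)
        self.ends_sorted = np.array([g.end for g in by_end], dtype=np.int64)
        # suffix minimum of starts over genes ordered by end
        starts = np.array([g.start for g in by_end], dtype=np.int64)
        self.suffmin_start = np.minimum.accumulate(starts[::-1])[::-1]
        by_start = sorted(genes, key=lambda g: g.start)
        self.starts_sorted = np.array([g.start for g in by_start], dtype=np.int64)
        ends = np.array([g.end for g in by_start], dtype=np.int64)
        self.prefmax_end = np.maximum.accumulate(ends)

    def gap_plus(self, gene_end: int) -> float | None:
        """Gap to the nearest gene occupying any base > gene_end, else None."""
        import numpy as np

        idx = int(np.searchsorted(self.ends_sorted, gene_end, side="right"))
        if idx >= len(self.ends_sorted):
            return None
        return float(max(0, int(self.suffmin_start[idx]) - gene_end - 1))

    def gap_minus(self, gene_start: int) -> float | None:
        import numpy as np

        idx = int(np.searchsorted(self.starts_sorted, gene_start, side="left"))
        if idx == 0:
            return None
        return float(max(0, gene_start - int(self.prefmax_end[idx - 1]) - 1))


def _gap_from_index(gene: GeneModel, index: _ChromIndex, chrom_length: int | None) -> tuple[float, bool]:
    """(gap, gap_is_chrom_end) for one gene using a prebuilt index.

    The index may include the gene itself: a gene never blocks its own
    downstream region because the neighbor test is strict (end > gene.end
    on '+', start < gene.start on '-').
    """
    if gene.strand == "+":
        gap = index.gap_plus(gene.end)
        if gap is None:
            if chrom_length is None:
                raise ValueError(f"chromosome length unknown for {gene.chrom}")
            return float(chrom_length - gene.end), True
        return gap, False
    gap = index.gap_minus(gene.start)
    if gap is None:
        return float(gene.start - 1), True
    return gap, False


def downstream_gap(gene: GeneModel, gene_set: GeneModelSet) -> float:
    """Intergenic distance downstream of a gene's 3' end, in bp.

    The neighbor is the nearest other gene on the same chromosome, either
    strand, occupying any base beyond the 3' end; an overlapping or nested
    neighbor covering the 3' end gives a gap of 0.  Without a neighbor the
    distance runs to the chromosome end (or start, on the minus strand),
    which requires the chromosome length to be known.
    """
    if gene.id not in gene_set:
        raise KeyError(f"gene {gene.id!r} not in set")
    index = _ChromIndex(gene_set.by_chrom(gene.chrom))
    gap, _ = _gap_from_index(gene, index, gene_set.chrom_lengths.get(gene.chrom))
    return gap


def extension_amount(
    L: int,
    D: float,
    params: ExtensionParams = ExtensionParams(),
    gap_is_chrom_end: bool = False,
) -> tuple[int, str]:
    """Apply the three-regime 3'-extension rule to one (L, D) pair.

    Returns ``(E, regime)``.  When the downstream room is the chromosome
    boundary rather than a neighboring gene (``gap_is_chrom_end``), a cap
    that binds is reported as ``chrom_end_capped`` instead of
    ``gap_capped``.
    """
    if L < 1:
        raise ValueError("gene length must be positive")
    if D < 0:
        raise ValueError("downstream gap must be non-negative")
    if D <= params.min_gap:
        return 0, "none"
    if D >= params.full_multiple * L:
        e = L
        regime = "full"
    else:
        e = int(params.frac * L)
        regime = "fractional"
    if math.isfinite(D) and e > D:
        e = int(D)
        regime = "chrom_end_capped" if gap_is_chrom_end else "gap_capped"
    return e, regime


def extend_three_prime(
    gene_set: GeneModelSet,
    params: ExtensionParams = ExtensionParams(),
) -> tuple[GeneModelSet, list[ExtensionResult]]:
    """Extend every gene model on its 3' side per the conditional rule.

    Returns the extended set (same ids, new coordinates) and the per-gene
    :class:`ExtensionResult` records.  Original coordinates are recoverable
    from each record (``L`` and ``E``).
    """
    extended: list[GeneModel] = []
    results: list[ExtensionResult] = []
    indices = {
        chrom: _ChromIndex(gene_set.by_chrom(chrom))
        for chrom in {g.chrom for g in gene_set}
    }
    for gene in gene_set:
        d, at_chrom_end = _gap_from_index(
            gene, indices[gene.chrom], gene_set.chrom_lengths.get(gene.chrom)
        )
        e, regime = extension_amount(gene.length, d, params, gap_is_chrom_end=at_chrom_end)
        if gene.strand == "+":
            new = replace(gene, end=gene.end + e)
        else:
            new = replace(gene, start=gene.start - e)
        extended.append(new)
        results.append(
            ExtensionResult(gene_id=gene.id, L=gene.length, D=d, E=e, regime=regime)
        )
    out = GeneModelSet(models=extended, chrom_lengths=dict(gene_set.chrom_lengths))
    results.sort(key=lambda r: r.gene_id)
    return out, results


# ---------------------------------------------------------------------------
# Novel-locus calling


def call_novel_loci(
    unassigned,
    extended_models: GeneModelSet | None = None,
    max_gap: int = 200,
    min_tags: int = 10,
) -> GeneModelSet:
    """Call novel transcribed loci from unassigned, deduplicated tags.

    Tags are clustered per (chromosome, strand) by single linkage on the
    start coordinate: a gap between successive tag starts larger than
    ``max_gap`` splits clusters.  Clusters with at least ``min_tags``
    members become novel loci spanning [min start, max tag end].  Loci
    overlapping an extended gene model on the same strand are discarded.

    ``unassigned`` is a :class:`~macetools.tagcounts.TagAlignmentSet` (any
    object with a ``frame`` DataFrame of chrom/start/length/strand works).
    """
    df = unassigned.frame
    loci: list[GeneModel] = []
    counter = 0
    chrom_lengths = dict(extended_models.chrom_lengths) if extended_models else {}
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        same_strand_genes = (
            [g for g in extended_models.by_chrom(str(chrom)) if g.strand == strand]
            if extended_models is not None
            else []
        )
        grp = grp.sort_values(["start", "length"])
        starts = grp["start"].to_numpy()
        ends = (grp["start"] + grp["length"] - 1).to_numpy()
        if len(starts) == 0:
            continue
        cluster_start = 0
        for i in range(1, len(starts) + 1):
            if i == len(starts) or starts[i] - starts[i - 1] > max_gap:
                members = slice(cluster_start, i)
                n = i - cluster_start
                if n >= min_tags:
                    lo = int(starts[members][0])
                    hi = int(ends[members].max())
                    overlaps_gene = any(
                        g.start <= hi and g.end >= lo for g in same_strand_genes
                    )
                    if not overlaps_gene:
                        counter += 1
                        loci.append(
                            GeneModel(
                                id=f"NOVEL_{counter:05d}",
                                chrom=str(chrom),
                                start=lo,
                                end=hi,
                                strand=str(strand),
                                confidence="novel",
                            )
                        )
                cluster_start = i
    return GeneModelSet(models=loci, chrom_lengths=chrom_lengths)


def extension_report(results: Sequence[ExtensionResult]):
    """Extension results as a tidy DataFrame (gene, L, D, E, regime)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "L": [r.L for r in results],
            "D": [r.D for r in results],
            "E": [r.E for r in results],
            "regime": [r.regime for r in results],
        }
    )
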