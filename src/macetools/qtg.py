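"""LD-block delimitation around focal QTL markers and candidate-gene calls.

A QTL interval is delimited as the set of SNP markers in strong linkage
disequilibrium (r^2 >= 0.8) with the focal trait-associated marker;
the block interval spans the member marker positions.  Salt-responsive
genes whose coordinates overlap a block become candidate quantitative
trait genes (QTGs).  Genotypes are biallelic codes of inbred lines, so
allele columns are haplotype-equivalent and r^2 is the squared Pearson
correlation of allele codes over lines complete at both markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "LDBlock",
    "QtgHit",
    "ld_r2",
    "delimit_block",
    "find_qtg",
]


@dataclass
class MarkerMap:
    """marker id -> (chrom, position bp); positions unique per chromosome."""

    positions: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for marker, (chrom, pos) in self.positions.items():
            key = (chrom, pos)
            if key in seen:
                raise ValueError(
                    f"markers {seen[key]!r} and {marker!r} share position {key}"
                )
            seen[key] = marker

    def chrom_of(self, marker: str) -> str:
        return self.positions[marker][0]

    def pos_of(self, marker: str) -> int:
        return self.positions[marker][1]

    def markers_on(self, chrom: str) -> list[str]:
        return sorted(
            (m for m, (c, _) in self.positions.items() if c == chrom),
            key=lambda m: self.positions[m][1],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls({r.marker: (str(r.chrom), int(r.pos)) for r in df.itertuples()})


@dataclass
class GenotypeMatrix:
    """Markers x lines biallelic codes {0, 1}; NaN marks missing calls."""

    frame: pd.DataFrame  # index marker, columns line ids

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        bad = vals[~np.isnan(vals)]
        if len(bad) and not np.isin(bad, (0.0, 1.0)).all():
            raise ValueError("genotype codes must be 0, 1 or missing")

    def alleles(self, marker: str) -> np.ndarray:
        return self.frame.loc[marker].to_numpy(dtype=float)

    def is_monomorphic(self, marker: str) -> bool:
        vals = self.alleles(marker)
        vals = vals[~np.isnan(vals)]
        return len(np.unique(vals)) < 2


@dataclass(frozen=True)
class LDBlock:
    """Focal-marker-centered interval covering all markers with r^2 >= threshold."""

    focal: str
    members: tuple[str, ...]
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of allele codes over complete lines.

    Equivalent, for haplotype data, to the classical
    (p_AB - p_A p_B)^2 / (p_A q_A p_B q_B).  Returns NaN (undefined, not
    zero) when either marker is monomorphic on the pairwise-complete
    subset; raises if fewer than 2 complete observations exist.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    complete = ~np.isnan(a) & ~np.isnan(b)
    if complete.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    a, b = a[complete], b[complete]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, r * r))


def delimit_block(
    focal: str,
    marker_map: MarkerMap,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.8,
) -> LDBlock:
    """Block of all same-chromosome markers with defined r^2 >= ``r2_min``.

    The focal marker always belongs (r^2 = 1 with itself); markers that
    are monomorphic (undefined r^2) are excluded.  The interval spans the
    member positions; a singleton block has length 0.
    """
    if focal not in marker_map.positions:
        raise KeyError(f"focal marker {focal!r} not in map")
    if focal not in genotypes.frame.index:
        raise KeyError(f"focal marker {focal!r} not in genotype matrix")
    chrom = marker_map.chrom_of(focal)
    focal_alleles = genotypes.alleles(focal)
    members = []
    for marker in marker_map.markers_on(chrom):
        if marker == focal:
            members.append(marker)
            continue
        if marker not in genotypes.frame.index:
            continue
        r2 = ld_r2(focal_alleles, genotypes.alleles(marker))
        if not math.isnan(r2) and r2 >= r2_min:
            members.append(marker)
    positions = [marker_map.pos_of(m) for m in members]
    return LDBlock(
        focal=focal,
        members=tuple(sorted(members, key=marker_map.pos_of)),
        chrom=chrom,
        start=min(positions),
        end=max(positions),
    )


@dataclass(frozen=True)
class QtgHit:
    """A responsive gene overlapping an LD block, with its fold-change context."""

    gene_id: str
    chrom: str
    start: int
    end: int
    block: LDBlock
    gfold: dict | None = None
    genotype: str | None = None


def find_qtg(
    blocks: Sequence[LDBlock],
    genes: pd.DataFrame,
    gfold_table: pd.DataFrame | None = None,
    genotype: str | None = None,
) -> list[QtgHit]:
    """Responsive genes whose interval overlaps an LD block by >= 1 bp.

    ``genes`` needs columns chrom/start/end indexed by gene id (1-based
    inclusive coordinates on the marker assembly).  ``gfold_table``
    (genes x timepoints) supplies the per-timepoint fold-change values
    carried on each hit for reporting.
    """
    hits = []
    for block in blocks:
        on_chrom = genes[genes["chrom"] == block.chrom]
        for gene_id, row in on_chrom.iterrows():
            if row["start"] <= block.end and row["end"] >= block.start:
                gf = (
                    gfold_table.loc[gene_id].to_dict()
                    if gfold_table is not None and gene_id in gfold_table.index
                    else None
                )
                hits.append(
                    QtgHit(
                        gene_id=str(gene_id),
                        chrom=str(row["chrom"]),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        block=block,
                        gfold=gf,
                        genotype=genotype,
                    )
                )
    return hits


def read_genotypes(path: str | Path) -> tuple[MarkerMap, GenotypeMatrix]:
    """Read a TSV with columns marker/chrom/pos followed by one column per line."""
    df = pd.read_csv(path, sep="\t")
    marker_map = MarkerMap.from_frame(df[["marker", "chrom", "pos"]])
    geno = df.drop(columns=["chrom", "pos"]).set_index("marker")
    return marker_map, GenotypeMatrix(geno)
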