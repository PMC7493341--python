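"""Background-restricted GO over-representation testing.

Each term is tested with the hypergeometric upper tail against the
genotype's transcriptomic background: with N background genes, K of them
annotated to the term, and n selected (responsive) genes of which GA
carry the term, p = P(X >= GA).  The expected count is GE = n*K/N and the
enrichment fold change is GA/GE.  p-values are Bonferroni-corrected over
the number of testable terms (K >= 1 after background restriction) and
terms with corrected p < 0.001 are called over-represented.  Annotations
are flat term ids; no ancestor propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "GoAnnotation",
    "EnrichmentResult",
    "enrich",
    "significance_transform",
    "read_go_annotation",
]


@dataclass
class GoAnnotation:
    """gene id -> set of term ids, with optional term descriptions."""

    gene_terms: dict[str, set[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_terms = {g: set(t) for g, t in self.gene_terms.items() if t}

    def restrict(self, genes: Iterable[str]) -> "GoAnnotation":
        keep = set(genes)
        return GoAnnotation(
            {g: t for g, t in self.gene_terms.items() if g in keep},
            self.descriptions,
        )

    def term_to_genes(self) -> dict[str, set[str]]:
        mapping: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for term in terms:
                mapping.setdefault(term, set()).add(gene)
        return mapping


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's test: observed GA vs expected GE with Bonferroni p."""

    term: str
    N: int
    K: int
    n: int
    GA: int
    GE: float
    fold: float
    p_raw: float
    p_corrected: float

    @property
    def neglog10(self) -> float:
        import math

        if self.p_corrected <= 0:
            return float("inf")
        return abs(-math.log10(self.p_corrected))  # abs() avoids -0.0 at p = 1


def read_go_annotation(path: str | Path) -> GoAnnotation:
    """Read a two-column gene<TAB>term file (one pair per line)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"], dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term"]):
        mapping.setdefault(gene, set()).add(term)
    return GoAnnotation(mapping)


def enrich(
    selected: Iterable[str],
    background: Iterable[str],
    annot: GoAnnotation,
    alpha: float = 0.001,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of terms in ``selected``.

    ``selected`` must be a subset of ``background``; the annotation is
    restricted to the background before testing.  The test universe N is
    the full background (annotated or not).  Results are sorted by
    corrected p, ties by term id.
    """
    sel = set(selected)
    bg = set(background)
    if not sel <= bg:
        extra = sorted(sel - bg)
        raise ValueError(f"selected genes outside background: {extra[:5]}")
    restricted = annot.restrict(bg)
    term_genes = restricted.term_to_genes()
    n_total = len(bg)
    n_sel = len(sel)
    testable = {t: g for t, g in term_genes.items() if len(g) >= 1}
    m = len(testable)
    results = []
    for term, genes in testable.items():
        k = len(genes)
        ga = len(genes & sel)
        ge = n_sel * k / n_total
        fold = ga / ge if ge > 0 else float("nan")
        # upper tail P(X >= GA) for X ~ Hypergeom(N, K, n)
        p_raw = float(stats.hypergeom.sf(ga - 1, n_total, k, n_sel))
        p_raw = min(1.0, p_raw)
        results.append(
            EnrichmentResult(
                term=term,
                N=n_total,
                K=k,
                n=n_sel,
                GA=ga,
                GE=ge,
                fold=fold,
                p_raw=p_raw,
                p_corrected=min(1.0, p_raw * m),
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.term))
    return results


def significance_transform(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate -log10 corrected p with significance flags.

    A term is significant iff corrected p < 1e-3, equivalently
    -log10(p_corrected) > 3; both derivations are asserted consistent.
    """
    rows = []
    for r in results:
        flag_p = r.p_corrected < 1e-3
        flag_t = r.neglog10 > 3.0
        assert flag_p == flag_t, "transform/threshold inconsistency"
        rows.append(
            {
                "term": r.term,
                "GA": r.GA,
                "GE": r.GE,
                "fold": r.fold,
                "p_corrected": r.p_corrected,
                "neglog10": r.neglog10,
                "significant": flag_p,
            }
        )
    return pd.DataFrame(rows)
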