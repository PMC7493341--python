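"""End-to-end orchestration of the tag-seq analysis stages.

A single :class:`PipelineConfig` names the input files (annotation, tag
alignments, count matrix with library metadata, GO annotation, genotype
matrix, Ct table — each stage runs only when its inputs are configured),
carries per-stage parameter blocks and one global seed, and points at an
output directory.  Stage outputs are flat TSV/GFF3 files for
diffability; a manifest records input checksums, parameters and the
seed, and a rerun with the same configuration reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, enrichment, genemodels, profiles, qtg, rtqpcr, tagcounts

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input paths, per-stage parameters, global seed and output directory."""

    outdir: str
    seed: int = 0
    annotation: str | None = None
    tags: str | None = None
    counts: str | None = None
    libraries: str | None = None
    go: str | None = None
    genotypes: str | None = None
    ct: str | None = None
    extension: dict = field(default_factory=dict)  # min_gap / frac / full_multiple
    counting: dict = field(default_factory=dict)  # min_mapq / stranded / dedup
    background: dict = field(default_factory=dict)  # threshold
    gfold: dict = field(default_factory=dict)  # c / n_draws / threshold
    enrichment: dict = field(default_factory=dict)  # alpha
    profiles: dict = field(default_factory=dict)  # c / n_perm
    qtg: dict = field(default_factory=dict)  # focal / r2_min
    qpcr: dict = field(default_factory=dict)  # target / reference

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def input_paths(self) -> dict[str, str]:
        names = ("annotation", "tags", "counts", "libraries", "go", "genotypes", "ct")
        return {n: getattr(self, n) for n in names if getattr(self, n) is not None}

    def validate(self) -> None:
        for name, path in self.input_paths().items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input does not exist: {path}")
        if self.go is not None and self.counts is None:
            raise ValueError("enrichment requires a count matrix input")
        if self.ct is not None and not self.qpcr.get("target"):
            raise ValueError("qpcr stage requires qpcr.target in the config")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator tagging stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("extension")
def _run_extension(config: PipelineConfig, outdir: Path):
    gene_set = genemodels.read_gff3(config.annotation)
    params = genemodels.ExtensionParams(**config.extension)
    extended, results = genemodels.extend_three_prime(gene_set, params)
    genemodels.write_gff3(extended, outdir / "extended.gff3")
    genemodels.extension_report(results).to_csv(
        outdir / "extension_report.tsv", sep="\t", index=False
    )
    return extended


@_stage("counting")
def _run_counting(config: PipelineConfig, outdir: Path, extended):
    opts = dict(config.counting)
    tags, summary = tagcounts.read_alignments(
        config.tags, min_mapq=opts.get("min_mapq", 20)
    )
    if opts.get("dedup", True):
        tags, n_dup = tagcounts.deduplicate(tags)
        summary.n_duplicates_removed = n_dup
    counts, summary, unassigned = tagcounts.count_tags(
        tags, extended, stranded=opts.get("stranded", "sense"), summary=summary
    )
    counts.rename("count").to_csv(outdir / "tag_counts.tsv", sep="\t")
    pd.Series(dataclasses.asdict(summary)).to_csv(
        outdir / "assignment_summary.tsv", sep="\t", header=False
    )
    novel = genemodels.call_novel_loci(
        unassigned,
        extended,
        max_gap=opts.get("max_gap", 200),
        min_tags=opts.get("min_tags", 10),
    )
    genemodels.write_gff3(novel, outdir / "novel_loci.gff3")
    return counts, summary, novel


@_stage("background")
def _run_background(config: PipelineConfig, outdir: Path):
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    metadata = pd.read_csv(config.libraries, sep="\t", index_col=0)
    matrix = tagcounts.CountMatrix(counts=counts, metadata=metadata, state="raw")
    grouping = {lib: matrix.genotype_of(lib) for lib in matrix.libraries}
    threshold = config.background.get("threshold", 2.5)
    filtered, loss = tagcounts.background_filter(matrix, grouping, threshold=threshold)
    filtered.counts.to_csv(outdir / "background_counts.tsv", sep="\t")
    loss.to_csv(outdir / "background_loss.tsv", sep="\t")
    tagcounts.expression_density_summary(matrix).to_csv(
        outdir / "expression_deciles.tsv", sep="\t"
    )
    return filtered


@_stage("gfold")
def _run_gfold(config: PipelineConfig, outdir: Path, filtered):
    opts = dict(config.gfold)
    params = diffexp.GfoldParams(
        c=opts.get("c", 0.01),
        n_draws=opts.get("n_draws", 20_000),
        seed=config.seed,
    )
    threshold = opts.get("threshold", 1.0)
    all_results: dict[str, dict[str, pd.DataFrame]] = {}
    rows = []
    for genotype in sorted(filtered.metadata["genotype"].unique()):
        plan = diffexp.ContrastPlan.from_metadata(filtered.metadata, genotype)
        libs = filtered.metadata.index[filtered.metadata["genotype"] == genotype]
        sub = tagcounts.CountMatrix(
            counts=filtered.counts[list(libs)],
            metadata=filtered.metadata.loc[libs],
            state="raw",
        )
        results = diffexp.classify_responsive(sub, plan, params, threshold=threshold)
        all_results[genotype] = results
        for tp, df in results.items():
            out = df.copy()
            out.insert(0, "genotype", genotype)
            out.insert(1, "timepoint", tp)
            rows.append(out)
    table = pd.concat(rows) if rows else pd.DataFrame()
    table.to_csv(outdir / "gfold.tsv", sep="\t")
    summary = {
        geno: diffexp.summarize_direction(res) for geno, res in all_results.items()
    }
    pd.concat(summary, names=["genotype", "timepoint"]).to_csv(
        outdir / "direction_summary.tsv", sep="\t"
    )
    return all_results


@_stage("enrichment")
def _run_enrichment(config: PipelineConfig, outdir: Path, filtered, gfold_results):
    annot = enrichment.read_go_annotation(config.go)
    alpha = config.enrichment.get("alpha", 0.001)
    rows = []
    for genotype, results in gfold_results.items():
        libs = filtered.metadata.index[filtered.metadata["genotype"] == genotype]
        background = set(
            filtered.counts.index[(filtered.counts[list(libs)] > 0).any(axis=1)]
        )
        for tp, df in results.items():
            for direction in ("up", "down"):
                selected = set(df.index[df["call"] == direction]) & background
                if not selected:
                    continue
                for r in enrichment.enrich(selected, background, annot, alpha=alpha):
                    rows.append(
                        {
                            "genotype": genotype,
                            "timepoint": tp,
                            "direction": direction,
                            "term": r.term,
                            "GA": r.GA,
                            "GE": r.GE,
                            "fold": r.fold,
                            "p_raw": r.p_raw,
                            "p_corrected": r.p_corrected,
                        }
                    )
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)


@_stage("profiles")
def _run_profiles(config: PipelineConfig, outdir: Path, gfold_results):
    opts = dict(config.profiles)
    c = opts.get("c", 1)
    n_perm = opts.get("n_perm", 200)
    rows = []
    for genotype, results in gfold_results.items():
        tps = list(results)
        expr = pd.DataFrame({tp: results[tp]["gfold"] for tp in tps})
        expr.insert(0, "t0", 0.0)  # the shared control anchors every profile at 0
        responsive = set()
        for df in results.values():
            responsive |= set(df.index[df["call"] != "ns"])
        expr = expr.loc[sorted(responsive)]
        if expr.empty:
            continue
        prof = profiles.enumerate_profiles(expr.shape[1], c=c)
        assignment = profiles.assign_genes(expr, prof)
        sig = profiles.profile_significance(
            assignment, expr, n_perm=n_perm, seed=config.seed
        )
        out = sig.table.copy()
        out.insert(0, "genotype", genotype)
        rows.append(out.reset_index())
    if rows:
        pd.concat(rows).to_csv(outdir / "profile_significance.tsv", sep="\t", index=False)


@_stage("qtg")
def _run_qtg(config: PipelineConfig, outdir: Path, extended, gfold_results):
    marker_map, genotype_matrix = qtg.read_genotypes(config.genotypes)
    focal = config.qtg.get("focal") or sorted(marker_map.positions)[0]
    r2_min = config.qtg.get("r2_min", 0.8)
    block = qtg.delimit_block(focal, marker_map, genotype_matrix, r2_min=r2_min)
    with open(outdir / "ld_blocks.bed", "w") as fh:
        fh.write(
            f"{block.chrom}\t{block.start - 1}\t{block.end}\t{block.focal}\t{len(block.members)}\t.\n"
        )
    genes = pd.DataFrame(
        {
            "chrom": [g.chrom for g in extended],
            "start": [g.start for g in extended],
            "end": [g.end for g in extended],
        },
        index=pd.Index([g.id for g in extended], name="gene_id"),
    )
    responsive = set()
    gfold_cols = {}
    for genotype, results in gfold_results.items():
        for tp, df in results.items():
            responsive |= set(df.index[df["call"] != "ns"])
            gfold_cols[f"{genotype}_{tp}"] = df["gfold"]
    gfold_table = pd.DataFrame(gfold_cols)
    hits = qtg.find_qtg([block], genes.loc[sorted(responsive & set(genes.index))], gfold_table)
    pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "block_focal": h.block.focal,
                **(h.gfold or {}),
            }
            for h in hits
        ]
    ).to_csv(outdir / "qtg_hits.tsv", sep="\t", index=False)


@_stage("qpcr")
def _run_qpcr(config: PipelineConfig, outdir: Path):
    table = pd.read_csv(config.ct)
    reference = config.qpcr.get("reference")
    targets = config.qpcr.get("target")
    if isinstance(targets, str):
        targets = [targets]
    rows = []
    for target in targets:
        rel = rtqpcr.ddct(table, target=target, reference=reference)
        call, p = rtqpcr.test_regulation(rel["rq"].to_numpy())
        out = rel.reset_index()
        out.insert(0, "gene", target)
        out["call"] = call
        out["p"] = p
        rows.append(out)
    pd.concat(rows).to_csv(outdir / "qpcr_results.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Validation happens before any stage runs; a stage failure raises
    :class:`PipelineError` naming the stage.  The manifest records input
    checksums, the seed and the parameter blocks.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    extended = None
    if config.annotation:
        extended = _run_extension(config, outdir)
    if config.tags:
        if extended is None:
            raise PipelineError("stage 'counting' failed: requires an annotation input")
        _run_counting(config, outdir, extended)
    gfold_results = None
    filtered = None
    if config.counts:
        if config.libraries is None:
            raise PipelineError("stage 'background' failed: requires a libraries input")
        filtered = _run_background(config, outdir)
        gfold_results = _run_gfold(config, outdir, filtered)
    if config.go and gfold_results is not None:
        _run_enrichment(config, outdir, filtered, gfold_results)
    if gfold_results is not None:
        _run_profiles(config, outdir, gfold_results)
    if config.genotypes and gfold_results is not None and extended is not None:
        _run_qtg(config, outdir, extended, gfold_results)
    if config.ct:
        _run_qpcr(config, outdir)

    manifest = {
        "seed": config.seed,
        "inputs": {k: _sha256(v) for k, v in sorted(config.input_paths().items())},
        "parameters": {
            k: getattr(config, k)
            for k in (
                "extension",
                "counting",
                "background",
                "gfold",
                "enrichment",
                "profiles",
                "qtg",
                "qpcr",
            )
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
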