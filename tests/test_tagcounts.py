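"""Deduplication, counting (with brute-force oracle), CPM and background filter."""

import numpy as np
import pandas as pd
import pytest

from macetools.genemodels import GeneModel, GeneModelSet, extend_three_prime
from macetools.tagcounts import (
    AssignmentSummary,
    CountMatrix,
    TagAlignmentSet,
    background_filter,
    build_count_matrix,
    count_tags,
    cpm,
    deduplicate,
    expression_density_summary,
    find_background_threshold,
    read_alignments,
    write_bed,
)


def tag_frame(rows):
    return TagAlignmentSet(
        pd.DataFrame(rows, columns=["read_id", "chrom", "start", "length", "strand", "mapq"])
    )


def simple_matrix(counts: dict, genotypes: dict | None = None) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    meta = pd.DataFrame(
        {
            "genotype": [
                (genotypes or {}).get(lib, "G") for lib in df.columns
            ],
            "condition": "control",
            "timepoint": "0min",
        },
        index=df.columns,
    )
    return CountMatrix(counts=df, metadata=meta, state="raw")


class TestReadAlignments:
    def test_bed_mapq_filter_tallies_removed(self, tmp_path):
        p = tmp_path / "tags.bed"
        lines = [f"chr1\t{100 + i}\t{150 + i}\tr{i}\t{5 if i < 2 else 60}\t+" for i in range(10)]
        p.write_text("\n".join(lines) + "\n")
        tags, summary = read_alignments(p, min_mapq=20)
        assert len(tags) == 8
        assert summary.n_nonunique_removed == 2
        assert summary.n_input == 10

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        tags, summary = read_alignments(p)
        assert len(tags) == 0 and summary.n_input == 0

    def test_bed_round_trip_preserves_tags(self, tmp_path, tags):
        p = tmp_path / "tags.bed"
        write_bed(tags, p)
        back, summary = read_alignments(p, min_mapq=0)
        assert len(back) == len(tags)
        assert summary.n_nonunique_removed == 0
        pd.testing.assert_frame_equal(
            back.frame.sort_values(["chrom", "start", "read_id"]).reset_index(drop=True),
            tags.frame.sort_values(["chrom", "start", "read_id"]).reset_index(drop=True),
        )

    def test_sam_input_via_pysam(self, tmp_path):
        p = tmp_path / "tags.sam"
        p.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:100000\n"
            "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r2\t16\tchr1\t201\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r3\t0\tchr1\t301\t5\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        tags, summary = read_alignments(p, min_mapq=20)
        assert len(tags) == 2
        assert summary.n_nonunique_removed == 1
        assert list(tags.frame["strand"]) == ["+", "-"]
        assert list(tags.frame["start"]) == [101, 201]


class TestDeduplicate:
    def test_identical_keys_keep_one(self):
        tags = tag_frame(
            [("b", "chr1", 100, 50, "+", 60), ("a", "chr1", 100, 50, "+", 60),
             ("c", "chr1", 100, 50, "+", 30)]
        )
        kept, removed = deduplicate(tags)
        assert removed == 2
        assert list(kept.frame["read_id"]) == ["a"]  # highest mapq, then smallest id

    def test_distinct_keys_identity(self):
        tags = tag_frame(
            [("a", "chr1", 100, 50, "+", 60), ("b", "chr1", 100, 50, "-", 60),
             ("c", "chr1", 101, 50, "+", 60)]
        )
        kept, removed = deduplicate(tags)
        assert removed == 0 and len(kept) == 3

    def test_idempotence(self, tags):
        once, n1 = deduplicate(tags)
        twice, n2 = deduplicate(once)
        assert n2 == 0
        pd.testing.assert_frame_equal(once.frame, twice.frame)


class TestCounting:
    GENES = [
        GeneModel("gA", "chr1", 1000, 2000, "+"),
        GeneModel("gB", "chr1", 1500, 2500, "+"),  # overlaps gA
        GeneModel("gC", "chr1", 5000, 6000, "-"),
    ]

    def make(self):
        return GeneModelSet(models=list(self.GENES), chrom_lengths={"chr1": 100000})

    def test_single_assignment(self):
        counts, summary, _ = count_tags(
            tag_frame([("t", "chr1", 1100, 50, "+", 60)]), self.make()
        )
        assert counts["gA"] == 1 and summary.n_assigned == 1

    def test_two_same_strand_genes_is_ambiguous(self):
        counts, summary, _ = count_tags(
            tag_frame([("t", "chr1", 1600, 50, "+", 60)]), self.make()
        )
        assert counts.sum() == 0 and summary.n_ambiguous == 1

    def test_strand_mismatch_unassigned(self):
        counts, summary, unassigned = count_tags(
            tag_frame([("t", "chr1", 5500, 50, "+", 60)]), self.make()
        )
        assert counts.sum() == 0 and summary.n_unassigned == 1
        assert len(unassigned) == 1

    def test_extension_rescues_downstream_tag(self):
        original = GeneModelSet(
            models=[GeneModel("gA", "chr1", 1000, 2000, "+")],
            chrom_lengths={"chr1": 100000},
        )
        extended, _ = extend_three_prime(original)
        tag = tag_frame([("t", "chr1", 2100, 50, "+", 60)])
        with_orig, _, _ = count_tags(tag, original)
        with_ext, _, _ = count_tags(tag, extended)
        assert with_orig["gA"] == 0
        assert with_ext["gA"] == 1

    def test_unknown_chromosome_counts_as_unassigned(self):
        counts, summary, _ = count_tags(
            tag_frame([("t", "chrZ", 100, 50, "+", 60)]), self.make()
        )
        assert summary.n_unassigned == 1

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(17)
        genes = []
        pos = 1
        for i in range(50):
            length = int(rng.integers(200, 2000))
            genes.append(
                GeneModel(
                    f"g{i}", "chr1", pos, pos + length - 1,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
            pos += length + int(rng.integers(-100, 500))  # some overlaps
            pos = max(pos, genes[-1].start + 1)
        gs = GeneModelSet(models=genes, chrom_lengths={"chr1": pos + 10000})
        tag_rows = [
            (f"t{j}", "chr1", int(rng.integers(1, pos + 5000)), 50,
             "+" if rng.random() < 0.5 else "-", 60)
            for j in range(1000)
        ]
        tags = tag_frame(tag_rows)
        counts, summary, _ = count_tags(tags, gs)
        # oracle: exhaustive all-pairs interval overlap
        oracle = {g.id: 0 for g in gs}
        for _, chrom, start, length, strand, _ in tag_rows:
            hits = [
                g.id
                for g in gs
                if g.chrom == chrom and g.strand == strand
                and g.start <= start + length - 1 and g.end >= start
            ]
            if len(hits) == 1:
                oracle[hits[0]] += 1
        assert dict(counts) == oracle

    def test_conservation_invariant(self, tags, models):
        extended, _ = extend_three_prime(models)
        deduped, n_dup = deduplicate(tags)
        summary = AssignmentSummary(n_input=len(tags), n_duplicates_removed=n_dup)
        counts, summary, _ = count_tags(deduped, extended, summary=summary)
        summary.check_conservation()  # raises on violation


class TestCpm:
    def test_definition(self):
        m = simple_matrix({"lib1": [5, 999_995]})
        assert cpm(m).counts.loc["g0", "lib1"] == pytest.approx(5.0)

    def test_column_sums_are_1e6(self, count_bundle):
        matrix, _ = count_bundle
        sums = cpm(matrix).counts.sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_invariance_under_uniform_scaling(self):
        m1 = simple_matrix({"lib1": [10, 30, 60]})
        m2 = simple_matrix({"lib1": [100, 300, 600]})
        pd.testing.assert_frame_equal(cpm(m1).counts, cpm(m2).counts)

    def test_zero_total_library_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            cpm(simple_matrix({"lib1": [0, 0]}))

    def test_state_transition_guard(self):
        m = cpm(simple_matrix({"lib1": [10, 20]}))
        with pytest.raises(ValueError):
            cpm(m)


def engineered_matrix() -> tuple[CountMatrix, dict]:
    """Matrix where a 2.5 CPM filter loses <5% of reads but 5 and 10 CPM lose more.

    Per library (1e6 reads): 1000 genes at 2 reads (2 CPM, 0.2% of reads),
    15000 genes at 4 reads (4 CPM, 6% of reads), 100 genes sharing the rest.
    """
    low = [2] * 1000
    mid = [4] * 15000
    rest = (1_000_000 - sum(low) - sum(mid)) // 100
    high = [rest] * 100
    col = low + mid + high
    m = simple_matrix({"lib1": col, "lib2": col})
    grouping = {"lib1": "G", "lib2": "G"}
    return m, grouping


class TestBackgroundFilter:
    def test_boundary_mean_exactly_at_threshold_is_retained(self):
        m = simple_matrix({"lib1": [25, 999_975]})
        filtered, _ = background_filter(m, {"lib1": "G"}, threshold=25.0)
        assert "g0" in filtered.counts.index

    def test_all_zero_gene_removed(self):
        m = simple_matrix({"lib1": [0, 100, 900]})
        filtered, _ = background_filter(m, {"lib1": "G"}, threshold=2.5)
        assert "g0" not in filtered.counts.index

    def test_default_synthetic_loss_under_5pct(self, count_bundle):
        matrix, _ = count_bundle
        grouping = {lib: matrix.genotype_of(lib) for lib in matrix.libraries}
        _, loss = background_filter(matrix, grouping, threshold=2.5)
        assert (loss < 0.05).all()

    def test_missing_genotype_mapping_rejected(self):
        m = simple_matrix({"lib1": [10, 20]})
        with pytest.raises(ValueError, match="genotype"):
            background_filter(m, {})

    def test_per_genotype_restriction(self):
        # gene g0 passes in genotype A only; its counts are zeroed for B
        m = simple_matrix(
            {"a1": [50, 999_950], "b1": [1, 999_999]},
            genotypes={"a1": "A", "b1": "B"},
        )
        filtered, _ = background_filter(m, {"a1": "A", "b1": "B"}, threshold=25.0)
        assert filtered.counts.loc["g0", "a1"] == 50
        assert filtered.counts.loc["g0", "b1"] == 0


class TestFindBackgroundThreshold:
    def test_degenerate_zero_candidate(self):
        m = simple_matrix({"lib1": [10, 20]})
        assert find_background_threshold(m, {"lib1": "G"}, candidates=(0.0,)) == 0.0

    def test_engineered_grid_returns_2p5(self):
        m, grouping = engineered_matrix()
        got = find_background_threshold(
            m, grouping, max_loss=0.05, candidates=(0.5, 1.0, 2.5, 5.0, 10.0)
        )
        assert got == 2.5

    def test_all_candidates_failing_raises(self):
        m, grouping = engineered_matrix()
        with pytest.raises(ValueError, match="no candidate"):
            find_background_threshold(m, grouping, candidates=(5.0, 10.0))


class TestDensitySummary:
    def test_identical_libraries_identical_rows(self):
        m = simple_matrix({"lib1": [10, 30, 60], "lib2": [10, 30, 60]})
        deciles = expression_density_summary(m)
        assert (deciles.loc["lib1"] == deciles.loc["lib2"]).all()

    def test_scaling_invariance(self):
        m = simple_matrix({"lib1": [10, 30, 60], "lib2": [100, 300, 600]})
        deciles = expression_density_summary(m)
        assert np.allclose(deciles.loc["lib1"], deciles.loc["lib2"])

    def test_duplicate_heavy_library_shifts_upper_deciles(self, tags, models):
        """PCR duplication concentrates reads, lifting the top of the CPM
        distribution relative to the deduplicated library."""
        extended, _ = extend_three_prime(models)
        deduped, _ = deduplicate(tags)
        raw_counts, _, _ = count_tags(tags, extended)
        dedup_counts, _, _ = count_tags(deduped, extended)
        meta = pd.DataFrame(
            {"genotype": "G", "condition": "control", "timepoint": "0min"},
            index=["raw", "dedup"],
        )
        m = build_count_matrix({"raw": raw_counts, "dedup": dedup_counts}, meta)
        deciles = expression_density_summary(m)
        assert not np.allclose(deciles.loc["raw"], deciles.loc["dedup"])
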