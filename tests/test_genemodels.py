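"""3'-extension rule, intergenic gaps, GFF3 round trips, novel loci."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macetools.genemodels import (
    ExtensionParams,
    GeneModel,
    GeneModelSet,
    GffParseError,
    call_novel_loci,
    downstream_gap,
    extend_three_prime,
    extension_amount,
    read_gff3,
    write_gff3,
)
from macetools.synth import SynthConfig, generate_annotation, generate_tags
from macetools.tagcounts import TagAlignmentSet, count_tags, deduplicate


def make_set(genes, chrom_lengths=None):
    return GeneModelSet(models=genes, chrom_lengths=chrom_lengths or {"chr1": 1_000_000})


class TestGff3IO:
    def test_toy_file_parses_strands(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(
            "##gff-version 3\n"
            "##sequence-region chr1 1 50000\n"
            "chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=a\n"
            "chr1\tsrc\tgene\t1000\t2000\t.\t-\t.\tID=b;confidence=LC\n"
            "chr1\tsrc\tgene\t3000\t3500\t.\t+\t.\tID=c\n"
        )
        gs = read_gff3(p)
        assert len(gs) == 3
        assert gs["b"].strand == "-"
        assert gs["b"].confidence == "LC"
        assert gs.chrom_lengths == {"chr1": 50000}

    def test_round_trip_identity(self, tmp_path, models):
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff3(models, p1)
        write_gff3(read_gff3(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_end_before_start_is_parse_error_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tsrc\tgene\t500\t100\t.\t+\t.\tID=a\n")
        with pytest.raises(GffParseError, match="line 1"):
            read_gff3(p)


class TestDownstreamGap:
    def test_plus_strand_simple_gap(self):
        gs = make_set([
            GeneModel("a", "chr1", 1000, 5000, "+"),
            GeneModel("b", "chr1", 7001, 8000, "+"),
        ])
        assert downstream_gap(gs["a"], gs) == 2000

    def test_gap_to_chromosome_end(self):
        gs = make_set([GeneModel("a", "chr1", 1000, 9000, "+")], {"chr1": 10000})
        assert downstream_gap(gs["a"], gs) == 1000

    def test_overlapping_neighbor_gives_zero(self):
        gs = make_set([
            GeneModel("a", "chr1", 1000, 5000, "+"),
            GeneModel("b", "chr1", 4500, 6000, "-"),
        ])
        assert downstream_gap(gs["a"], gs) == 0

    def test_minus_strand_mirrored(self):
        gs = make_set([
            GeneModel("a", "chr1", 1000, 2000, "+"),
            GeneModel("b", "chr1", 3501, 6000, "-"),
        ])
        assert downstream_gap(gs["b"], gs) == 1500

    def test_unknown_chrom_length_raises(self):
        gs = GeneModelSet(models=[GeneModel("a", "chr1", 1000, 9000, "+")])
        with pytest.raises(ValueError, match="length unknown"):
            downstream_gap(gs["a"], gs)


class TestExtensionRule:
    @pytest.mark.parametrize(
        "L,D,expected_E,expected_regime",
        [
            (1000, 2000, 400, "fractional"),
            (10000, 1500, 1500, "gap_capped"),
            (500, 5000, 500, "full"),
            (800, 900, 0, "none"),
            (800, 1000, 0, "none"),  # boundary: D == min_gap does not extend
        ],
    )
    def test_worked_cases(self, L, D, expected_E, expected_regime):
        e, regime = extension_amount(L, D)
        assert e == expected_E
        assert regime == expected_regime

    def test_grid_hits_all_regimes_and_respects_rule(self):
        params = ExtensionParams()
        regimes = set()
        for L in range(200, 20001, 396):
            for frac_of_L in (0.0, 0.05, 0.3, 0.5, 1.0, 2.0, 2.99, 3.0, 5.0):
                D = int(frac_of_L * L)
                for at_chrom_end in (False, True):
                    e, regime = extension_amount(L, D, params, gap_is_chrom_end=at_chrom_end)
                    regimes.add(regime)
                    assert e <= max(D, 0)
                    if D <= 1000:
                        assert e == 0 and regime == "none"
                    elif D >= 3 * L:
                        assert e == L and regime == "full"
                    else:
                        assert e == min(int(0.4 * L), D)
        assert regimes == {"none", "fractional", "full", "gap_capped", "chrom_end_capped"}

    def test_chrom_end_capped_regime(self):
        e, regime = extension_amount(10000, 1500, gap_is_chrom_end=True)
        assert (e, regime) == (1500, "chrom_end_capped")

    @given(L=st.integers(200, 20000), D=st.integers(1001, 20000))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_length_until_cap(self, L, D):
        """In the fractional regime E is non-decreasing in L until a cap binds."""
        if D >= 3 * L or D >= 3 * (L + 100):
            return
        e1, _ = extension_amount(L, D)
        e2, _ = extension_amount(L + 100, D)
        assert e2 >= e1

    def test_identity_limit_reproduces_annotation(self, models):
        params = ExtensionParams(frac=0.0, full_multiple=math.inf)
        extended, results = extend_three_prime(models, params)
        for g, e in zip(models, extended):
            assert (g.start, g.end) == (e.start, e.end)
        assert all(r.E == 0 for r in results)

    def test_extension_never_crosses_neighbor_or_chrom_end(self, models):
        extended, results = extend_three_prime(models)
        by_id = {r.gene_id: r for r in results}
        for orig, ext in zip(models, extended):
            r = by_id[orig.id]
            assert r.E <= r.D
            assert ext.start >= 1
            assert ext.end <= models.chrom_lengths[ext.chrom]
        # extended genes still do not overlap the next original gene
        for chrom in models.chrom_lengths:
            originals = models.by_chrom(chrom)
            exts = {g.id: g for g in extended.by_chrom(chrom)}
            for a, b in zip(originals, originals[1:]):
                if a.strand == "+":
                    assert exts[a.id].end < b.start


class TestNovelLoci:
    @staticmethod
    def tag_set(positions, strand="+", chrom="chr1", length=50):
        return TagAlignmentSet(
            pd.DataFrame(
                {
                    "read_id": [f"t{i}" for i in range(len(positions))],
                    "chrom": chrom,
                    "start": positions,
                    "length": length,
                    "strand": strand,
                    "mapq": 60,
                }
            )
        )

    def test_single_cluster(self):
        loci = call_novel_loci(self.tag_set([1000 + 50 * i for i in range(15)]))
        assert len(loci) == 1
        locus = loci.models[0]
        assert (locus.start, locus.end) == (1000, 1000 + 50 * 14 + 49)
        assert locus.confidence == "novel"

    def test_gap_boundary_splits_clusters(self):
        positions = [100 + 10 * i for i in range(10)]
        positions += [positions[-1] + 201 + 10 * i for i in range(10)]
        loci = call_novel_loci(self.tag_set(positions), max_gap=200)
        assert len(loci) == 2

    def test_min_tags_threshold(self):
        loci = call_novel_loci(self.tag_set([100 * i + 1 for i in range(9)]), min_tags=10)
        assert len(loci) == 0

    def test_synthetic_recovery_of_true_loci(self):
        cfg = SynthConfig(seed=21)
        models, truth = generate_annotation(cfg)
        tags = generate_tags(models, truth, cfg)
        tags, _ = deduplicate(tags)
        extended, _ = extend_three_prime(models)
        _, _, unassigned = count_tags(tags, extended)
        loci = call_novel_loci(unassigned, extended)
        recovered = 0
        for t in truth.novel_loci.itertuples():
            if any(
                l.chrom == t.chrom
                and l.strand == t.strand
                and l.start <= t.end
                and l.end >= t.start
                for l in loci
            ):
                recovered += 1
        assert recovered / len(truth.novel_loci) >= 0.95
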