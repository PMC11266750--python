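"""PROMPT reference construction: parsing, TSS, windows, overlap filtering, I/O."""

import io

import numpy as np
import pytest

from promptseq import (
    GeneRecord,
    GenomeAnnotation,
    build_prompt_regions,
    filter_nonoverlapping,
    gene_tss,
    parse_annotation,
    read_prompt_regions,
    write_gtf,
    write_prompt_regions,
)
from promptseq.annotation import GtfParseError


def _gtf(*lines: str) -> io.StringIO:
    return io.StringIO("\n".join(lines) + "\n")


class TestParseAnnotation:
    def test_gene_line_maps_fields(self):
        ann = parse_annotation(
            _gtf('chr1\t.\tgene\t10001\t12000\t.\t+\t.\tgene_id "g1"; gene_biotype "protein_coding";')
        )
        (g,) = ann.genes
        assert (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype) == (
            "g1", "chr1", 10001, 12000, "+", "protein_coding",
        )

    def test_biotype_attribute_and_default(self):
        ann = parse_annotation(
            _gtf(
                'chr1\t.\tgene\t1\t10\t.\t+\t.\tgene_id "a"; gene_biotype "lncRNA";',
                'chr1\t.\tgene\t100\t200\t.\t-\t.\tgene_id "b";',
            )
        )
        assert ann.by_id()["a"].biotype == "lncRNA"
        assert ann.by_id()["b"].biotype == "unknown"

    def test_transcripts_and_exons_attach_by_gene_id(self):
        ann = parse_annotation(
            _gtf(
                'chr1\t.\tgene\t100\t500\t.\t+\t.\tgene_id "g";',
                'chr1\t.\ttranscript\t100\t500\t.\t+\t.\tgene_id "g";',
                'chr1\t.\texon\t100\t200\t.\t+\t.\tgene_id "g";',
                'chr1\t.\texon\t400\t500\t.\t+\t.\tgene_id "g";',
            )
        )
        g = ann.by_id()["g"]
        assert g.transcripts == [(100, 500)]
        assert g.exons == [(100, 200), (400, 500)]

    def test_comments_and_blank_lines_ignored(self):
        ann = parse_annotation(_gtf("# header", "", 'chr1\t.\tgene\t1\t5\t.\t+\t.\tgene_id "g";'))
        assert len(ann.genes) == 1

    @pytest.mark.parametrize(
        "line,msg",
        [
            ('chr1\t.\tgene\t500\t400\t.\t+\t.\tgene_id "g";', "line 1"),
            ('chr1\t.\tgene\t1\t5\t.\t+\tgene_id "g";', "line 1"),
            ('chr1\t.\tgene\tx\t5\t.\t+\t.\tgene_id "g";', "line 1"),
            ('chr1\t.\tgene\t1\t5\t.\t+\t.\tno_id "g";', "gene_id"),
        ],
    )
    def test_malformed_lines_raise_with_line_number(self, line, msg):
        with pytest.raises(GtfParseError, match=msg):
            parse_annotation(_gtf(line))

    def test_duplicate_gene_id_raises(self):
        with pytest.raises(GtfParseError, match="duplicate"):
            parse_annotation(
                _gtf(
                    'chr1\t.\tgene\t1\t5\t.\t+\t.\tgene_id "g";',
                    'chr2\t.\tgene\t1\t5\t.\t+\t.\tgene_id "g";',
                )
            )

    def test_gtf_writer_round_trips(self, ten_gene_annotation):
        buf = io.StringIO()
        write_gtf(ten_gene_annotation, buf)
        buf.seek(0)
        again = parse_annotation(buf)
        assert [(g.gene_id, g.start, g.end, g.strand, g.biotype) for g in again.genes] == [
            (g.gene_id, g.start, g.end, g.strand, g.biotype) for g in ten_gene_annotation.genes
        ]


class TestTss:
    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [("+", 10001, 12000, 10001), ("-", 5001, 8000, 8000), ("+", 1, 1, 1)],
    )
    def test_strand_convention(self, strand, start, end, expected):
        assert gene_tss(GeneRecord("g", "chr1", start, end, strand)) == expected


class TestBuildPromptRegions:
    def test_plus_strand_window(self):
        ann = GenomeAnnotation([GeneRecord("g", "chr1", 10001, 12000, "+")])
        (p,) = build_prompt_regions(ann)
        assert (p.start, p.end, p.length) == (7001, 10000, 3000)

    def test_minus_strand_window(self):
        ann = GenomeAnnotation([GeneRecord("g", "chr1", 5001, 8000, "-")])
        (p,) = build_prompt_regions(ann)
        assert (p.start, p.end, p.length) == (8001, 11000, 3000)

    def test_clipping_at_chromosome_start(self):
        ann = GenomeAnnotation([GeneRecord("g", "chr1", 1500, 2000, "+")])
        (p,) = build_prompt_regions(ann)
        assert (p.start, p.end, p.length) == (1, 1499, 1499)
        # brute-force check: intersection of the ideal window with [1, inf)
        ideal = set(range(1500 - 3000, 1500))
        clipped = {x for x in ideal if x >= 1}
        assert clipped == set(range(p.start, p.end + 1))

    def test_clipping_at_chromosome_end(self):
        ann = GenomeAnnotation(
            [GeneRecord("g", "chr1", 100, 900, "-")], chrom_lengths={"chr1": 2000}
        )
        (p,) = build_prompt_regions(ann)
        assert (p.start, p.end) == (901, 2000)

    def test_zero_length_window_dropped(self):
        ann = GenomeAnnotation([GeneRecord("g", "chr1", 1, 100, "+")])
        assert build_prompt_regions(ann) == []

    def test_region_never_overlaps_anchor_body(self, ten_gene_annotation):
        for p in build_prompt_regions(ten_gene_annotation):
            g = ten_gene_annotation.by_id()[p.anchor_gene_id]
            assert p.end < g.start or p.start > g.end
            assert 1 <= p.length <= 3000


class TestFilterNonoverlapping:
    def test_overlap_with_other_gene_body_excludes(self):
        genes = [
            GeneRecord("g1", "chr1", 10001, 12000, "+"),
            GeneRecord("g2", "chr1", 6000, 7500, "+"),
        ]
        ann = GenomeAnnotation(genes)
        prompts = [p for p in build_prompt_regions(ann) if p.anchor_gene_id == "g1"]
        assert prompts[0].start == 7001  # overlaps g2's body by 500 bp
        assert filter_nonoverlapping(prompts, ann) == []

    def test_adjacent_gene_body_retained(self):
        genes = [
            GeneRecord("g1", "chr1", 10001, 12000, "+"),
            GeneRecord("g2", "chr1", 5000, 6999, "+"),
        ]
        ann = GenomeAnnotation(genes)
        prompts = [p for p in build_prompt_regions(ann) if p.anchor_gene_id == "g1"]
        assert [p.anchor_gene_id for p in filter_nonoverlapping(prompts, ann)] == ["g1"]

    def test_prompt_prompt_overlap_keeps_both(self):
        # convergent genes whose upstream windows overlap each other only
        genes = [
            GeneRecord("g1", "chr1", 20000, 22000, "+"),  # PROMPT [17000,19999]
            GeneRecord("g2", "chr1", 10000, 14000, "-"),  # PROMPT [14001,17000]
        ]
        ann = GenomeAnnotation(genes)
        prompts = build_prompt_regions(ann)
        assert prompts[0].start <= prompts[1].end and prompts[1].start <= prompts[0].end
        assert len(filter_nonoverlapping(prompts, ann)) == 2

    def test_strand_agnostic_exclusion(self):
        genes = [
            GeneRecord("g1", "chr1", 10001, 12000, "+"),
            GeneRecord("g2", "chr1", 8000, 9000, "-"),  # opposite strand still excludes
        ]
        ann = GenomeAnnotation(genes)
        prompts = [p for p in build_prompt_regions(ann) if p.anchor_gene_id == "g1"]
        assert filter_nonoverlapping(prompts, ann) == []

    def test_retained_prompts_overlap_no_gene_body(self, ten_gene_annotation):
        kept = filter_nonoverlapping(build_prompt_regions(ten_gene_annotation), ten_gene_annotation)
        for p in kept:  # exhaustive scan
            for g in ten_gene_annotation.genes:
                assert g.chrom != p.chrom or p.end < g.start or p.start > g.end

    def test_retained_count_monotone_under_gene_addition(self, far_apart_annotation):
        base = far_apart_annotation
        kept_before = filter_nonoverlapping(build_prompt_regions(base), base)
        rng = np.random.default_rng(0)
        genes = list(base.genes)
        for i in range(8):
            s = int(rng.integers(1, 120_000))
            genes.append(GeneRecord(f"extra{i}", "chr1", s, s + 2000, "+"))
            bigger = GenomeAnnotation(genes=list(genes))
            kept_after = filter_nonoverlapping(
                [p for p in build_prompt_regions(bigger) if not p.anchor_gene_id.startswith("extra")],
                bigger,
            )
            assert len(kept_after) <= len(kept_before)
            kept_before = kept_after

    def test_far_apart_genes_all_retained_full_length(self, far_apart_annotation):
        kept = filter_nonoverlapping(
            build_prompt_regions(far_apart_annotation), far_apart_annotation
        )
        assert len(kept) == len(far_apart_annotation.genes)
        assert all(p.length == 3000 for p in kept)


class TestPromptIO:
    def test_bed6_coordinate_convention(self):
        ann = GenomeAnnotation([GeneRecord("g", "chr1", 10001, 12000, "+")])
        (p,) = build_prompt_regions(ann)
        buf = io.StringIO()
        write_prompt_regions([p], buf, "BED6")
        chrom, start, end, name, score, strand = buf.getvalue().strip().split("\t")
        assert (chrom, start, end, name, strand) == ("chr1", "7000", "10000", "PROMPT_g", "+")

    @pytest.mark.parametrize("fmt", ["BED6", "SAF"])
    def test_round_trip_identity(self, fmt, ten_gene_annotation):
        prompts = filter_nonoverlapping(
            build_prompt_regions(ten_gene_annotation), ten_gene_annotation
        )
        buf = io.StringIO()
        write_prompt_regions(prompts, buf, fmt)
        buf.seek(0)
        assert read_prompt_regions(buf, fmt) == prompts

    def test_empty_list_gives_empty_or_header_only(self):
        buf = io.StringIO()
        write_prompt_regions([], buf, "BED6")
        assert buf.getvalue() == ""
        buf = io.StringIO()
        write_prompt_regions([], buf, "SAF")
        assert buf.getvalue().splitlines() == ["GeneID\tChr\tStart\tEnd\tStrand"]

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            write_prompt_regions([], io.StringIO(), "GFF3")
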