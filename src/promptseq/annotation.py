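"""Genome annotation parsing and PROMPT reference construction.

PROMPTs (PROMoter uPstream Transcripts) are short, unstable RNAs produced
within a few kilobases upstream of active transcription start sites, often
antisense to the downstream gene.  To quantify them, this module builds one
candidate upstream interval per annotated gene (by default the window from
3 kb upstream to 1 bp upstream of the TSS), then discards every candidate
whose interval touches any annotated gene body, so that reads falling in a
retained region cannot be attributed to ordinary genic transcription.

Coordinates on the public dataclasses are 1-based inclusive (GTF/SAF
convention); the BED6 writer/reader converts to and from 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from intervaltree import IntervalTree

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "PromptRegion",
    "parse_annotation",
    "gene_tss",
    "build_prompt_regions",
    "filter_nonoverlapping",
    "write_prompt_regions",
    "read_prompt_regions",
    "write_gtf",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class GeneRecord:
    """One annotated gene: gene-level span, strand, biotype and sub-features."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    biotype: str = "unknown"
    transcripts: list[tuple[int, int]] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}-{self.end}")
        if not self.biotype:
            self.biotype = "unknown"


@dataclass
class GenomeAnnotation:
    """A set of genes plus optional chromosome lengths."""

    genes: list[GeneRecord]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id(s): {', '.join(dup)}")

    def by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


@dataclass(frozen=True)
class PromptRegion:
    """Candidate PROMPT interval upstream of one anchor gene's TSS."""

    prompt_id: str
    anchor_gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    anchor_strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GtfParseError(ValueError):
    pass


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_annotation(gtf_stream: Iterable[str] | TextIO) -> GenomeAnnotation:
    """Parse GTF lines (GENCODE dialect) into a :class:`GenomeAnnotation`.

    Only ``gene``, ``transcript`` and ``exon`` features are consumed;
    transcript/exon spans are attached to their gene via ``gene_id``.
    Malformed lines raise :class:`GtfParseError` naming the line number;
    a repeated gene feature for the same ``gene_id`` is an error.
    """
    genes: dict[str, GeneRecord] = {}
    pending: dict[str, dict[str, list[tuple[int, int]]]] = {}

    for lineno, raw in enumerate(gtf_stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
        if start > end or start < 1:
            raise GtfParseError(f"line {lineno}: invalid span {start}-{end}")
        if feature not in ("gene", "transcript", "exon"):
            continue
        attributes = _parse_attributes(attrs)
        gene_id = attributes.get("gene_id")
        if not gene_id:
            raise GtfParseError(f"line {lineno}: missing gene_id attribute")

        if feature == "gene":
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
            if gene_id in genes:
                raise GtfParseError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            genes[gene_id] = GeneRecord(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                biotype=attributes.get("gene_biotype", "unknown"),
            )
        else:
            slot = pending.setdefault(gene_id, {"transcript": [], "exon": []})
            slot[feature].append((start, end))

    for gene_id, spans in pending.items():
        if gene_id not in genes:
            continue  # orphan sub-features tolerated
        gene = genes[gene_id]
        gene.transcripts.extend(spans["transcript"])
        for s, e in spans["exon"]:
            if s < gene.start or e > gene.end:
                raise GtfParseError(f"gene {gene_id}: exon {s}-{e} outside gene span")
            gene.exons.append((s, e))
    return GenomeAnnotation(genes=list(genes.values()))


def gene_tss(gene: GeneRecord) -> int:
    """Gene-level transcription start site: the 5'-most position on the gene's strand."""
    return gene.start if gene.strand == "+" else gene.end


def build_prompt_regions(
    annotation: GenomeAnnotation, upstream_len: int = 3000
) -> list[PromptRegion]:
    """Build the upstream window [-upstream_len, -1 bp] relative to each TSS.

    Windows are clipped to [1, chrom_length] (when a length is known);
    windows that clip to zero length are dropped.  Regions never overlap
    their own anchor gene body by construction.
    """
    if upstream_len < 1:
        raise ValueError("upstream_len must be >= 1")
    regions: list[PromptRegion] = []
    for gene in annotation.genes:
        tss = gene_tss(gene)
        if gene.strand == "+":
            start, end = tss - upstream_len, tss - 1
        else:
            start, end = tss + 1, tss + upstream_len
        start = max(start, 1)
        clen = annotation.chrom_lengths.get(gene.chrom)
        if clen is not None:
            end = min(end, clen)
        if end < start:
            continue
        regions.append(
            PromptRegion(
                prompt_id=f"PROMPT_{gene.gene_id}",
                anchor_gene_id=gene.gene_id,
                chrom=gene.chrom,
                start=start,
                end=end,
                anchor_strand=gene.strand,
            )
        )
    return regions


def filter_nonoverlapping(
    prompts: Iterable[PromptRegion], annotation: GenomeAnnotation
) -> list[PromptRegion]:
    """Retain PROMPTs sharing zero bp with any gene body, strand-agnostically.

    The test is against gene-level start-end spans of every gene (the anchor
    gene itself cannot overlap by construction).  Overlaps between two
    PROMPT regions do not disqualify either.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in annotation.genes:
        # half-open internal coordinates
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start - 1, gene.end, gene.gene_id)
    kept = []
    for p in prompts:
        tree = trees.get(p.chrom)
        if tree is None or not tree.overlap(p.start - 1, p.end):
            kept.append(p)
    return kept


def write_prompt_regions(prompts: Iterable[PromptRegion], sink: TextIO, format: str = "BED6") -> None:
    """Write PROMPT regions as BED6 (0-based half-open) or SAF (1-based inclusive)."""
    fmt = format.upper()
    if fmt == "BED6":
        for p in prompts:
            sink.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.prompt_id}\t0\t{p.anchor_strand}\n")
    elif fmt == "SAF":
        sink.write("GeneID\tChr\tStart\tEnd\tStrand\n")
        for p in prompts:
            sink.write(f"{p.prompt_id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.anchor_strand}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_gtf(annotation: GenomeAnnotation, sink: TextIO, source: str = "promptseq") -> None:
    """Write an annotation as GENCODE-dialect GTF (gene/transcript/exon lines)."""
    for g in annotation.genes:
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        sink.write(f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
        for s, e in g.transcripts:
            sink.write(f"{g.chrom}\t{source}\ttranscript\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
        for s, e in g.exons:
            sink.write(f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def _anchor_from_prompt_id(prompt_id: str) -> str:
    return prompt_id[len("PROMPT_"):] if prompt_id.startswith("PROMPT_") else prompt_id


def read_prompt_regions(source: TextIO, format: str = "BED6") -> list[PromptRegion]:
    """Inverse of :func:`write_prompt_regions` (exact round trip)."""
    fmt = format.upper()
    regions = []
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if fmt == "BED6":
            chrom, start0, end, name, _score, strand = f[:6]
            regions.append(
                PromptRegion(name, _anchor_from_prompt_id(name), chrom, int(start0) + 1, int(end), strand)
            )
        elif fmt == "SAF":
            if f[0] == "GeneID":
                continue
            name, chrom, start, end, strand = f[:5]
            regions.append(
                PromptRegion(name, _anchor_from_prompt_id(name), chrom, int(start), int(end), strand)
            )
        else:
            raise ValueError(f"unknown format {format!r}")
    return regions
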