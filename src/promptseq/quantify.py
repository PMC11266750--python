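"""Strand-aware fragment counting over PROMPT regions and genes.

Fragments (sequenced cDNA templates, one span per template) are assigned to
features by interval overlap plus a strand rule.  Because PROMPTs are
transcribed bidirectionally relative to their downstream gene, PROMPT
regions are counted in three modes: ``sense`` (fragment strand equals the
anchor gene's strand), ``antisense`` (opposite) and ``unstranded`` (either).
Gene counting uses the exon-union model.  A fragment compatible with more
than one feature under the mode's strand rule is ambiguous and assigned to
none; every fragment contributes at most one count.

Fragments use 0-based half-open coordinates; features are 1-based inclusive
(see :mod:`promptseq.annotation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import GeneRecord, GenomeAnnotation

__all__ = [
    "Fragment",
    "FragmentSet",
    "CountMatrix",
    "CountTally",
    "load_fragments",
    "count_features",
    "count_genes",
]

STRAND_MODES = ("sense", "antisense", "unstranded")


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end}: start must be < end")


@dataclass
class FragmentSet:
    """Loaded fragments plus whether their strands carry protocol information."""

    fragments: list[Fragment]
    strand_informative: bool = True
    n_skipped: int = 0  # secondary/supplementary/unmapped/low-MAPQ records


@dataclass
class CountTally:
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    skipped_unknown_chrom: int = 0  # subset of unassigned

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.unassigned


@dataclass
class CountMatrix:
    """Integer fragment counts, features x samples, with per-feature metadata.

    ``feature_meta`` is indexed by feature_id with columns ``kind``
    ({gene, prompt}), ``strand_mode`` ({sense, antisense, unstranded, n/a}),
    ``anchor_gene_id`` and ``biotype``.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature/sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        self.feature_meta = self.feature_meta.reindex(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        df = self.feature_meta.copy()
        for j, s in enumerate(self.sample_ids):
            df[s] = self.counts[:, j]
        df.index.name = "feature_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        meta_cols = [c for c in ("kind", "strand_mode", "anchor_gene_id", "biotype") if c in df.columns]
        sample_ids = [c for c in df.columns if c not in meta_cols]
        return cls(
            counts=df[sample_ids].to_numpy(),
            feature_ids=list(df.index),
            sample_ids=sample_ids,
            feature_meta=df[meta_cols],
        )


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _resolve_strand(alignment_strand: str, library_strandedness: str) -> str:
    if library_strandedness == "reverse":
        return _flip(alignment_strand)
    return alignment_strand


def load_fragments(
    source: str | Path,
    library_strandedness: str = "reverse",
    min_mapq: int = 0,
) -> FragmentSet:
    """Load fragments from a BED6 table or a BAM/SAM file.

    For BAM, properly paired mates are merged into one template-span
    fragment (counted once, from the leftmost mate); secondary,
    supplementary and unmapped records are skipped, as are records below
    ``min_mapq``.  Fragment strand is the strand of read 1, flipped when
    the library protocol is ``reverse``.  With an ``unstranded`` protocol
    the alignment strand is carried through but flagged non-informative.
    """
    if library_strandedness not in ("forward", "reverse", "unstranded"):
        raise ValueError(f"unknown library_strandedness {library_strandedness!r}")
    path = Path(source)
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        return _load_bam(path, library_strandedness, min_mapq)
    return _load_bed(path, library_strandedness)


def _load_bed(path: Path, library_strandedness: str) -> FragmentSet:
    frags = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "+"
            if library_strandedness == "reverse":
                strand = _flip(strand)
            frags.append(Fragment(f[0], int(f[1]), int(f[2]), strand))
    return FragmentSet(frags, strand_informative=library_strandedness != "unstranded")


def _load_bam(path: Path, library_strandedness: str, min_mapq: int) -> FragmentSet:
    frags = []
    n_skipped = 0
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                n_skipped += 1
                continue
            if read.mapping_quality < min_mapq:
                n_skipped += 1
                continue
            if read.is_paired and read.is_proper_pair and read.template_length != 0:
                if read.template_length < 0:
                    continue  # rightmost mate; template counted at leftmost
                start = read.reference_start
                end = start + read.template_length
                r1_reverse = read.is_reverse if read.is_read1 else not read.is_reverse
            else:
                start, end = read.reference_start, read.reference_end
                r1_reverse = read.is_reverse
            strand = "-" if r1_reverse else "+"
            frags.append(
                Fragment(read.reference_name, start, end, _resolve_strand(strand, library_strandedness))
            )
    return FragmentSet(frags, strand_informative=library_strandedness != "unstranded", n_skipped=n_skipped)


def _feature_strand(feature) -> str:
    return getattr(feature, "anchor_strand", None) or getattr(feature, "strand")


def _strand_ok(frag_strand: str, feat_strand: str, mode: str) -> bool:
    if mode == "sense":
        return frag_strand == feat_strand
    if mode == "antisense":
        return frag_strand != feat_strand
    if mode == "unstranded":
        return True
    raise ValueError(f"unknown mode {mode!r}")


def count_features(
    fragments: Iterable[Fragment],
    features: Sequence,
    mode: str = "antisense",
    min_overlap: int = 1,
) -> tuple[np.ndarray, CountTally]:
    """Count fragments over single-interval features under one strand mode.

    A fragment is compatible with a feature if their overlap is at least
    ``min_overlap`` bp and the mode's strand rule holds against the
    feature's anchor strand.  Fragments compatible with several features
    are ambiguous and counted to none.  Returns one integer count per
    feature (in input order) and the assignment tally.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, feat in enumerate(features):
        trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start - 1, feat.end, idx)

    counts = np.zeros(len(features), dtype=np.int64)
    tally = CountTally()
    warned = False
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            tally.unassigned += 1
            tally.skipped_unknown_chrom += 1
            if not warned:
                warnings.warn(f"fragment chromosome {frag.chrom!r} absent from feature set; skipping")
                warned = True
            continue
        matched = []
        for iv in tree.overlap(frag.start, frag.end):
            if min(iv.end, frag.end) - max(iv.begin, frag.start) < min_overlap:
                continue
            if _strand_ok(frag.strand, _feature_strand(features[iv.data]), mode):
                matched.append(iv.data)
        if len(matched) == 1:
            counts[matched[0]] += 1
            tally.assigned += 1
        elif len(matched) > 1:
            tally.ambiguous += 1
        else:
            tally.unassigned += 1
    return counts, tally


def _exon_union(gene: GeneRecord) -> list[tuple[int, int]]:
    """Merged exon intervals (1-based inclusive); gene span if no exons annotated."""
    spans = sorted(gene.exons) if gene.exons else [(gene.start, gene.end)]
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_genes(
    fragments: Iterable[Fragment],
    annotation: GenomeAnnotation,
    library_strandedness: str = "reverse",
    min_overlap: int = 1,
) -> tuple[np.ndarray, CountTally]:
    """Count fragments over genes with the exon-union model.

    Overlap per gene is the total intersection of the fragment with the
    union of the gene's exons.  Stranded protocols require the fragment
    strand (already protocol-resolved at load time) to equal the gene
    strand; an unstranded protocol accepts either strand.  Ambiguity rule
    as in :func:`count_features`.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(annotation.genes):
        for s, e in _exon_union(gene):
            trees.setdefault(gene.chrom, IntervalTree()).addi(s - 1, e, idx)

    stranded = library_strandedness != "unstranded"
    genes = annotation.genes
    counts = np.zeros(len(genes), dtype=np.int64)
    tally = CountTally()
    warned = False
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            tally.unassigned += 1
            tally.skipped_unknown_chrom += 1
            if not warned:
                warnings.warn(f"fragment chromosome {frag.chrom!r} absent from annotation; skipping")
                warned = True
            continue
        overlap_bp: dict[int, int] = {}
        for iv in tree.overlap(frag.start, frag.end):
            bp = min(iv.end, frag.end) - max(iv.begin, frag.start)
            if bp > 0:
                overlap_bp[iv.data] = overlap_bp.get(iv.data, 0) + bp
        matched = [
            gi
            for gi, bp in overlap_bp.items()
            if bp >= min_overlap and (not stranded or frag.strand == genes[gi].strand)
        ]
        if len(matched) == 1:
            counts[matched[0]] += 1
            tally.assigned += 1
        elif len(matched) > 1:
            tally.ambiguous += 1
        else:
            tally.unassigned += 1
    return counts, tally
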