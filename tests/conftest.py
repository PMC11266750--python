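import io
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from promptseq import GenomeAnnotation, GeneRecord, parse_annotation

TEN_GENE_GTF = """\
# hand-built toy annotation
chr1\ttoy\tgene\t10001\t12000\t.\t+\t.\tgene_id "g01"; gene_biotype "protein_coding";
chr1\ttoy\tgene\t20000\t21000\t.\t-\t.\tgene_id "g02"; gene_biotype "lncRNA";
chr1\ttoy\tgene\t22500\t23500\t.\t+\t.\tgene_id "g03"; gene_biotype "protein_coding";
chr1\ttoy\tgene\t40000\t45000\t.\t+\t.\tgene_id "g04"; gene_biotype "snoRNA";
chr1\ttoy\tgene\t44000\t46000\t.\t-\t.\tgene_id "g05"; gene_biotype "snRNA";
chr2\ttoy\tgene\t1500\t2500\t.\t+\t.\tgene_id "g06"; gene_biotype "protein_coding";
chr2\ttoy\tgene\t30000\t31000\t.\t-\t.\tgene_id "g07"; gene_biotype "processed_pseudogene";
chr2\ttoy\tgene\t31500\t32500\t.\t+\t.\tgene_id "g08"; gene_biotype "protein_coding";
chr2\ttoy\tgene\t50000\t52000\t.\t+\t.\tgene_id "g09"; gene_biotype "lncRNA";
chr2\ttoy\tgene\t60000\t61000\t.\t-\t.\tgene_id "g10";
"""


@pytest.fixture(scope="session")
def ten_gene_annotation() -> GenomeAnnotation:
    ann = parse_annotation(io.StringIO(TEN_GENE_GTF))
    ann.chrom_lengths.update({"chr1": 100_000, "chr2": 62_000})
    return ann


@pytest.fixture()
def far_apart_annotation() -> GenomeAnnotation:
    """Genes separated by much more than the PROMPT window on both sides."""
    genes = [
        GeneRecord(f"far{i}", "chr1", 10_000 + i * 20_000, 11_000 + i * 20_000,
                   "+" if i % 2 == 0 else "-", "protein_coding")
        for i in range(6)
    ]
    return GenomeAnnotation(genes=genes)
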