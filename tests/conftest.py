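import textwrap

import pytest

from scdc.annotation import BindingSiteSet, GeneModel


@pytest.fixture
def gff_file(tmp_path):
    """Small GFF3: a two-transcript gene, a two-exon gene, a single-exon
    gene, and a gene with no exon features."""
    content = textwrap.dedent(
        """\
        ##gff-version 3
        X\tsrc\tgene\t100\t300\t.\t+\t.\tID=gene1
        X\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=gene1.t1;Parent=gene1
        X\tsrc\texon\t100\t200\t.\t+\t.\tParent=gene1.t1
        X\tsrc\tmRNA\t150\t300\t.\t+\t.\tID=gene1.t2;Parent=gene1
        X\tsrc\texon\t150\t300\t.\t+\t.\tParent=gene1.t2
        2L\tsrc\tgene\t10\t30\t.\t-\t.\tID=gene2
        2L\tsrc\tmRNA\t10\t30\t.\t-\t.\tID=gene2.t1;Parent=gene2
        2L\tsrc\texon\t10\t19\t.\t-\t.\tParent=gene2.t1
        2L\tsrc\texon\t15\t30\t.\t-\t.\tParent=gene2.t1
        2L\tsrc\tgene\t50\t59\t.\t+\t.\tID=gene3
        2L\tsrc\tmRNA\t50\t59\t.\t+\t.\tID=gene3.t1;Parent=gene3
        2L\tsrc\texon\t50\t59\t.\t+\t.\tParent=gene3.t1
        4\tsrc\tgene\t5\t40\t.\t+\t.\tID=gene4
        """
    )
    path = tmp_path / "genes.gff3"
    path.write_text(content)
    return path


@pytest.fixture
def x_gene():
    return GeneModel(gene_id="g1", chrom="X", start=100, end=200, exonic_length=101)


@pytest.fixture
def mle_sites():
    return BindingSiteSet(
        component="MLE",
        intervals=[("X", 10, 20), ("X", 500, 600)],
    )
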