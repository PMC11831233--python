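import numpy as np
import pytest

from pacscope.annotation import load_annotation


TOY_GTF = """\
#!toy annotation
chr1\ttest\tgene\t1\t2000\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\ttest\ttranscript\t1\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\texon\t1\t400\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\texon\t901\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\tCDS\t101\t400\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\tCDS\t901\t1500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\tthree_prime_utr\t1501\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\ttest\ttranscript\t1\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t2"; tag "retained_intron";
chr1\ttest\texon\t1\t2000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t2";
chr1\ttest\tgene\t5001\t7000\t.\t-\t.\tgene_id "G2"; gene_biotype "protein_coding";
chr1\ttest\ttranscript\t5001\t7000\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\texon\t5001\t5600\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\texon\t6001\t7000\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\tCDS\t5501\t5600\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\tCDS\t6001\t6800\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\tthree_prime_utr\t5001\t5500\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr1\ttest\tgene\t9001\t9600\t.\t+\t.\tgene_id "G3"; gene_biotype "lincRNA";
chr1\ttest\ttranscript\t9001\t9600\t.\t+\t.\tgene_id "G3"; transcript_id "G3.t1";
chr1\ttest\texon\t9001\t9600\t.\t+\t.\tgene_id "G3"; transcript_id "G3.t1";
"""


@pytest.fixture
def toy_gtf_path(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture
def toy_annotation(toy_gtf_path):
    return load_annotation(toy_gtf_path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
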