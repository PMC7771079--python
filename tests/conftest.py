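import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# Two-gene toy annotation, 1-based inclusive GTF coordinates.
# GENEA: transcript t1 with 3 exons of 200 bp, t2 with 2 of them.
# GENEB: single transcript with 2 exons of 300 bp.
# One line uses the unquoted attribute dialect on purpose.
TOY_GTF = """\
chr1\ttoy\tgene\t101\t1100\t.\t+\t.\tgene_id "GENEA"; gene_name "GENEA"; gene_biotype "protein_coding";
chr1\ttoy\texon\t101\t300\t.\t+\t.\tgene_id "GENEA"; transcript_id "GENEA.t1";
chr1\ttoy\texon\t501\t700\t.\t+\t.\tgene_id "GENEA"; transcript_id "GENEA.t1";
chr1\ttoy\texon\t901\t1100\t.\t+\t.\tgene_id "GENEA"; transcript_id "GENEA.t1";
chr1\ttoy\texon\t101\t300\t.\t+\t.\tgene_id GENEA; transcript_id GENEA.t2;
chr1\ttoy\texon\t901\t1100\t.\t+\t.\tgene_id "GENEA"; transcript_id "GENEA.t2";
chr1\ttoy\tgene\t2001\t2900\t.\t-\t.\tgene_id "GENEB"; gene_name "GENEB"; gene_biotype "protein_coding";
chr1\ttoy\texon\t2001\t2300\t.\t-\t.\tgene_id "GENEB"; transcript_id "GENEB.t1";
chr1\ttoy\texon\t2601\t2900\t.\t-\t.\tgene_id "GENEB"; transcript_id "GENEB.t1";
"""

PSEUDO_GTF_LINE = (
    'chr1\ttoy\texon\t5001\t5400\t.\t+\t.\t'
    'gene_id "GENEP"; transcript_id "GENEP.t1"; '
    'gene_biotype "processed_pseudogene";\n'
)


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture
def toy_annotation(toy_gtf):
    from lrfuse import parse_gtf

    return parse_gtf(toy_gtf)
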