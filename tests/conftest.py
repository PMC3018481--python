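import pytest

from tcsorg.records import GeneRecord


def make_gene(tag, start, end, strand="+", replicon="repA", **kw):
    return GeneRecord(
        locus_tag=tag, replicon_id=replicon, start=start, end=end, strand=strand, **kw
    )


@pytest.fixture
def toy_replicon():
    """Four genes: g1-g2 linked cis, g3 linked to g2 in trans, g4 far away."""
    return [
        make_gene("g1", 100, 900, "+"),
        make_gene("g2", 951, 2000, "+"),      # 50 bp from g1, cis
        make_gene("g3", 2021, 3000, "-"),     # 20 bp from g2, trans
        make_gene("g4", 10000, 11000, "+"),   # far: orphan
    ]


@pytest.fixture
def gene_tsv(tmp_path):
    path = tmp_path / "genes.tsv"
    path.write_text(
        "replicon_id\treplicon_type\ttopology\tlocus_tag\tstart\tstop\tstrand\tflags\n"
        "repA\tchromosome\tlinear\tg1\t100\t900\t+\t\n"
        "repA\tchromosome\tlinear\tg2\t951\t2000\t+\t\n"
        "repA\tchromosome\tlinear\tg3\t2021\t3000\t-\tmispredicted\n"
    )
    return path


@pytest.fixture
def domain_tsv(tmp_path):
    path = tmp_path / "domains.tsv"
    path.write_text(
        "locus_tag\tdomain_name\taa_start\taa_end\n"
        "g1\tHisKA\t10\t70\n"
        "g1\tHATPase_c\t80\t180\n"
        "g2\tResponse_reg\t5\t120\n"
        "g3\tPAS\t5\t90\n"
    )
    return path
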