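"""Parsing, gene-name normalization and coordinate handling."""

import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from mitocomp import vocab
from mitocomp.genome_io import (
    DuplicateGeneError, GeneFeature, Mitogenome, ParseError, coding_sequence,
    normalize_gene_name, parse_genbank, read_fasta_with_features,
    write_feature_table, write_fasta, write_genbank,
)


def _gb(body, length, name="TEST"):
    seq = body.replace(" ", "").replace("\n", "")
    assert len(seq) == length
    lines = []
    for i in range(0, length, 60):
        chunk = seq[i:i + 60]
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    origin = "\n".join(lines)
    return origin


def _record(features, seq, name="TEST"):
    origin = _gb(seq, len(seq), name)
    return textwrap.dedent(f"""\
LOCUS       {name}                {len(seq)} bp    DNA     circular INV 01-JAN-2020
DEFINITION  synthetic test record.
ACCESSION   {name}
FEATURES             Location/Qualifiers
{features}ORIGIN
{origin}
//
""")


@pytest.mark.parametrize("raw, anticodon, expected", [
    ("COX1", None, "cox1"),
    ("COI", None, "cox1"),
    ("cox1", None, "cox1"),
    ("ND4L", None, "nad4L"),
    ("CYTB", None, "cob"),
    ("16S ribosomal RNA", None, "rrnL"),
    ("l-rRNA", None, "rrnL"),
    ("12S", None, "rrnS"),
    ("D-loop", None, "CR"),
    ("A+T-rich region", None, "CR"),
    ("tRNA-Ala", None, "trnA"),
    ("tRNA-Ser", "uga", "trnS2"),
    ("tRNA-Ser", "gcu", "trnS1"),
    ("tRNA-Leu", "uaa", "trnL2"),
    ("tRNA-Leu", "uag", "trnL1"),
    ("tRNA-Leu(UUR)", None, "trnL2"),
    ("tRNA-Ser(AGN)", None, "trnS1"),
    ("trnSuga", None, "trnS2"),
    ("trnLuaa", None, "trnL2"),
    ("trnL1", None, "trnL1"),
    ("trnS2", None, "trnS2"),
    ("ORF-314", None, None),
    ("tRNA-Leu", None, None),   # ambiguous isoacceptor is never guessed
    ("tRNA-Ser", None, None),
])
def test_normalize_gene_name(raw, anticodon, expected):
    assert normalize_gene_name(raw, anticodon) == expected


@given(st.sampled_from(vocab.ALL_GENES))
@settings(deadline=None, derandomize=True)
def test_normalize_is_idempotent_on_canonical_names(gene):
    assert normalize_gene_name(gene) == gene


def test_vocabulary_counts():
    classes = [vocab.feature_class(g) for g in vocab.ALL_GENES]
    assert classes.count("PCG") == 13
    assert classes.count("tRNA") == 22
    assert classes.count("rRNA") == 2
    assert classes.count("control") == 1


def test_parse_minimal_cds(tmp_path):
    seq = "ATGAAACCCGGGTTTACGACGACGTAATAA" + "A" * 30
    text = _record('     CDS             1..30\n'
                   '                     /gene="COX1"\n', seq)
    p = tmp_path / "a.gb"
    p.write_text(text)
    g = parse_genbank(p)
    assert len(g.features) == 1
    f = g.features[0]
    assert f.gene == "cox1" and f.strand == "J" and f.spans == [(0, 30)]
    assert coding_sequence(g, "cox1") == seq[:30]


def test_parse_trna_with_anticodon(tmp_path):
    seq = "ATGAAATAA" + "C" * 56 + "G" * 5
    text = _record(
        '     CDS             1..9\n'
        '                     /gene="COX1"\n'
        '     tRNA            10..65\n'
        '                     /product="tRNA-Ser"\n'
        '                     /note="anticodon:uga"\n', seq)
    p = tmp_path / "b.gb"
    p.write_text(text)
    g = parse_genbank(p)
    assert g.feature_for("trnS2").anticodon == "uga"


def test_parse_origin_wrapping_feature(tmp_path):
    # 200 bp circle; gene from 181..200 then 1..30: unwrapped length 50
    seq = "ACGT" * 50
    text = _record('     CDS             join(181..200,1..30)\n'
                   '                     /gene="COX1"\n', seq)
    p = tmp_path / "c.gb"
    p.write_text(text)
    g = parse_genbank(p)
    f = g.feature_for("cox1")
    assert f.length == 50
    assert f.genomic_interval(200) == (180, 230)
    assert coding_sequence(g, "cox1") == seq[180:] + seq[:30]


def test_parse_minus_strand_and_revcomp(tmp_path):
    seq = "AAACCC" + "G" * 54
    text = _record('     CDS             complement(1..6)\n'
                   '                     /gene="ND2"\n'
                   '     CDS             7..60\n'
                   '                     /gene="COX1"\n', seq)
    p = tmp_path / "d.gb"
    p.write_text(text)
    g = parse_genbank(p)
    assert g.feature_for("nad2").strand == "N"
    assert coding_sequence(g, "nad2") == "GGGTTT"


def test_cox1_on_minus_strand_flips_j_labels(tmp_path):
    seq = "A" * 60
    text = _record('     CDS             complement(1..30)\n'
                   '                     /gene="COX1"\n'
                   '     CDS             31..60\n'
                   '                     /gene="ND2"\n', seq)
    p = tmp_path / "e.gb"
    p.write_text(text)
    g = parse_genbank(p)
    assert g.feature_for("cox1").strand == "J"
    assert g.feature_for("nad2").strand == "N"


def test_duplicate_annotation_is_an_error(tmp_path):
    seq = "A" * 60
    text = _record('     CDS             1..30\n'
                   '                     /gene="COX1"\n'
                   '     CDS             31..60\n'
                   '                     /gene="COI"\n', seq)
    p = tmp_path / "f.gb"
    p.write_text(text)
    with pytest.raises(DuplicateGeneError):
        parse_genbank(p)
    g = parse_genbank(p, duplicate_policy="first")
    assert len([f for f in g.features if f.gene == "cox1"]) == 1


def test_coordinate_beyond_length_is_parse_error():
    with pytest.raises(ParseError, match="beyond"):
        Mitogenome(id="X", organism="", sequence="ACGT",
                   features=[GeneFeature("cox1", "J", [(0, 10)])])


def test_unparseable_file_raises(tmp_path):
    p = tmp_path / "junk.gb"
    p.write_text("this is not genbank\n")
    with pytest.raises(ParseError):
        parse_genbank(p)


def test_n_runs_counts_stretches():
    g = Mitogenome(id="X", organism="", sequence="ACGNNNACGNACG")
    assert g.n_runs == 2


def test_fasta_feature_table_roundtrip(tmp_path, base_genome):
    write_fasta(base_genome, tmp_path / "g.fasta")
    write_feature_table(base_genome, tmp_path / "g.tsv")
    g2 = read_fasta_with_features(tmp_path / "g.fasta", tmp_path / "g.tsv",
                                  genome_id=base_genome.id)
    assert g2.sequence == base_genome.sequence
    a = {(f.gene, f.strand, tuple(f.spans)) for f in base_genome.features}
    b = {(f.gene, f.strand, tuple(f.spans)) for f in g2.features}
    assert a == b


def test_genbank_roundtrip_preserves_everything(tmp_path, base_genome):
    write_genbank(base_genome, tmp_path / "g.gb")
    g2 = parse_genbank(tmp_path / "g.gb")
    assert g2.sequence == base_genome.sequence
    assert len(g2.features) == len(base_genome.features)
    for f in base_genome.features:
        f2 = g2.feature_for(f.gene)
        assert (f2.strand, f2.spans) == (f.strand, f.spans)
        assert coding_sequence(g2, f.gene) == coding_sequence(base_genome, f.gene)


def test_coding_sequence_length_equals_span_sum(base_genome):
    for f in base_genome.features:
        assert len(coding_sequence(base_genome, f.gene)) == f.length
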