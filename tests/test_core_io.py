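"""Core types and file-format round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lnclact import io as lio
from lnclact.core import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GenomicInterval,
    SampleDesign,
    TranscriptModel,
    ValidationError,
    gene_spans,
    validate_design,
)


# ---------------------------------------------------------------------------
# GenomicInterval / TranscriptModel
# ---------------------------------------------------------------------------

def test_interval_rejects_degenerate():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 10, 5)
    with pytest.raises(ValidationError):
        GenomicInterval("", 0, 5)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 0, 5, "x")


def test_interval_overlap_is_half_open():
    a = GenomicInterval("chr1", 0, 10)
    assert a.overlaps(GenomicInterval("chr1", 9, 20))
    assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # touching, no overlap
    assert not a.overlaps(GenomicInterval("chr2", 0, 10))
    assert len(a) == 10


def test_transcript_model_invariants():
    e1 = GenomicInterval("chr1", 0, 100, "+")
    e2 = GenomicInterval("chr1", 200, 300, "+")
    t = TranscriptModel("t1", "g1", (e1, e2), "protein_coding")
    assert t.length == 200 and t.n_exons == 2
    assert (t.start, t.end) == (0, 300)
    assert t.span() == GenomicInterval("chr1", 0, 300, "+")
    with pytest.raises(ValidationError):
        TranscriptModel("t2", "g1", (e2, e1))  # unsorted
    with pytest.raises(ValidationError):
        TranscriptModel("t3", "g1", ())
    with pytest.raises(ValidationError):
        TranscriptModel(
            "t4", "g1", (e1, GenomicInterval("chr2", 200, 300, "+"))
        )  # mixed chrom
    with pytest.raises(ValidationError):
        TranscriptModel(
            "t5", "g1", (e1, GenomicInterval("chr1", 200, 300, "-"))
        )  # mixed strand
    with pytest.raises(ValidationError):
        TranscriptModel(
            "t6", "g1", (e1, GenomicInterval("chr1", 50, 300, "+"))
        )  # overlapping exons


def test_gene_spans_unions_transcripts():
    mk = lambda tid, gid, s, e: TranscriptModel(
        tid, gid, (GenomicInterval("chr1", s, e, "+"),)
    )
    df = gene_spans([mk("a", "G", 100, 200), mk("b", "G", 150, 400)])
    assert df.iloc[0].tolist() == ["G", "chr1", 100, 400, "+"]
    with pytest.raises(ValidationError):
        gene_spans(
            [mk("a", "G", 0, 10),
             TranscriptModel("b", "G", (GenomicInterval("chr2", 0, 10, "+"),))]
        )


# ---------------------------------------------------------------------------
# Design / ExpressionMatrix
# ---------------------------------------------------------------------------

def _design():
    return [
        SampleDesign("s1", "B1", "D15", 1),
        SampleDesign("s2", "B1", "D90", 1),
        SampleDesign("s3", "B2", "D15", 1),
    ]


def test_design_uniqueness():
    with pytest.raises(ValidationError):
        validate_design(_design() + [SampleDesign("s1", "B9", "D9", 1)])
    with pytest.raises(ValidationError):
        validate_design(_design() + [SampleDesign("s4", "B1", "D15", 1)])


def test_expression_matrix_validation_and_queries():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], index=["t1", "t2"],
        columns=["s1", "s2", "s3"],
    )
    m = ExpressionMatrix(df, _design())
    assert m.samples_for(breed="B1") == ["s1", "s2"]
    assert m.samples_for(breed="B1", stage="D90") == ["s2"]
    assert m.subset(["t2"]).values.index.tolist() == ["t2"]
    with pytest.raises(KeyError):
        m.subset(["nope"])
    with pytest.raises(ValidationError):
        ExpressionMatrix(df, _design(), unit="tpm")
    with pytest.raises(ValidationError):
        ExpressionMatrix(df.rename(columns={"s3": "sX"}), _design())
    with pytest.raises(ValidationError):
        ExpressionMatrix(-df, _design())
    bad = df.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValidationError):
        ExpressionMatrix(bad, _design())


def test_expression_matrix_reorders_columns_to_design():
    df = pd.DataFrame(
        [[3.0, 1.0, 2.0]], index=["t1"], columns=["s3", "s1", "s2"]
    )
    m = ExpressionMatrix(df, _design())
    assert m.values.columns.tolist() == ["s1", "s2", "s3"]
    assert m.values.loc["t1"].tolist() == [1.0, 2.0, 3.0]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def test_gtf_round_trip_on_dataset(dataset, tmp_path):
    path = tmp_path / "assembled.gtf"
    lio.write_gtf(dataset.assembled, path)
    back = lio.read_gtf(path)
    original = sorted(dataset.assembled, key=lambda t: (t.chrom, t.start, t.transcript_id))
    assert len(back) == len(original)
    for a, b in zip(back, original):
        assert a.transcript_id == b.transcript_id
        assert a.gene_id == b.gene_id
        assert a.exons == b.exons
        assert a.biotype == b.biotype


def test_gtf_coordinates_are_one_based_inclusive(tmp_path):
    t = TranscriptModel(
        "t1", "g1", (GenomicInterval("chr1", 0, 100, "+"),), "protein_coding"
    )
    path = tmp_path / "x.gtf"
    lio.write_gtf([t], path)
    row = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
    fields = row.split("\t")
    assert (fields[3], fields[4]) == ("1", "100")
    assert lio.read_gtf(path)[0].exons[0] == t.exons[0]


def test_gtf_parse_errors(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text("chr1\tsrc\texon\t1\t100\t.\t+\t.\n")  # 8 columns
    with pytest.raises(lio.GtfParseError, match="line 1"):
        lio.read_gtf(p)
    p.write_text('chr1\tsrc\texon\tx\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
    with pytest.raises(lio.GtfParseError, match="non-integer"):
        lio.read_gtf(p)
    p.write_text('chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g";\n')
    with pytest.raises(lio.GtfParseError, match="transcript_id"):
        lio.read_gtf(p)
    p.write_text('chr1\tsrc\tCDS\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
    assert lio.read_gtf(p) == []  # non-exon rows ignored


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data())
def test_gtf_round_trip_property(data, tmp_path_factory):
    n = data.draw(st.integers(1, 8))
    transcripts = []
    for i in range(n):
        strand = data.draw(st.sampled_from("+-"))
        n_ex = data.draw(st.integers(1, 4))
        pos = data.draw(st.integers(0, 1000))
        exons = []
        for _ in range(n_ex):
            length = data.draw(st.integers(1, 300))
            exons.append(GenomicInterval("chr1", pos, pos + length, strand))
            pos += length + data.draw(st.integers(1, 500))
        transcripts.append(
            TranscriptModel(f"t{i}", f"g{i}", tuple(exons),
                            data.draw(st.sampled_from(["protein_coding", "lncRNA", "unknown"])))
        )
    path = tmp_path_factory.mktemp("gtfprop") / "t.gtf"
    lio.write_gtf(transcripts, path)
    back = {t.transcript_id: t for t in lio.read_gtf(path)}
    assert len(back) == len(transcripts)
    for t in transcripts:
        assert back[t.transcript_id].exons == t.exons
        assert back[t.transcript_id].biotype == t.biotype


def test_bed6_export(tmp_path):
    t = TranscriptModel(
        "t1", "g1",
        (GenomicInterval("chr2", 10, 20, "-"), GenomicInterval("chr2", 30, 40, "-")),
    )
    path = tmp_path / "x.bed"
    lio.write_bed6([t], path)
    assert path.read_text() == "chr2\t10\t40\tt1\t0\t-\n"


# ---------------------------------------------------------------------------
# FASTA / design / expression / GMT / Ct
# ---------------------------------------------------------------------------

def test_fasta_round_trip_and_normalization(tmp_path):
    path = tmp_path / "x.fa"
    lio.write_fasta({"a": "ACGT", "b": "TTTTTTTTTT"}, path)
    assert lio.read_fasta(path) == {"a": "ACGT", "b": "TTTTTTTTTT"}
    path.write_text(">u\nacgu\n")
    assert lio.read_fasta(path) == {"u": "ACGT"}  # upper-cased, U -> T
    path.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(ValidationError, match="duplicate"):
        lio.read_fasta(path)


def test_design_round_trip(tmp_path):
    path = tmp_path / "design.tsv"
    lio.write_design(_design(), path)
    assert lio.read_design(path) == _design()


def test_read_expression_rejects_unknown_sample(tmp_path):
    lio.write_design(_design(), tmp_path / "design.tsv")
    df = pd.DataFrame([[1.0, 2.0]], index=pd.Index(["t1"], name="transcript_id"),
                      columns=["s1", "sZ"])
    df.to_csv(tmp_path / "expr.tsv", sep="\t")
    with pytest.raises(ValidationError, match="absent from design"):
        lio.read_expression(tmp_path / "expr.tsv", tmp_path / "design.tsv")


def test_expression_round_trip(dataset, tmp_path):
    lio.write_expression(dataset.expression, tmp_path / "e.tsv")
    lio.write_design(dataset.expression.samples, tmp_path / "d.tsv")
    back = lio.read_expression(tmp_path / "e.tsv", tmp_path / "d.tsv")
    assert np.allclose(back.values.to_numpy(), dataset.expression.values.to_numpy(),
                       rtol=1e-12)
    assert back.samples == dataset.expression.samples


def test_gmt_round_trip_and_categories(tmp_path):
    sets = GeneSetCollection(
        [
            GeneSet("S1", frozenset({"A", "B"}), "BP:growth", "BP"),
            GeneSet("S2", frozenset({"C"}), "pathway:lipid", "pathway"),
            GeneSet("S3", frozenset({"D"}), "free text", "other"),
        ]
    )
    path = tmp_path / "x.gmt"
    lio.write_gmt(sets, path)
    back = lio.read_gmt(path)
    assert back.names() == ["S1", "S2", "S3"]
    assert back["S1"].category == "BP" and back["S1"].genes == frozenset({"A", "B"})
    assert back["S2"].category == "pathway"
    assert back["S3"].category == "other"
    path.write_text("only_two\tcols\n")
    with pytest.raises(ValidationError, match=">=3"):
        lio.read_gmt(path)


def test_ct_table_validation(tmp_path):
    p = tmp_path / "ct.tsv"
    pd.DataFrame(
        {"sample_id": ["s1"], "gene_id": ["g"], "replicate": [1], "ct": [24.0]}
    ).to_csv(p, sep="\t", index=False)
    df = lio.read_ct_table(p)
    assert not df["censored"].iloc[0]
    pd.DataFrame(
        {"sample_id": ["s1"], "gene_id": ["g"], "replicate": [1], "ct": [46.0]}
    ).to_csv(p, sep="\t", index=False)
    with pytest.raises(ValidationError, match=r"\(0, 45\]"):
        lio.read_ct_table(p)


def test_gene_list_round_trip(tmp_path):
    p = tmp_path / "genes.txt"
    lio.write_gene_list(["LALBA", "FASN"], p)
    p.write_text(p.read_text() + "# comment\n\n")
    assert lio.read_gene_list(p) == ["LALBA", "FASN"]
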