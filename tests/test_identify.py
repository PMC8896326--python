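"""Triage cascade and positional classification."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import positional_oracle
from lnclact.core import GenomicInterval, TranscriptModel, ValidationError
from lnclact.identify import (
    accept_lncrnas,
    classify_all,
    plot_summary,
    positional_class,
    summarize_features,
    triage,
)


def _tx(tid, gid, chrom, strand, exon_pairs, biotype="unknown"):
    return TranscriptModel(
        tid, gid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs),
        biotype,
    )


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

REFERENCE = [
    _tx("ref_cod", "GC", "chr1", "+", [(1000, 1200), (2000, 2200)], "protein_coding"),
    _tx("ref_mir", "GM", "chr1", "+", [(5000, 5080)], "miRNA"),
    _tx("ref_lnc", "GL", "chr1", "-", [(8000, 8200), (9000, 9200)], "lncRNA"),
]


def test_triage_cascade_order_and_fates():
    assembled = [
        # same-strand exonic overlap with coding -> removed first, even though
        # it is also short
        _tx("a_cod", "x1", "chr1", "+", [(1100, 1150)]),
        # opposite strand over a coding exon survives the coding filter
        _tx("a_anti", "x2", "chr1", "-", [(1100, 1300), (1500, 1700)]),
        # overlap with a small ncRNA is removed regardless of strand
        _tx("a_small", "x3", "chr1", "-", [(5010, 5380)]),
        # same-strand overlap with an annotated lncRNA is retained
        _tx("a_known", "x4", "chr1", "-", [(8100, 8150)]),
        # short
        _tx("a_short", "x5", "chr1", "+", [(20000, 20090), (21000, 21090)]),
        # single exon
        _tx("a_single", "x6", "chr1", "+", [(30000, 30500)]),
        # clean candidate
        _tx("a_cand", "x7", "chr1", "+", [(40000, 40200), (41000, 41200)]),
    ]
    fates = {d.transcript_id: d.fate for d in triage(assembled, REFERENCE)}
    assert fates == {
        "a_cod": "known_coding_removed",
        "a_anti": "candidate_for_coding_potential",
        "a_small": "small_ncRNA_removed",
        "a_known": "known_lncRNA_retained",
        "a_short": "too_short_removed",
        "a_single": "too_few_exons_removed",
        "a_cand": "candidate_for_coding_potential",
    }


def test_triage_rejects_empty_input():
    with pytest.raises(ValidationError):
        triage([], REFERENCE)


def test_triage_thresholds_are_parameters():
    assembled = [_tx("a", "x", "chr1", "+", [(40000, 40150)])]
    assert triage(assembled, REFERENCE, min_length=150, min_exons=1)[0].fate == (
        "candidate_for_coding_potential"
    )
    assert triage(assembled, REFERENCE, min_length=151, min_exons=1)[0].fate == (
        "too_short_removed"
    )


def test_triage_on_dataset_matches_planted_kinds(dataset):
    decisions = {d.transcript_id: d.fate for d in triage(dataset.assembled, dataset.reference)}
    truth = dataset.truth.transcripts.set_index("transcript_id")
    for tid, fate in decisions.items():
        kind = truth.loc[tid, "kind"]
        if kind == "coding":
            assert fate == "known_coding_removed"
        elif kind == "small_ncRNA":
            assert fate == "small_ncRNA_removed"
        elif truth.loc[tid, "is_known_lncrna"]:
            assert fate == "known_lncRNA_retained"
        else:
            assert fate == "candidate_for_coding_potential"


def test_accept_lncrnas_resolution():
    decisions = triage(
        [
            _tx("a_known", "x4", "chr1", "-", [(8100, 8150)]),
            _tx("a_cand", "x7", "chr1", "+", [(40000, 40200), (41000, 41200)]),
            _tx("a_bad", "x8", "chr1", "+", [(50000, 50200), (51000, 51200)]),
        ],
        REFERENCE,
    )
    accepted, updated = accept_lncrnas(decisions, {"a_cand": True, "a_bad": False})
    assert accepted == ["a_known", "a_cand"]
    fates = {d.transcript_id: d.fate for d in updated}
    assert fates["a_cand"] == "lncRNA_accepted"
    assert fates["a_bad"] == "coding_potential_rejected"
    with pytest.raises(KeyError):
        accept_lncrnas(decisions, {"a_cand": True})


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

CODING = [
    _tx("tA", "GA", "chr1", "+", [(10000, 10500), (12000, 12500), (14000, 14500)],
        "protein_coding"),
    _tx("tB", "GB", "chr1", "-", [(30000, 30400), (32000, 32400)], "protein_coding"),
]


@pytest.mark.parametrize(
    "exons,strand,expected,gene",
    [
        # exon-exon overlap, same strand
        ([(10400, 10600), (11000, 11200)], "+", "sense_overlapping", "GA"),
        # exon-exon overlap, opposite strand
        ([(10400, 10600), (11000, 11200)], "-", "antisense", "GA"),
        # within the gene span, no exon overlap, either strand -> intronic
        ([(10600, 10800), (11000, 11400)], "+", "intronic", "GA"),
        ([(10600, 10800), (11000, 11400)], "-", "intronic", "GA"),
        # straddles the same-strand gene span without exon overlap
        ([(9000, 9400), (10600, 10900)], "+", "sense_overlapping", "GA"),
        # same geometry on the opposite strand is NOT sense-overlapping;
        # with no containment either, it is intergenic
        ([(9000, 9400), (10600, 10900)], "-", "intergenic", None),
        # far from everything
        ([(50000, 50300), (51000, 51300)], "+", "intergenic", None),
    ],
)
def test_positional_rules(exons, strand, expected, gene):
    lnc = _tx("L", "XL", "chr1", strand, exons)
    pc = positional_class(lnc, CODING)
    assert pc.positional_class == expected
    assert pc.evidence_gene == gene


def test_positional_requires_strand():
    lnc = _tx("L", "XL", "chr1", ".", [(0, 100), (200, 400)])
    with pytest.raises(ValidationError):
        positional_class(lnc, CODING)


def test_positional_class_matches_truth_on_dataset(dataset):
    coding = [t for t in dataset.reference if t.biotype == "protein_coding"]
    truth = dataset.truth.transcripts
    lnc_truth = truth[truth["kind"] == "lncRNA"].set_index("transcript_id")
    lncs = [t for t in dataset.assembled if t.transcript_id in lnc_truth.index]
    classes = classify_all(lncs, coding).set_index("transcript_id")
    for tid in lnc_truth.index:
        assert classes.loc[tid, "class"] == lnc_truth.loc[tid, "positional_class"]


def test_positional_matches_per_base_oracle_random_layouts():
    rng = np.random.default_rng(21)
    for _ in range(200):
        codings = []
        for g in range(int(rng.integers(1, 4))):
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, 4000))
            exons, pos = [], start
            for _ in range(int(rng.integers(1, 4))):
                e = pos + int(rng.integers(50, 300))
                exons.append((pos, e))
                pos = e + int(rng.integers(50, 600))
            codings.append(_tx(f"t{g}", f"G{g}", "chr1", strand, exons, "protein_coding"))
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, 5000))
        exons, pos = [], start
        for _ in range(int(rng.integers(1, 3))):
            e = pos + int(rng.integers(50, 300))
            exons.append((pos, e))
            pos = e + int(rng.integers(50, 600))
        lnc = _tx("L", "XL", "chr1", strand, exons)
        assert positional_class(lnc, codings).positional_class == positional_oracle(
            lnc, codings
        )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_summarize_and_plot(dataset, tmp_path):
    lnc_ids = set(dataset.truth.lncrna_ids())
    lncs = [t for t in dataset.assembled if t.transcript_id in lnc_ids]
    mrnas = [t for t in dataset.assembled if t.biotype == "protein_coding"]
    summary = summarize_features(lncs, mrnas, dataset.expression)
    assert set(summary) == {"length", "exons", "expression"}
    assert summary["length"]["count"].sum() == len(lncs) + len(mrnas)
    # lncRNAs are shorter and less expressed than mRNAs by construction
    expr = summary["expression"].set_index("group")["mean_value"]
    assert expr["lncRNA"] < expr["mRNA"]
    png = tmp_path / "summary.png"
    plot_summary(summary, str(png))
    assert png.stat().st_size > 0
    with pytest.raises(ValidationError):
        summarize_features([], mrnas)
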