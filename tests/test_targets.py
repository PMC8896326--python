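"""Cis targets, correlations, trans targets and the panel network."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import cis_oracle, spearman_oracle
from lnclact.core import GenomicInterval, TranscriptModel, ValidationError, gene_spans
from lnclact.targets import (
    DEFAULT_MILK_PANEL,
    cis_targets,
    cis_targets_frame,
    correlation,
    edges_frame,
    export_graphml,
    panel_network,
    trans_targets,
)


def _tx(tid, gid, chrom, strand, exon_pairs, biotype="protein_coding"):
    return TranscriptModel(
        tid, gid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs),
        biotype,
    )


# ---------------------------------------------------------------------------
# Cis targets
# ---------------------------------------------------------------------------

CODING = [
    _tx("t1", "G_LEFT", "chr1", "+", [(10_000, 20_000)]),
    _tx("t2", "G_RIGHT", "chr1", "-", [(150_000, 160_000)]),
    _tx("t3", "G_FAR", "chr1", "+", [(500_000, 510_000)]),
    _tx("t4", "G_OTHER", "chr2", "+", [(10_000, 20_000)]),
]


def test_cis_upstream_downstream_within_window():
    lnc = _tx("L", "XL", "chr1", "+", [(100_000, 100_500), (101_000, 102_000)], "unknown")
    hits = cis_targets([lnc], CODING, window=100_000)
    got = {(h.gene_id, h.side, h.distance) for h in hits}
    assert got == {("G_LEFT", "upstream", 80_000), ("G_RIGHT", "downstream", 48_000)}


def test_cis_window_excludes_distant_genes():
    lnc = _tx("L", "XL", "chr1", "+", [(300_000, 300_500), (301_000, 302_000)], "unknown")
    hits = cis_targets([lnc], CODING, window=100_000)
    # G_RIGHT ends 160k (gap 140k > window), G_FAR starts 500k (gap 198k)
    assert hits == []
    hits = cis_targets([lnc], CODING, window=200_000)
    assert {(h.gene_id, h.side) for h in hits} == {
        ("G_RIGHT", "upstream"), ("G_FAR", "downstream")
    }


def test_cis_overlap_distance_zero():
    lnc = _tx("L", "XL", "chr1", "-", [(15_000, 15_400), (16_000, 16_500)], "unknown")
    hits = cis_targets([lnc], CODING, window=100_000)
    assert ("G_LEFT", "overlapping", 0) in {
        (h.gene_id, h.side, h.distance) for h in hits
    }


def test_cis_requires_positive_window():
    with pytest.raises(ValidationError):
        cis_targets([], CODING, window=0)


def test_cis_matches_all_pairs_oracle():
    rng = np.random.default_rng(33)
    for _ in range(150):
        coding = []
        pos = 0
        for g in range(int(rng.integers(1, 8))):
            start = pos + int(rng.integers(0, 50_000))
            end = start + int(rng.integers(1_000, 30_000))
            coding.append(_tx(f"t{g}", f"G{g}", "chr1", "+", [(start, end)]))
            pos = end
        lnc_start = int(rng.integers(0, pos + 100_000))
        lnc = _tx("L", "XL", "chr1", "+",
                  [(lnc_start, lnc_start + 500), (lnc_start + 1_000, lnc_start + 1_500)],
                  "unknown")
        window = int(rng.integers(1_000, 150_000))
        got = {
            (h.gene_id, h.side, h.distance)
            for h in cis_targets([lnc], coding, window=window)
        }
        spans = gene_spans(coding)
        rows = [
            (r.gene_id, r.chrom, r.start, r.end) for r in spans.itertuples()
        ]
        assert got == cis_oracle(lnc, rows, window)


def test_cis_targets_frame_columns():
    lnc = _tx("L", "XL", "chr1", "+", [(100_000, 102_000)], "unknown")
    df = cis_targets_frame(cis_targets([lnc], CODING))
    assert list(df.columns) == ["lncrna_id", "gene_id", "side", "distance"]


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def test_pearson_matches_scipy():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=30), rng.normal(size=30)
    r, p = correlation(x, y, method="pearson")
    rs, ps = stats.pearsonr(x, y)
    assert r == pytest.approx(rs) and p == pytest.approx(ps)


def test_spearman_exact_p_matches_enumeration():
    rng = np.random.default_rng(8)
    for n in (4, 5, 6):
        for _ in range(10):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:
                y[0] = y[1]  # exercise ties
            r, p = correlation(x, y, method="spearman")
            r_o, p_o = spearman_oracle(x, y)
            assert r == pytest.approx(r_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)


def test_spearman_perfect_monotone():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.0, 4.0, 9.0, 16.0, 30.0, 100.0]
    r, p = correlation(x, y, method="spearman")
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(2 / 720)  # only the two extreme orderings


def test_correlation_edge_cases():
    assert correlation([1, 1, 1], [1, 2, 3])[0] != correlation([1, 1, 1], [1, 2, 3])[0]  # nan
    assert correlation([1, 1, 1], [1, 2, 3])[1] == 1.0
    with pytest.raises(ValidationError):
        correlation([1, 2], [1, 2])
    with pytest.raises(ValidationError):
        correlation([1, 2, np.inf], [1, 2, 3])
    with pytest.raises(ValidationError):
        correlation([1, 2, 3], [1, 2, 3], method="kendall")


# ---------------------------------------------------------------------------
# Trans targets
# ---------------------------------------------------------------------------

def _expr_frames():
    rng = np.random.default_rng(12)
    cols = [f"s{i}" for i in range(9)]
    base = rng.normal(size=9)
    lnc = pd.DataFrame(
        {c: v for c, v in zip(cols, 2.0 ** (base + rng.normal(0, 0.05, 9)))},
        index=["L1"],
    )
    genes = pd.DataFrame(
        np.vstack([
            2.0 ** (base + rng.normal(0, 0.05, 9)),      # tracks L1
            2.0 ** (-base + rng.normal(0, 0.05, 9)),     # anti-tracks L1
            2.0 ** rng.normal(size=9),                   # independent
        ]),
        index=["G_POS", "G_NEG", "G_NULL"], columns=cols,
    )
    return lnc, genes


def test_trans_targets_thresholds_and_signs():
    lnc, genes = _expr_frames()
    edges = trans_targets(lnc, genes, r_min=0.9, p_max=0.05)
    by_gene = {e.gene_id: e for e in edges}
    assert set(by_gene) == {"G_POS", "G_NEG"}
    assert by_gene["G_POS"].sign == "positive"
    assert by_gene["G_NEG"].sign == "negative"
    assert all(abs(e.r) >= 0.9 and e.p_value < 0.05 for e in edges)
    assert all(e.relation == "trans_target" for e in edges)


def test_trans_targets_requires_shared_columns():
    lnc, genes = _expr_frames()
    with pytest.raises(ValidationError):
        trans_targets(lnc, genes[reversed(genes.columns)])


# ---------------------------------------------------------------------------
# Panel network
# ---------------------------------------------------------------------------

def test_panel_network_counts_signs():
    lnc, genes = _expr_frames()
    edges, summary = panel_network(lnc, genes, alpha=0.05)
    assert summary.loc[0, "edges"] == len(edges)
    assert summary.loc[0, "positive"] == sum(e.sign == "positive" for e in edges)
    assert summary.loc[0, "negative"] == sum(e.sign == "negative" for e in edges)
    assert {e.gene_id for e in edges} == {"G_POS", "G_NEG"}
    assert all(e.fdr < 0.05 for e in edges)
    with pytest.raises(ValidationError):
        panel_network(lnc, genes.iloc[0:0], alpha=0.05)


def test_panel_default_list():
    assert len(DEFAULT_MILK_PANEL) == 20
    assert "LALBA" in DEFAULT_MILK_PANEL


def test_edges_frame_and_graphml(tmp_path):
    import networkx as nx

    lnc, genes = _expr_frames()
    edges, _ = panel_network(lnc, genes, alpha=0.05)
    df = edges_frame(edges)
    assert list(df.columns) == [
        "lncrna_id", "gene_id", "method", "r", "p_value", "fdr", "sign", "relation"
    ]
    path = tmp_path / "net.graphml"
    export_graphml(edges, str(path))
    g = nx.read_graphml(path)
    assert g.number_of_edges() == len(edges)
    assert g.nodes["L1"]["kind"] == "lncRNA"


def test_planted_edges_recovered_on_dataset(dataset):
    """Every planted lncRNA-panel edge is recovered in at least one breed.

    Correlations run on log2(FPKM + eps), the scale the pipeline uses for
    the Pearson network.
    """
    edges_truth = dataset.truth.edges
    vals = np.log2(dataset.expression.values + 0.01)
    found = set()
    for breed in dataset.config.breeds:
        cols = dataset.expression.samples_for(breed=breed)
        lnc = vals.loc[sorted(set(edges_truth["lncrna_id"])), cols]
        genes = vals.loc[sorted(set(edges_truth["gene_transcript_id"])), cols]
        edges, _ = panel_network(lnc, genes, alpha=0.05)
        for e in edges:
            found.add((e.lncrna_id, e.gene_id))
    for row in edges_truth.itertuples():
        assert (row.lncrna_id, row.gene_transcript_id) in found
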