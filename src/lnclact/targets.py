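"""Cis/trans target prediction and the signed co-expression network.

Cis targets are the nearest protein-coding neighbors within a genomic
window (default 100 kb) on each side of a lncRNA locus.  Trans targets are
differentially expressed genes whose expression tracks a DE lncRNA across
samples (Spearman |rho| >= 0.9, p < 0.05).  The panel network correlates DE
lncRNAs with a curated milk quality/yield candidate-gene panel (Pearson,
BH-FDR), recording edge signs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TranscriptModel, ValidationError, gene_spans

#: Milk quality and yield candidate genes named in the bovine lactation
#: literature; editable default panel, users may extend or replace it.
DEFAULT_MILK_PANEL = (
    "GPAM", "LPL", "ABCG2", "LALBA", "UGCG", "VLDLR", "SREBF1", "PPARG",
    "SGPL1", "SCAP", "FASN", "SPTLC1", "BDH1", "SLC2A8", "CSNK1", "NOS2",
    "MFGE8", "LIPIN1", "THRSP", "ESRRA",
)


@dataclass
class CisTarget:
    lncrna_id: str
    gene_id: str
    side: str  # upstream | downstream | overlapping
    distance: int


def cis_targets(
    lncrnas: Sequence[TranscriptModel],
    coding_transcripts: Sequence[TranscriptModel],
    window: int = 100_000,
) -> list[CisTarget]:
    """Nearest protein-coding gene on each genomic side within ``window``.

    Upstream means the nearest gene span ending at or before the lncRNA
    span start (genomic left); downstream the nearest starting at or after
    its end (genomic right), irrespective of strand.  Genes whose span
    overlaps the lncRNA span are reported with distance 0 and side
    ``overlapping``.  Ties break by smallest gene start.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    spans = gene_spans(coding_transcripts)
    by_chrom = {c: g.sort_values(["start", "gene_id"]) for c, g in spans.groupby("chrom")}
    out: list[CisTarget] = []
    for lnc in lncrnas:
        genes = by_chrom.get(lnc.chrom)
        if genes is None:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        ids = genes["gene_id"].to_numpy()
        overlap = (starts < lnc.end) & (ends > lnc.start)
        for gid in sorted(ids[overlap], key=lambda g: int(starts[ids == g][0])):
            out.append(CisTarget(lnc.transcript_id, gid, "overlapping", 0))
        left = ~overlap & (ends <= lnc.start)
        if left.any():
            gaps = lnc.start - ends[left]
            best = gaps.min()
            if best <= window:
                cand = sorted(
                    zip(gaps, starts[left], ids[left]), key=lambda x: (x[0], x[1])
                )
                g = cand[0]
                out.append(CisTarget(lnc.transcript_id, str(g[2]), "upstream", int(g[0])))
        right = ~overlap & (starts >= lnc.end)
        if right.any():
            gaps = starts[right] - lnc.end
            best = gaps.min()
            if best <= window:
                cand = sorted(
                    zip(gaps, starts[right], ids[right]), key=lambda x: (x[0], x[1])
                )
                g = cand[0]
                out.append(CisTarget(lnc.transcript_id, str(g[2]), "downstream", int(g[0])))
    return out


def cis_targets_frame(targets: Sequence[CisTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.lncrna_id, t.gene_id, t.side, t.distance) for t in targets],
        columns=["lncrna_id", "gene_id", "side", "distance"],
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 9


@lru_cache(maxsize=16)
def _rank_permutations(ranks: tuple[float, ...]) -> np.ndarray:
    """All distinct orderings of a rank multiset, centered, as a matrix."""
    perms = np.array(list(itertools.permutations(ranks)), dtype=float)
    return perms - perms.mean(axis=1, keepdims=True)


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (mid-ranks, ties ok)."""
    perms = _rank_permutations(tuple(sorted(yr)))
    xc = xr - xr.mean()
    denom = np.sqrt((xc**2).sum()) * np.sqrt((perms[0] ** 2).sum())
    if denom == 0:
        return 1.0
    rhos = perms @ xc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson uses the t-approximation.  Spearman operates on mid-ranks with
    an exact permutation p for n <= 9 and the t-approximation beyond.  A
    constant vector yields r = nan with p = 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = xa.size
    if n < 3:
        raise ValidationError("correlation requires n >= 3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("correlation inputs must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return float("nan"), 1.0
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
        return float(r), float(p)
    if method == "spearman":
        xr = stats.rankdata(xa)
        yr = stats.rankdata(ya)
        r, p_t = stats.pearsonr(xr, yr)
        if n <= _EXACT_N_MAX:
            return float(r), _spearman_exact_p(xr, yr, float(r))
        return float(r), float(p_t)
    raise ValidationError(f"unknown correlation method {method!r}")


@dataclass
class CorrelationEdge:
    lncrna_id: str
    gene_id: str
    method: str
    r: float
    p_value: float
    fdr: float
    sign: str  # positive | negative
    relation: str  # trans_target | panel_edge


def _edge_sign(r: float) -> str:
    return "positive" if r > 0 else "negative"


def trans_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_min: float = 0.9,
    p_max: float = 0.05,
    method: str = "spearman",
) -> list[CorrelationEdge]:
    """All (lncRNA, gene) pairs with |rho| >= r_min and p < p_max.

    Both expression frames must share the same sample columns (typically
    all samples of one breed).
    """
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise ValidationError("lncRNA and gene matrices must share sample columns")
    edges = []
    gvals = {g: gene_expr.loc[g].to_numpy(dtype=float) for g in gene_expr.index}
    for lid in lnc_expr.index:
        xv = lnc_expr.loc[lid].to_numpy(dtype=float)
        for gid, yv in gvals.items():
            r, p = correlation(xv, yv, method=method)
            if not math.isnan(r) and abs(r) >= r_min and p < p_max:
                edges.append(
                    CorrelationEdge(str(lid), str(gid), method, r, p,
                                    float("nan"), _edge_sign(r), "trans_target")
                )
    return edges


def panel_network(
    lnc_expr: pd.DataFrame,
    panel_expr: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[CorrelationEdge], pd.DataFrame]:
    """Signed Pearson network between lncRNAs and panel genes at BH-FDR < alpha.

    Returns the edge list and a one-row summary with positive/negative edge
    counts.  The FDR family is all lncRNA x panel pairs supplied.
    """
    from .expression import benjamini_hochberg

    if list(lnc_expr.columns) != list(panel_expr.columns):
        raise ValidationError("matrices must share sample columns")
    if panel_expr.empty:
        raise ValidationError("no panel genes present in the expression matrix")
    pairs = []
    for lid in lnc_expr.index:
        xv = lnc_expr.loc[lid].to_numpy(dtype=float)
        for gid in panel_expr.index:
            yv = panel_expr.loc[gid].to_numpy(dtype=float)
            r, p = correlation(xv, yv, method="pearson")
            pairs.append((str(lid), str(gid), r, p))
    pvals = np.array([p for *_, p in pairs])
    fdrs = benjamini_hochberg(pvals)
    edges = [
        CorrelationEdge(lid, gid, "pearson", r, p, float(q), _edge_sign(r), "panel_edge")
        for (lid, gid, r, p), q in zip(pairs, fdrs)
        if not math.isnan(r) and q < alpha
    ]
    n_pos = sum(e.sign == "positive" for e in edges)
    n_neg = len(edges) - n_pos
    summary = pd.DataFrame(
        [{"edges": len(edges), "positive": n_pos, "negative": n_neg}]
    )
    return edges, summary


def edges_frame(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.lncrna_id, e.gene_id, e.method, e.r, e.p_value, e.fdr, e.sign, e.relation)
            for e in edges
        ],
        columns=["lncrna_id", "gene_id", "method", "r", "p_value", "fdr", "sign", "relation"],
    )


def export_graphml(edges: Sequence[CorrelationEdge], path: str) -> None:
    """Write the signed network for graph tools (lncRNAs vs genes, bipartite)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.lncrna_id, kind="lncRNA")
        g.add_node(e.gene_id, kind="gene")
        g.add_edge(e.lncrna_id, e.gene_id, r=e.r, sign=e.sign, relation=e.relation)
    nx.write_graphml(g, path)
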