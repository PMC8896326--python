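"""Hypergeometric over-representation analysis against GO/KEGG-style sets.

Each gene set is tested with the hypergeometric upper tail P(X >= k) of
seeing k target genes in a set of size K drawn from a background of N genes
with a target list of size n.  Significance follows the raw p < alpha rule,
with BH-FDR per category always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection, ValidationError
from .expression import benjamini_hochberg


@dataclass
class EnrichmentRecord:
    set_name: str
    category: str
    k: int  # targets in set
    K: int  # set size within background
    n: int  # target-list size within background
    N: int  # background size
    p_value: float
    fdr: float
    significant: bool


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    target_genes: Sequence[str],
    collection: GeneSetCollection,
    background_genes: Sequence[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of the target list in each gene set.

    Sets are intersected with the background before testing.  The FDR
    family is each category within the collection.
    """
    background = set(background_genes)
    targets = set(target_genes)
    if not background:
        raise ValidationError("background gene set is empty")
    if not targets:
        raise ValidationError("target gene list is empty")
    stray = targets - background
    if stray:
        raise ValidationError(
            f"target genes absent from background: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(targets)
    records = []
    for gs in collection:
        in_bg = gs.genes & background
        if not in_bg:
            continue
        K = len(in_bg)
        k = len(in_bg & targets)
        p = hypergeom_tail(k, K, n, N)
        records.append(
            EnrichmentRecord(gs.name, gs.category, k, K, n, N, p, float("nan"), p < alpha)
        )
    # BH within each category
    by_cat: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_cat.setdefault(r.category, []).append(i)
    for idxs in by_cat.values():
        fdrs = benjamini_hochberg([records[i].p_value for i in idxs])
        for i, q in zip(idxs, fdrs):
            records[i].fdr = float(q)
    return records


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.category, r.k, r.K, r.n, r.N, r.p_value, r.fdr, r.significant)
            for r in records
        ],
        columns=["set_name", "category", "k", "K", "n", "N", "p_value", "fdr", "significant"],
    )
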