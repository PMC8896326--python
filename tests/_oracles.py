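"""Independent reference implementations used only by the tests.

Each oracle is written from the textbook definition, deliberately with a
different algorithm and code structure than the library, so agreement is
meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Longest ORF by exhaustive span enumeration
# ---------------------------------------------------------------------------

def orf_oracle(seq: str) -> tuple[int, int]:
    """(length_nt incl. stop, start) of the longest ATG..stop ORF, ties by
    smallest start; (0, -1) when none exists."""
    s = seq.upper()
    best = (0, -1)
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(s):
            if s[j : j + 3] in STOPS:
                length = j + 3 - i
                if length > best[0] or (length == best[0] and i < best[1]):
                    best = (length, i)
                break
            j += 3
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE, second transcription of the published tables
# ---------------------------------------------------------------------------

# (lower bound, probability) rows, highest bound first; last row is the floor.
_F_POSITION = {
    "A": [(1.9, 0.51), (1.8, 0.55), (1.7, 0.57), (1.6, 0.52), (1.5, 0.48),
          (1.4, 0.58), (1.3, 0.57), (1.2, 0.54), (1.1, 0.50), (0.0, 0.36)],
    "C": [(1.9, 0.29), (1.8, 0.44), (1.7, 0.55), (1.6, 0.49), (1.5, 0.52),
          (1.4, 0.60), (1.3, 0.60), (1.2, 0.56), (1.1, 0.51), (0.0, 0.38)],
    "G": [(1.9, 0.62), (1.8, 0.67), (1.7, 0.74), (1.6, 0.65), (1.5, 0.61),
          (1.4, 0.62), (1.3, 0.66), (1.2, 0.72), (1.1, 0.83), (0.0, 0.51)],
    "T": [(1.9, 0.51), (1.8, 0.60), (1.7, 0.69), (1.6, 0.64), (1.5, 0.62),
          (1.4, 0.67), (1.3, 0.58), (1.2, 0.48), (1.1, 0.39), (0.0, 0.24)],
}
_F_CONTENT = {
    "A": [(0.33, 0.40), (0.31, 0.55), (0.29, 0.58), (0.27, 0.58), (0.25, 0.52),
          (0.23, 0.48), (0.21, 0.45), (0.19, 0.45), (0.17, 0.38), (0.0, 0.19)],
    "C": [(0.33, 0.50), (0.31, 0.63), (0.29, 0.59), (0.27, 0.50), (0.25, 0.41),
          (0.23, 0.30), (0.21, 0.33), (0.19, 0.29), (0.17, 0.33), (0.0, 0.23)],
    "G": [(0.33, 0.21), (0.31, 0.40), (0.29, 0.58), (0.27, 0.58), (0.25, 0.61),
          (0.23, 0.66), (0.21, 0.76), (0.19, 0.83), (0.17, 0.93), (0.0, 0.90)],
    "T": [(0.33, 0.30), (0.31, 0.49), (0.29, 0.56), (0.27, 0.53), (0.25, 0.48),
          (0.23, 0.48), (0.21, 0.34), (0.19, 0.20), (0.17, 0.09), (0.0, 0.09)],
}
_F_WEIGHTS = {
    ("position", "A"): 0.26, ("position", "C"): 0.18,
    ("position", "G"): 0.31, ("position", "T"): 0.33,
    ("content", "A"): 0.11, ("content", "C"): 0.12,
    ("content", "G"): 0.15, ("content", "T"): 0.14,
}


def fickett_oracle(seq: str) -> float:
    s = [b for b in seq.upper()]
    total = 0.0
    counts = {b: [0, 0, 0] for b in "ACGT"}
    for i, b in enumerate(s):
        if b in counts:
            counts[b][i % 3] += 1
    usable = sum(sum(v) for v in counts.values())
    for b in "ACGT":
        pos_val = max(counts[b]) / (min(counts[b]) + 1)
        prob = next(p for bound, p in _F_POSITION[b] if pos_val >= bound)
        total += prob * _F_WEIGHTS[("position", b)]
        frac = (sum(counts[b]) / usable) if usable else 0.0
        prob = next(p for bound, p in _F_CONTENT[b] if frac >= bound)
        total += prob * _F_WEIGHTS[("content", b)]
    return total


# ---------------------------------------------------------------------------
# Positional classification by per-base set arithmetic
# ---------------------------------------------------------------------------

def positional_oracle(lnc, codings) -> str:
    """Class of one lncRNA via explicit per-base overlap sets.

    Mirrors the documented precedence: same-strand exonic overlap, then
    antisense exonic overlap, then containment in a gene span, then a
    same-strand span straddle, else intergenic.
    """
    lnc_bases = set()
    for e in lnc.exons:
        lnc_bases.update(range(e.start, e.end))
    same_exonic = opp_exonic = False
    for c in codings:
        if c.chrom != lnc.chrom:
            continue
        c_bases = set()
        for e in c.exons:
            c_bases.update(range(e.start, e.end))
        if lnc_bases & c_bases:
            if c.strand == lnc.strand:
                same_exonic = True
            else:
                opp_exonic = True
    if same_exonic:
        return "sense_overlapping"
    if opp_exonic:
        return "antisense"
    spans: dict[str, list] = {}
    for c in codings:
        if c.chrom != lnc.chrom:
            continue
        r = spans.setdefault(c.gene_id, [c.start, c.end, c.strand])
        r[0] = min(r[0], c.start)
        r[1] = max(r[1], c.end)
    lnc_span = set(range(lnc.start, lnc.end))
    for s, e, _st in spans.values():
        if lnc_span <= set(range(s, e)):
            return "intronic"
    for s, e, st in spans.values():
        if st == lnc.strand and (lnc_span & set(range(s, e))):
            return "sense_overlapping"
    return "intergenic"


# ---------------------------------------------------------------------------
# Cis targets by an all-pairs scan over gene spans
# ---------------------------------------------------------------------------

def cis_oracle(lnc, gene_span_rows, window) -> set[tuple[str, str, int]]:
    """{(gene_id, side, distance)} from a plain scan over (gene, chrom,
    start, end) rows."""
    out = set()
    left_best = right_best = None
    for gid, chrom, s, e in gene_span_rows:
        if chrom != lnc.chrom:
            continue
        if s < lnc.end and lnc.start < e:
            out.add((gid, "overlapping", 0))
            continue
        if e <= lnc.start:
            gap = lnc.start - e
            key = (gap, s, gid)
            if gap <= window and (left_best is None or key < left_best):
                left_best = key
        if s >= lnc.end:
            gap = s - lnc.end
            key = (gap, s, gid)
            if gap <= window and (right_best is None or key < right_best):
                right_best = key
    if left_best is not None:
        out.add((left_best[2], "upstream", left_best[0]))
    if right_best is not None:
        out.add((right_best[2], "downstream", right_best[0]))
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, textbook formula
# ---------------------------------------------------------------------------

def bh_oracle(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


# ---------------------------------------------------------------------------
# Hypergeometric upper tail by direct enumeration
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


# ---------------------------------------------------------------------------
# Spearman exact two-sided permutation p by full enumeration
# ---------------------------------------------------------------------------

def _midranks(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> tuple[float, float]:
    xr = _midranks(x)
    yr = _midranks(y)
    rho_obs = float(np.corrcoef(xr, yr)[0, 1])
    count = total = 0
    for perm in itertools.permutations(yr):
        rho = float(np.corrcoef(xr, np.asarray(perm))[0, 1])
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return rho_obs, count / total
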