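"""Triage of assembled transcripts into lncRNA candidates, and positional
classification of accepted lncRNAs relative to protein-coding genes.

The triage cascade removes known coding and small-ncRNA transcripts, keeps
annotated lncRNAs, drops short and single-exon models, and forwards the rest
to coding-potential scoring.  Accepted lncRNAs are then classed as
intergenic, intronic, antisense or sense-overlapping.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    SMALL_NCRNA_BIOTYPES,
    ExpressionMatrix,
    TranscriptModel,
    ValidationError,
)

FATES = (
    "known_coding_removed",
    "small_ncRNA_removed",
    "known_lncRNA_retained",
    "too_short_removed",
    "too_few_exons_removed",
    "candidate_for_coding_potential",
    "lncRNA_accepted",
    "coding_potential_rejected",
)

POSITIONAL_CLASSES = ("intergenic", "intronic", "antisense", "sense_overlapping")


@dataclass
class TriageDecision:
    transcript_id: str
    fate: str
    reason: str = ""


@dataclass
class PositionalClass:
    transcript_id: str
    positional_class: str
    evidence_gene: str | None  # overlapping coding gene, None iff intergenic


class _ExonIndex:
    """Sorted exon intervals per (chrom, strand) with overlap queries."""

    def __init__(self, transcripts: Sequence[TranscriptModel]) -> None:
        buckets: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for t in transcripts:
            for e in t.exons:
                buckets.setdefault((e.chrom, e.strand), []).append(
                    (e.start, e.end, t.transcript_id)
                )
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._items: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        self._max_end: dict[tuple[str, str], list[int]] = {}
        for key, ivs in buckets.items():
            ivs.sort()
            self._items[key] = ivs
            self._starts[key] = [iv[0] for iv in ivs]
            # running max of ends lets us prune the left scan
            run = []
            m = 0
            for iv in ivs:
                m = max(m, iv[1])
                run.append(m)
            self._max_end[key] = run

    def overlapping(
        self, chrom: str, start: int, end: int, strands: Sequence[str]
    ) -> list[str]:
        hits = []
        for strand in strands:
            key = (chrom, strand)
            if key not in self._items:
                continue
            starts = self._starts[key]
            items = self._items[key]
            hi = bisect_left(starts, end)
            for i in range(hi - 1, -1, -1):
                if self._max_end[key][i] <= start:
                    break
                if items[i][1] > start:
                    hits.append(items[i][2])
        return hits

    def any_overlap(
        self, transcript: TranscriptModel, strands: Sequence[str]
    ) -> str | None:
        for e in transcript.exons:
            hit = self.overlapping(e.chrom, e.start, e.end, strands)
            if hit:
                return hit[0]
        return None


def _opposite(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise ValidationError("strand-dependent operation requires a stranded feature")


def triage(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    min_length: int = 200,
    min_exons: int = 2,
    small_ncrna_biotypes: frozenset[str] = SMALL_NCRNA_BIOTYPES,
) -> list[TriageDecision]:
    """Assign one fate to each assembled transcript (fates partition the input).

    Test order: (1) exonic same-strand overlap with a reference
    protein-coding transcript, (2) exonic overlap (either strand) with a
    blocklisted small-ncRNA biotype, (3) exonic same-strand overlap with a
    reference lncRNA, (4) spliced length below ``min_length``, (5) exon
    count below ``min_exons``, (6) candidate for coding-potential scoring.
    """
    if not assembled:
        raise ValidationError("assembled transcript set is empty")
    coding_idx = _ExonIndex([t for t in reference if t.biotype == "protein_coding"])
    small_idx = _ExonIndex([t for t in reference if t.biotype in small_ncrna_biotypes])
    lnc_idx = _ExonIndex([t for t in reference if t.biotype == "lncRNA"])
    decisions = []
    for t in assembled:
        strands = (t.strand,) if t.strand in "+-" else ("+", "-", ".")
        hit = coding_idx.any_overlap(t, strands)
        if hit is not None:
            decisions.append(
                TriageDecision(t.transcript_id, "known_coding_removed",
                               f"exonic same-strand overlap with {hit}")
            )
            continue
        hit = small_idx.any_overlap(t, ("+", "-", "."))
        if hit is not None:
            decisions.append(
                TriageDecision(t.transcript_id, "small_ncRNA_removed",
                               f"exonic overlap with small ncRNA {hit}")
            )
            continue
        hit = lnc_idx.any_overlap(t, strands)
        if hit is not None:
            decisions.append(
                TriageDecision(t.transcript_id, "known_lncRNA_retained",
                               f"exonic same-strand overlap with annotated lncRNA {hit}")
            )
            continue
        if t.length < min_length:
            decisions.append(
                TriageDecision(t.transcript_id, "too_short_removed",
                               f"spliced length {t.length} < {min_length}")
            )
            continue
        if t.n_exons < min_exons:
            decisions.append(
                TriageDecision(t.transcript_id, "too_few_exons_removed",
                               f"{t.n_exons} exon(s) < {min_exons}")
            )
            continue
        decisions.append(
            TriageDecision(t.transcript_id, "candidate_for_coding_potential", "")
        )
    return decisions


def accept_lncrnas(
    decisions: Sequence[TriageDecision],
    consensus: Mapping[str, bool],
) -> tuple[list[str], list[TriageDecision]]:
    """Resolve candidates with their consensus calls into the final lncRNA set.

    Retained known lncRNAs are accepted without scoring.  Returns the
    accepted transcript ids and the updated decision list.
    """
    accepted: list[str] = []
    updated: list[TriageDecision] = []
    for d in decisions:
        if d.fate == "known_lncRNA_retained":
            accepted.append(d.transcript_id)
            updated.append(d)
        elif d.fate == "candidate_for_coding_potential":
            if d.transcript_id not in consensus:
                raise KeyError(
                    f"candidate {d.transcript_id!r} lacks a consensus call"
                )
            if consensus[d.transcript_id]:
                accepted.append(d.transcript_id)
                updated.append(
                    TriageDecision(d.transcript_id, "lncRNA_accepted",
                                   "consensus noncoding")
                )
            else:
                updated.append(
                    TriageDecision(d.transcript_id, "coding_potential_rejected",
                                   "at least one predictor voted coding")
                )
        else:
            updated.append(d)
    return accepted, updated


def positional_class(
    lncrna: TranscriptModel,
    coding_transcripts: Sequence[TranscriptModel],
) -> PositionalClass:
    """Classify one lncRNA against protein-coding transcripts.

    Precedence (most specific first):
      1. exon-exon overlap with a same-strand coding transcript
         -> sense_overlapping
      2. exon-exon overlap with an opposite-strand coding transcript
         -> antisense
      3. no exonic overlap but the lncRNA span lies within a coding gene
         span (either strand) -> intronic
      4. no exonic overlap, span straddles (overlaps but is not contained
         in) a same-strand coding gene span -> sense_overlapping
      5. otherwise intergenic
    Ties among multiple overlapping genes break by largest overlap, then
    smallest gene start.
    """
    if lncrna.strand not in "+-":
        raise ValidationError(
            f"{lncrna.transcript_id}: positional classification requires a strand"
        )
    same, opposite = [], []
    for c in coding_transcripts:
        if c.chrom != lncrna.chrom:
            continue
        (same if c.strand == lncrna.strand else opposite).append(c)

    def exon_overlap_bases(c: TranscriptModel) -> int:
        total = 0
        for e in lncrna.exons:
            for ce in c.exons:
                total += max(0, min(e.end, ce.end) - max(e.start, ce.start))
        return total

    def best_gene(cands: list[tuple[int, int, str]]) -> str:
        # (overlap descending, gene start ascending)
        cands.sort(key=lambda x: (-x[0], x[1]))
        return cands[0][2]

    hits = [(exon_overlap_bases(c), c.start, c.gene_id) for c in same]
    hits = [h for h in hits if h[0] > 0]
    if hits:
        return PositionalClass(lncrna.transcript_id, "sense_overlapping", best_gene(hits))
    hits = [(exon_overlap_bases(c), c.start, c.gene_id) for c in opposite]
    hits = [h for h in hits if h[0] > 0]
    if hits:
        return PositionalClass(lncrna.transcript_id, "antisense", best_gene(hits))

    # gene spans (union of transcript spans per gene_id), either strand
    spans: dict[str, list] = {}
    for c in same + opposite:
        r = spans.setdefault(c.gene_id, [c.start, c.end, c.strand])
        r[0] = min(r[0], c.start)
        r[1] = max(r[1], c.end)
    containing = [
        (e - s, s, g)
        for g, (s, e, _st) in spans.items()
        if s <= lncrna.start and lncrna.end <= e
    ]
    if containing:
        containing.sort(key=lambda x: (x[1],))
        return PositionalClass(lncrna.transcript_id, "intronic", containing[0][2])
    straddling = [
        (min(lncrna.end, e) - max(lncrna.start, s), s, g)
        for g, (s, e, st) in spans.items()
        if st == lncrna.strand and s < lncrna.end and lncrna.start < e
    ]
    straddling = [h for h in straddling if h[0] > 0]
    if straddling:
        return PositionalClass(
            lncrna.transcript_id, "sense_overlapping", best_gene(straddling)
        )
    return PositionalClass(lncrna.transcript_id, "intergenic", None)


def classify_all(
    lncrnas: Sequence[TranscriptModel],
    coding_transcripts: Sequence[TranscriptModel],
) -> pd.DataFrame:
    rows = []
    for t in lncrnas:
        pc = positional_class(t, coding_transcripts)
        rows.append((pc.transcript_id, pc.positional_class, pc.evidence_gene or ""))
    return pd.DataFrame(rows, columns=["transcript_id", "class", "evidence_gene"])


def summarize_features(
    lncrnas: Sequence[TranscriptModel],
    mrnas: Sequence[TranscriptModel],
    expression: ExpressionMatrix | None = None,
    length_bins: Sequence[int] = (0, 500, 1000, 2000, 5000, 10**9),
) -> dict[str, pd.DataFrame]:
    """Length, exon-count and mean-expression summaries for lncRNAs vs mRNAs."""
    if not lncrnas or not mrnas:
        raise ValidationError("both transcript sets must be nonempty")
    out: dict[str, pd.DataFrame] = {}
    groups = {"lncRNA": lncrnas, "mRNA": mrnas}
    length_rows, exon_rows, expr_rows = [], [], []
    for name, ts in groups.items():
        lengths = np.array([t.length for t in ts])
        hist, _ = np.histogram(lengths, bins=np.asarray(length_bins))
        for lo, hi, count in zip(length_bins[:-1], length_bins[1:], hist):
            length_rows.append((name, lo, hi, int(count)))
        exon_counts = pd.Series([t.n_exons for t in ts]).value_counts().sort_index()
        for n, count in exon_counts.items():
            exon_rows.append((name, int(n), int(count)))
        if expression is not None:
            ids = [t.transcript_id for t in ts if t.transcript_id in expression.values.index]
            if ids:
                expr_rows.append(
                    (name, float(expression.values.loc[ids].to_numpy().mean()))
                )
    out["length"] = pd.DataFrame(
        length_rows, columns=["group", "bin_start", "bin_end", "count"]
    )
    out["exons"] = pd.DataFrame(exon_rows, columns=["group", "n_exons", "count"])
    if expr_rows:
        out["expression"] = pd.DataFrame(expr_rows, columns=["group", "mean_value"])
    return out


def plot_summary(summary: dict[str, pd.DataFrame], path: str) -> None:
    """Render the feature summary (length / exon / expression panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 + ("expression" in summary)
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.2))
    for group, sub in summary["length"].groupby("group"):
        axes[0].plot(range(len(sub)), sub["count"], marker="o", label=group)
    axes[0].set_xlabel("length bin")
    axes[0].set_ylabel("transcripts")
    axes[0].legend()
    for group, sub in summary["exons"].groupby("group"):
        axes[1].plot(sub["n_exons"], sub["count"], marker="o", label=group)
    axes[1].set_xlabel("exons")
    if "expression" in summary:
        e = summary["expression"]
        axes[2].bar(e["group"], e["mean_value"])
        axes[2].set_ylabel("mean FPKM")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
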