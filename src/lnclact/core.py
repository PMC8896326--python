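"""Domain types shared by every pipeline stage.

Coordinates are 0-based, half-open throughout the package; GTF/GFF I/O
converts to and from the 1-based inclusive convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: Biotypes treated as small noncoding RNA during triage.  Open label set:
#: callers may pass their own blocklist.
SMALL_NCRNA_BIOTYPES = frozenset(
    {"rRNA", "tRNA", "snoRNA", "snRNA", "miRNA", "misc_RNA"}
)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be nonempty")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-structured transcript with a gene assignment and biotype label."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValidationError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        prev_end = None
        for e in exons:
            if prev_end is not None and e.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        """Span start (0-based)."""
        return self.exons[0].start

    @property
    def end(self) -> int:
        """Span end (exclusive)."""
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class SampleDesign:
    """One RNA-seq library: breed x lactation stage x biological replicate."""

    sample_id: str
    breed: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >=1")


def validate_design(samples: Sequence[SampleDesign]) -> None:
    """Check uniqueness of sample ids and (breed, stage, replicate) triples."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in design")
    triples = [(s.breed, s.stage, s.replicate) for s in samples]
    if len(set(triples)) != len(triples):
        raise ValidationError("duplicate (breed, stage, replicate) in design")


class ExpressionMatrix:
    """Transcripts x samples abundance table bound to a sample design.

    ``values`` is a pandas DataFrame indexed by transcript_id with one column
    per sample_id, in the order of ``samples``.  ``unit`` is ``"fpkm"`` or
    ``"counts"``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleDesign],
        unit: str = "fpkm",
    ) -> None:
        if unit not in ("fpkm", "counts"):
            raise ValidationError(f"unit must be 'fpkm' or 'counts': {unit!r}")
        validate_design(samples)
        sample_ids = [s.sample_id for s in samples]
        if list(values.columns) != sample_ids:
            missing = set(sample_ids) - set(values.columns)
            extra = set(values.columns) - set(sample_ids)
            if missing or extra:
                raise ValidationError(
                    f"matrix/design sample mismatch (missing={sorted(missing)}, "
                    f"unmatched={sorted(extra)})"
                )
            values = values[sample_ids]
        if values.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValidationError("expression matrix contains negative values")
        self.values = values
        self.samples = tuple(samples)
        self.unit = unit

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "breed": [s.breed for s in self.samples],
                "stage": [s.stage for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).set_index("sample_id")

    def samples_for(self, breed: str | None = None, stage: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if breed is not None and s.breed != breed:
                continue
            if stage is not None and s.stage != stage:
                continue
            out.append(s.sample_id)
        return out

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(transcript_ids)
        missing = [t for t in ids if t not in self.values.index]
        if missing:
            raise KeyError(f"transcripts absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[ids], self.samples, self.unit)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


class GeneSetCollection:
    """Named gene sets with GMT semantics (unique names, nonempty sets)."""

    def __init__(self, sets: Sequence[GeneSet]) -> None:
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene-set names in collection")
        self._sets = {s.name: s for s in sets}

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def names(self) -> list[str]:
        return list(self._sets)


def gene_spans(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Collapse transcripts to per-gene spans (min start, max end per gene).

    Returns a DataFrame with columns gene_id, chrom, start, end, strand.
    Genes whose transcripts disagree on chrom keep the first chrom seen and
    are flagged via a ValidationError instead: one gene, one locus.
    """
    rows: dict[str, list] = {}
    for t in transcripts:
        if t.gene_id in rows:
            r = rows[t.gene_id]
            if r[0] != t.chrom:
                raise ValidationError(f"gene {t.gene_id} spans multiple chroms")
            r[1] = min(r[1], t.start)
            r[2] = max(r[2], t.end)
        else:
            rows[t.gene_id] = [t.chrom, t.start, t.end, t.strand]
    return pd.DataFrame(
        [(g, *r) for g, r in rows.items()],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
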