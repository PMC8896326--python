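"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF, FASTA, BED6, tab-separated tables (expression, design, Ct) and GMT.
All tables are tab-separated with a header row; missing values are not
permitted in expression matrices.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GenomicInterval,
    SampleDesign,
    TranscriptModel,
    ValidationError,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Malformed GTF input; message names the offending line number."""


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into TranscriptModels.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Biotype is taken from ``transcript_biotype`` then ``gene_biotype``,
    defaulting to ``"unknown"``.  Non-exon feature rows are ignored.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1:
                raise ValidationError(
                    f"{path}: line {lineno}: exon end < start ({end1} < {start1})"
                )
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing transcript_id/gene_id attribute"
                )
            biotype = attr.get("transcript_biotype") or attr.get("gene_biotype") or "unknown"
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            )
            meta[tid] = (gid, biotype)
    out = []
    for tid, ivs in exons.items():
        gid, biotype = meta[tid]
        out.append(
            TranscriptModel(tid, gid, tuple(sorted(ivs, key=lambda e: e.start)), biotype)
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon rows (1-based inclusive coordinates)."""
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        fh.write("#gtf exported by lnclact\n")
        for t in ordered:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tlnclact\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def write_bed6(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Export transcript spans as BED6 (0-based half-open, native)."""
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ordered:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t{t.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {identifier: uppercase DNA string}, U normalized to T.

    Identifiers are the first whitespace token of each header.  Duplicate
    identifiers and empty sequences are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            raise ValidationError(f"{path}: duplicate FASTA identifier {name!r}")
        s = str(rec.seq).upper().replace("U", "T")
        if not s:
            raise ValidationError(f"{path}: empty sequence for {name!r}")
        seqs[name] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: design requires columns {sorted(required)}")
    return [
        SampleDesign(r.sample_id, r.breed, r.stage, int(r.replicate))
        for r in df.itertuples()
    ]


def write_design(samples: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "breed": [s.breed for s in samples],
            "stage": [s.stage for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | Path, design_path: str | Path, unit: str = "fpkm"
) -> ExpressionMatrix:
    """Load an expression TSV (transcript rows, sample columns) plus design.

    Samples must appear in both files; a matrix sample missing from the
    design is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: expression matrix contains missing values")
    design = read_design(design_path)
    design_ids = {s.sample_id for s in design}
    extra = [c for c in df.columns if c not in design_ids]
    if extra:
        raise ValidationError(
            f"{path}: samples absent from design: {extra[:5]}"
        )
    kept = [s for s in design if s.sample_id in df.columns]
    return ExpressionMatrix(df[[s.sample_id for s in kept]], kept, unit)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT: name <tab> description <tab> gene1 <tab> gene2 ...

    A description of the form ``category:...`` assigns the set to a GO/KEGG
    category (BP, MF, CC, pathway); otherwise the category is ``other``.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: line {lineno}: GMT row needs >=3 columns")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            category = "other"
            if ":" in desc:
                head = desc.split(":", 1)[0]
                if head in ("BP", "MF", "CC", "pathway"):
                    category = head
            sets.append(GeneSet(name, frozenset(genes), desc, category))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            desc = s.description or f"{s.category}:"
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{desc}\t{genes}\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: sample_id, gene_id, replicate, ct[, censored]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_id", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: Ct table requires columns {sorted(required)}")
    if "censored" not in df.columns:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)
    if ((df["ct"] <= 0) | (df["ct"] > 45)).any():
        raise ValidationError(f"{path}: Ct values must lie in (0, 45]")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line gene list (e.g. the milk panel)."""
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
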