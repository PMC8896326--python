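"""Synthetic genomes-in-miniature with planted truth.

The generator emulates the statistical structure of a two-breed, three
lactation-stage, three-replicate bovine mammary transcriptome study:

* a miniature annotation of protein-coding genes plus planted lncRNA loci
  of the four positional classes (intergenic, intronic, antisense,
  sense-overlapping) and a few small-ncRNA decoys;
* transcript sequences whose coding/noncoding composition is separable by
  the four coding-potential features (ORF size and coverage, Fickett,
  hexamer bias);
* a log-normal FPKM matrix with planted stage-wise differential expression
  and planted lncRNA-gene correlation edges via a shared latent factor;
* a qPCR Ct table consistent with the expression ratios, normalized to two
  stage-constant reference genes.

All randomness flows through a single seeded generator in a fixed order, so
identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .coding_potential import STOP_CODONS, find_longest_orf
from .core import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GenomicInterval,
    SampleDesign,
    TranscriptModel,
    ValidationError,
)
from .targets import DEFAULT_MILK_PANEL


class GenerationError(RuntimeError):
    """Raised when a requested locus cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a scaled-down 2-breed x 3-stage x 3-replicate design
    with mostly intergenic lncRNA loci, strong planted DE effects and
    high-correlation planted regulatory edges.
    """

    seed: int = 7
    n_chroms: int = 3
    chrom_length: int = 1_500_000
    n_coding_genes: int = 60
    n_lnc_intergenic: int = 20
    n_lnc_intronic: int = 6
    n_lnc_antisense: int = 3
    n_lnc_sense_overlapping: int = 3
    known_lnc_fraction: float = 0.3
    n_small_ncrna: int = 4
    # sequence model
    orf_codons_mean: float = 150.0
    orf_codons_sd: float = 40.0
    noncoding_orf_max_codons: int = 50
    hexamer_sharpness: float = 1.0
    # design
    breeds: tuple[str, ...] = ("Kashmiri", "Jersey")
    stages: tuple[str, ...] = ("D15", "D90", "D250")
    replicates: int = 3
    # expression
    mrna_log2_mean: float = 3.0
    lnc_log2_mean: float = 0.0
    log2_sd: float = 2.0
    de_fraction: float = 0.3
    mrna_de_fraction: float = 0.2
    de_log2fc: float = 2.0
    noise_sd_log2: float = 0.25
    # planted correlation edges
    n_planted_edges: int = 8
    edge_latent_weight: float = 0.9
    edge_latent_scale: float = 2.0
    edge_latent_jitter: float = 0.5
    # qPCR
    qpcr_noise_sd: float = 0.2
    n_qpcr_targets: int = 10
    qpcr_ct_intercept: float = 30.0
    qpcr_scale: float = 8.0
    qpcr_censor_ct: float = 40.0
    reference_fpkm: float = 50.0
    # training sequences for the coding-potential model
    n_training_per_class: int = 200
    training_length_range: tuple[int, int] = (400, 2000)
    # gene sets
    n_gene_sets: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if not 0 < self.edge_latent_weight <= 1:
            raise ValidationError("edge_latent_weight must lie in (0, 1]")
        if self.hexamer_sharpness < 0:
            raise ValidationError("hexamer_sharpness must be >= 0")


@dataclass
class TruthTables:
    """Planted ground truth for every downstream stage."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, kind, is_known_lncrna, positional_class
    de: pd.DataFrame = field(default_factory=pd.DataFrame)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    qpcr_targets: list[str] = field(default_factory=list)

    def lncrna_ids(self) -> list[str]:
        t = self.transcripts
        return list(t.loc[t["kind"] == "lncRNA", "transcript_id"])

    def coding_ids(self) -> list[str]:
        t = self.transcripts
        return list(t.loc[t["kind"] == "coding", "transcript_id"])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
]


def _build_exons(
    chrom: str, start: int, strand: str, exon_lens: Sequence[int], intron_lens: Sequence[int]
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def _overlaps_any(start: int, end: int, placed: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in placed)


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptModel], list[TranscriptModel], TruthTables]:
    """Place coding genes and planted lncRNA/small-ncRNA loci.

    Returns (reference annotation, assembled transcripts, truth tables).
    Coding genes never overlap each other; each planted lncRNA satisfies
    its positional-class definition by construction and has >= 2 exons and
    spliced length >= 200.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    margin = 5_000

    # --- coding genes ------------------------------------------------------
    coding: list[TranscriptModel] = []
    gene_layout: dict[str, list[TranscriptModel]] = {c: [] for c in chroms}
    chrom_i = 0
    pos = margin
    for g in range(config.n_coding_genes):
        n_ex = int(rng.integers(3, 10))
        exon_lens = rng.integers(120, 400, size=n_ex)
        intron_lens = rng.integers(500, 5000, size=n_ex - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        while pos + span > config.chrom_length - margin:
            chrom_i += 1
            pos = margin
            if chrom_i >= len(chroms):
                raise GenerationError(
                    "chromosomes too short for the requested coding genes"
                )
        gid = DEFAULT_MILK_PANEL[g] if g < len(DEFAULT_MILK_PANEL) else f"GCOD{g:04d}"
        t = TranscriptModel(
            f"T_{gid}",
            gid,
            _build_exons(chroms[chrom_i], pos, strand, exon_lens, intron_lens),
            "protein_coding",
        )
        coding.append(t)
        gene_layout[chroms[chrom_i]].append(t)
        pos += span + int(10 ** rng.uniform(3.4, 5.2))

    placed: dict[str, list[tuple[int, int]]] = {
        c: [(t.start, t.end) for t in ts] for c, ts in gene_layout.items()
    }

    def reserve(chrom: str, start: int, end: int) -> None:
        placed[chrom].append((start, end))

    def lnc_geometry() -> tuple[np.ndarray, np.ndarray]:
        n_ex = int(rng.integers(2, 4))
        return rng.integers(150, 400, size=n_ex), rng.integers(300, 1500, size=n_ex - 1)

    lncs: list[TranscriptModel] = []
    lnc_truth_class: dict[str, str] = {}
    lnc_counter = 0

    def add_lnc(exons: tuple[GenomicInterval, ...], cls: str) -> None:
        nonlocal lnc_counter
        lnc_counter += 1
        tid = f"TLNC{lnc_counter:04d}"
        t = TranscriptModel(tid, f"XLOC_{lnc_counter:04d}", exons, "unknown")
        if t.length < 200 or t.n_exons < 2:
            raise GenerationError(f"planted lncRNA violates length/exon floor ({cls})")
        lncs.append(t)
        lnc_truth_class[tid] = cls
        reserve(t.chrom, t.start, t.end)

    max_tries = 400

    # intergenic: inside a gap between gene spans, >= 1 kb clearance
    def gaps_for(chrom: str) -> list[tuple[int, int]]:
        spans = sorted(placed[chrom])
        gaps = []
        prev = margin
        for s, e in spans:
            if s - prev > 0:
                gaps.append((prev, s))
            prev = max(prev, e)
        gaps.append((prev, config.chrom_length - margin))
        return gaps

    for _ in range(config.n_lnc_intergenic):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            exon_lens, intron_lens = lnc_geometry()
            span = int(exon_lens.sum() + intron_lens.sum())
            gaps = [g for g in gaps_for(chrom) if g[1] - g[0] > span + 2_000]
            if not gaps:
                continue
            lo, hi = gaps[int(rng.integers(len(gaps)))]
            start = int(rng.integers(lo + 1_000, hi - span - 1_000))
            if _overlaps_any(start, start + span, placed[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            add_lnc(_build_exons(chrom, start, strand, exon_lens, intron_lens), "intergenic")
            break
        else:
            raise GenerationError("could not place an intergenic lncRNA")

    # intronic: fully inside one intron of a coding gene, either strand
    for _ in range(config.n_lnc_intronic):
        for attempt in range(max_tries):
            host = coding[int(rng.integers(len(coding)))]
            introns = [
                (host.exons[i].end, host.exons[i + 1].start)
                for i in range(host.n_exons - 1)
            ]
            exon_lens = rng.integers(150, 300, size=2)
            intron_lens = rng.integers(200, 400, size=1)
            span = int(exon_lens.sum() + intron_lens.sum())
            fits = [iv for iv in introns if iv[1] - iv[0] > span + 200]
            if not fits:
                continue
            lo, hi = fits[int(rng.integers(len(fits)))]
            start = int(rng.integers(lo + 100, hi - span - 100))
            # other planted features must not collide inside this intron
            others = [p for p in placed[host.chrom] if p != (host.start, host.end)]
            if _overlaps_any(start, start + span, others):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            add_lnc(_build_exons(host.chrom, start, strand, exon_lens, intron_lens), "intronic")
            break
        else:
            raise GenerationError("could not place an intronic lncRNA")

    # antisense: first exon in an intron, second exon overlapping the next
    # coding exon, on the opposite strand
    for _ in range(config.n_lnc_antisense):
        for attempt in range(max_tries):
            host = coding[int(rng.integers(len(coding)))]
            i = int(rng.integers(host.n_exons - 1))
            intron = (host.exons[i].end, host.exons[i + 1].start)
            if intron[1] - intron[0] < 700:
                continue
            target_exon = host.exons[i + 1]
            exon2_start = target_exon.start - 80
            exon2_end = target_exon.start + min(120, len(target_exon) - 1)
            exon1_end = exon2_start - int(rng.integers(250, 450))
            exon1_start = exon1_end - int(rng.integers(150, 300))
            if exon1_start <= intron[0] + 50:
                continue
            others = [p for p in placed[host.chrom] if p != (host.start, host.end)]
            if _overlaps_any(exon1_start, exon2_end, others):
                continue
            strand = "-" if host.strand == "+" else "+"
            exons = (
                GenomicInterval(host.chrom, exon1_start, exon1_end, strand),
                GenomicInterval(host.chrom, exon2_start, exon2_end, strand),
            )
            add_lnc(exons, "antisense")
            break
        else:
            raise GenerationError("could not place an antisense lncRNA")

    # sense-overlapping: straddles the host gene boundary on the same strand
    # (first exon upstream of the gene span, second inside the first intron)
    for _ in range(config.n_lnc_sense_overlapping):
        for attempt in range(max_tries):
            host = coding[int(rng.integers(len(coding)))]
            intron = (host.exons[0].end, host.exons[1].start)
            if intron[1] - intron[0] < 600:
                continue
            exon2_start = intron[0] + 100
            exon2_end = exon2_start + int(rng.integers(150, min(350, intron[1] - intron[0] - 150)))
            exon1_end = host.start - int(rng.integers(300, 800))
            exon1_start = exon1_end - int(rng.integers(150, 300))
            if exon1_start < margin:
                continue
            others = [p for p in placed[host.chrom] if p != (host.start, host.end)]
            if _overlaps_any(exon1_start, host.start, others):
                continue
            exons = (
                GenomicInterval(host.chrom, exon1_start, exon1_end, host.strand),
                GenomicInterval(host.chrom, exon2_start, exon2_end, host.strand),
            )
            add_lnc(exons, "sense_overlapping")
            break
        else:
            raise GenerationError("could not place a sense-overlapping lncRNA")

    # small ncRNA decoys (single short exon, intergenic)
    small: list[TranscriptModel] = []
    small_biotypes = ("tRNA", "rRNA", "snoRNA", "miRNA")
    for j in range(config.n_small_ncrna):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(70, 160))
            gaps = [g for g in gaps_for(chrom) if g[1] - g[0] > length + 2_000]
            if not gaps:
                continue
            lo, hi = gaps[int(rng.integers(len(gaps)))]
            start = int(rng.integers(lo + 1_000, hi - length - 1_000))
            if _overlaps_any(start, start + length, placed[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            t = TranscriptModel(
                f"TSNC{j + 1:03d}",
                f"GSNC{j + 1:03d}",
                (GenomicInterval(chrom, start, start + length, strand),),
                small_biotypes[j % len(small_biotypes)],
            )
            small.append(t)
            reserve(chrom, start, start + length)
            break
        else:
            raise GenerationError("could not place a small ncRNA")

    # known lncRNAs appear in the reference with biotype lncRNA
    n_known = int(round(config.known_lnc_fraction * len(lncs)))
    known_ids = {t.transcript_id for t in lncs[:n_known]}
    reference = list(coding) + list(small) + [
        TranscriptModel(f"REF_{t.transcript_id}", t.gene_id, t.exons, "lncRNA")
        for t in lncs
        if t.transcript_id in known_ids
    ]
    assembled = list(coding) + list(small) + list(lncs)

    rows = []
    for t in coding:
        rows.append((t.transcript_id, t.gene_id, "coding", False, ""))
    for t in small:
        rows.append((t.transcript_id, t.gene_id, "small_ncRNA", False, ""))
    for t in lncs:
        rows.append(
            (
                t.transcript_id,
                t.gene_id,
                "lncRNA",
                t.transcript_id in known_ids,
                lnc_truth_class[t.transcript_id],
            )
        )
    truth = TruthTables(
        transcripts=pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "gene_id",
                "kind",
                "is_known_lncrna",
                "positional_class",
            ],
        )
    )
    return reference, assembled, truth


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass
class SequenceModel:
    """Class-conditional composition models shared by annotation and training.

    Coding: codon usage over the 61 sense codons, a Dirichlet draw sharpened
    by ``hexamer_sharpness`` (sharpness 0 gives the uniform table, so the
    coding and noncoding compositions converge).  Noncoding: a first-order
    Markov background chain, likewise sharpened.
    """

    codon_weights: np.ndarray
    transition: np.ndarray  # 4x4 row-stochastic
    initial: np.ndarray


def _sharpen(weights: np.ndarray, sharpness: float) -> np.ndarray:
    w = np.power(weights, sharpness)
    return w / w.sum(axis=-1, keepdims=True)


def build_sequence_model(
    config: SimulationConfig, rng: np.random.Generator
) -> SequenceModel:
    codon = _sharpen(rng.dirichlet(np.ones(len(_SENSE_CODONS))), config.hexamer_sharpness)
    trans = _sharpen(rng.dirichlet(np.ones(4), size=4), config.hexamer_sharpness)
    init = np.full(4, 0.25)
    return SequenceModel(codon, trans, init)


def _markov_sequence(model: SequenceModel, length: int, rng: np.random.Generator) -> str:
    cum = np.cumsum(model.transition, axis=1)
    u = rng.random(length)
    idx = np.empty(length, dtype=int)
    idx[0] = int(np.searchsorted(np.cumsum(model.initial), u[0]))
    for i in range(1, length):
        idx[i] = int(np.searchsorted(cum[idx[i - 1]], u[i]))
    np.clip(idx, 0, 3, out=idx)
    return "".join(_BASES[idx])


def _cap_orfs(seq: str, max_codons: int, max_iter: int = 300) -> str:
    """Break any ORF longer than the cap by inserting an in-frame stop."""
    cap_nt = max_codons * 3
    s = list(seq)
    for _ in range(max_iter):
        orf = find_longest_orf("".join(s))
        if orf.length_nt <= cap_nt:
            return "".join(s)
        cut = orf.start + (max_codons - 1) * 3
        s[cut : cut + 3] = list("TAA")
    raise GenerationError("failed to cap noncoding ORFs")


def generate_noncoding_sequence(
    model: SequenceModel, length: int, max_codons: int, rng: np.random.Generator
) -> str:
    return _cap_orfs(_markov_sequence(model, length, rng), max_codons)


def generate_coding_sequence(
    model: SequenceModel,
    length: int,
    orf_codons: int,
    rng: np.random.Generator,
) -> str:
    """UTR5 + ATG + biased sense codons + stop + UTR3, total = ``length``."""
    orf_codons = max(10, min(orf_codons, (length - 60) // 3 - 2))
    orf_len = 3 * orf_codons + 6  # ATG + codons + stop
    utr_total = length - orf_len
    utr5 = int(rng.integers(10, max(11, min(120, utr_total))))
    utr3 = utr_total - utr5
    codon_idx = rng.choice(len(_SENSE_CODONS), size=orf_codons, p=model.codon_weights)
    orf = "ATG" + "".join(_SENSE_CODONS[i] for i in codon_idx) + STOP_CODONS[
        int(rng.integers(3))
    ]
    utr5_seq = _markov_sequence(model, utr5, rng) if utr5 else ""
    utr3_seq = _markov_sequence(model, utr3, rng) if utr3 else ""
    return utr5_seq + orf + utr3_seq


def generate_sequences(
    assembled: Sequence[TranscriptModel],
    truth: TruthTables,
    config: SimulationConfig,
    rng: np.random.Generator,
    model: SequenceModel | None = None,
) -> dict[str, str]:
    """Sequence per assembled transcript; length equals spliced length."""
    if model is None:
        model = build_sequence_model(config, rng)
    kinds = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["kind"]))
    seqs: dict[str, str] = {}
    for t in assembled:
        kind = kinds[t.transcript_id]
        if kind == "coding":
            orf_codons = int(
                round(rng.normal(config.orf_codons_mean, config.orf_codons_sd))
            )
            seqs[t.transcript_id] = generate_coding_sequence(
                model, t.length, orf_codons, rng
            )
        else:
            seqs[t.transcript_id] = generate_noncoding_sequence(
                model, t.length, config.noncoding_orf_max_codons, rng
            )
    return seqs


def generate_training_sequences(
    config: SimulationConfig,
    rng: np.random.Generator,
    model: SequenceModel,
    n_per_class: int | None = None,
) -> tuple[list[str], list[str]]:
    """Labeled (coding, noncoding) training sequences from the same models."""
    n = config.n_training_per_class if n_per_class is None else n_per_class
    lo, hi = config.training_length_range
    coding, noncoding = [], []
    for _ in range(n):
        length = int(rng.integers(lo, hi))
        orf_codons = int(round(rng.normal(config.orf_codons_mean, config.orf_codons_sd)))
        coding.append(generate_coding_sequence(model, length, orf_codons, rng))
    for _ in range(n):
        length = int(rng.integers(lo, hi))
        noncoding.append(
            generate_noncoding_sequence(model, length, config.noncoding_orf_max_codons, rng)
        )
    return coding, noncoding


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_DE_PATTERNS = ((0.0, 1.0, 2.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


def make_design(config: SimulationConfig) -> list[SampleDesign]:
    return [
        SampleDesign(f"{b}_{s}_R{r}", b, s, r)
        for b in config.breeds
        for s in config.stages
        for r in range(1, config.replicates + 1)
    ]


def generate_expression(
    assembled: Sequence[TranscriptModel],
    truth: TruthTables,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, TruthTables]:
    """FPKM matrix with planted DE effects and planted correlation edges.

    Baseline log2-FPKM is Normal(mu_kind, sigma) with the lncRNA mean below
    the mRNA mean.  Planted DE transcripts get signed stage shifts of
    magnitude ``de_log2fc`` per step; planted edges share a latent
    stage-varying factor with loading ``edge_latent_weight``.  Replicate
    noise is Normal(0, noise_sd_log2).
    """
    samples = make_design(config)
    tids = [t.transcript_id for t in assembled]
    kinds = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["kind"]))
    stage_idx = {s: i for i, s in enumerate(config.stages)}

    base = np.array(
        [
            rng.normal(
                config.lnc_log2_mean if kinds[t] == "lncRNA" else config.mrna_log2_mean,
                config.log2_sd,
            )
            for t in tids
        ]
    )

    lnc_ids = [t for t in tids if kinds[t] == "lncRNA"]
    panel_tids = [
        t.transcript_id for t in assembled if t.gene_id in DEFAULT_MILK_PANEL
    ]

    # planted correlation edges first: their members are excluded from the
    # independent DE mechanism so the latent factor alone drives them
    n_edges = min(config.n_planted_edges, len(lnc_ids), len(panel_tids))
    edge_lncs = list(rng.choice(lnc_ids, size=n_edges, replace=False)) if n_edges else []
    edge_genes = (
        list(rng.choice(panel_tids, size=n_edges, replace=False)) if n_edges else []
    )
    edge_rows = []
    tid_pos = {t: i for i, t in enumerate(tids)}
    n_samples = len(samples)
    extra = np.zeros((len(tids), n_samples))
    gene_ids = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["gene_id"]))
    for lnc, gene in zip(edge_lncs, edge_genes):
        stage_vals = rng.permutation(np.array([-1.0, 0.0, 1.0]))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        z = np.array(
            [
                stage_vals[stage_idx[s.stage]]
                + rng.normal(0.0, config.edge_latent_jitter)
                for s in samples
            ]
        )
        load = config.edge_latent_weight * config.edge_latent_scale
        extra[tid_pos[lnc]] += load * z
        extra[tid_pos[gene]] += sign * load * z
        edge_rows.append(
            {
                "lncrna_id": lnc,
                "gene_id": gene_ids[gene],
                "gene_transcript_id": gene,
                "sign": "positive" if sign > 0 else "negative",
            }
        )

    edge_members = set(edge_lncs) | set(edge_genes)

    # planted DE, per breed
    shift = {b: np.zeros((len(tids), len(config.stages))) for b in config.breeds}
    de_rows = []
    for breed in config.breeds:
        for tid in tids:
            if tid in edge_members or kinds[tid] == "small_ncRNA":
                continue
            frac = (
                config.de_fraction
                if kinds[tid] == "lncRNA"
                else config.mrna_de_fraction
            )
            if rng.random() >= frac:
                continue
            pattern = np.array(_DE_PATTERNS[int(rng.integers(len(_DE_PATTERNS)))])
            direction = 1.0 if rng.random() < 0.5 else -1.0
            profile = direction * config.de_log2fc * pattern
            shift[breed][tid_pos[tid]] = profile
            n_st = len(config.stages)
            pairs = [(i, i + 1) for i in range(n_st - 1)]
            if n_st > 2:
                pairs.append((0, n_st - 1))
            for ia, ib in pairs:
                lfc = profile[ib] - profile[ia]
                de_rows.append(
                    {
                        "breed": breed,
                        "transcript_id": tid,
                        "stage_a": config.stages[ia],
                        "stage_b": config.stages[ib],
                        "true_log2fc": lfc,
                        "is_de": bool(abs(lfc) > 0),
                    }
                )

    noise = (
        rng.normal(0.0, config.noise_sd_log2, size=(len(tids), n_samples))
        if config.noise_sd_log2 > 0
        else np.zeros((len(tids), n_samples))
    )
    log2val = np.empty((len(tids), n_samples))
    for j, s in enumerate(samples):
        log2val[:, j] = (
            base + shift[s.breed][:, stage_idx[s.stage]] + extra[:, j] + noise[:, j]
        )
    values = pd.DataFrame(
        np.power(2.0, log2val), index=pd.Index(tids, name="transcript_id"),
        columns=[s.sample_id for s in samples],
    )
    matrix = ExpressionMatrix(values, samples, unit="fpkm")
    truth.de = pd.DataFrame(
        de_rows,
        columns=["breed", "transcript_id", "stage_a", "stage_b", "true_log2fc", "is_de"],
    )
    truth.edges = pd.DataFrame(
        edge_rows, columns=["lncrna_id", "gene_id", "gene_transcript_id", "sign"]
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def ct_from_fpkm(fpkm: float, config: SimulationConfig) -> tuple[float, bool]:
    """Deterministic part of the Ct model: Ct = a - log2(FPKM * scale)."""
    if fpkm <= 0:
        return config.qpcr_censor_ct, True
    return float(config.qpcr_ct_intercept - np.log2(fpkm * config.qpcr_scale)), False


def _pick_qpcr_targets(truth: TruthTables, config: SimulationConfig) -> list[str]:
    """Up- and down-regulated DE lncRNAs, balanced where possible."""
    if truth.de.empty:
        return []
    sub = truth.de[truth.de["is_de"]]
    strongest = (
        sub.assign(abs_lfc=sub["true_log2fc"].abs())
        .sort_values(["abs_lfc", "transcript_id"], ascending=[False, True])
        .drop_duplicates("transcript_id")
    )
    lnc_ids = set(truth.lncrna_ids())
    strongest = strongest[strongest["transcript_id"].isin(lnc_ids)]
    up = list(strongest.loc[strongest["true_log2fc"] > 0, "transcript_id"])
    down = list(strongest.loc[strongest["true_log2fc"] < 0, "transcript_id"])
    half = config.n_qpcr_targets // 2
    chosen = up[:half] + down[:half]
    for extra_pool in (up[half:], down[half:]):
        for tid in extra_pool:
            if len(chosen) >= config.n_qpcr_targets:
                break
            chosen.append(tid)
    return chosen[: config.n_qpcr_targets]


def generate_qpcr(
    expression: ExpressionMatrix,
    truth: TruthTables,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, TruthTables]:
    """Triplicate Ct table for validated lncRNAs plus two reference genes.

    Reference genes (GAPDH/UXT analogs) have stage-constant expression, so
    their Ct is constant across stages up to noise.  Zero FPKM is censored
    at the maximum cycle with a flag.
    """
    targets = _pick_qpcr_targets(truth, config)
    truth.qpcr_targets = targets
    rows = []
    sample_ids = expression.sample_ids
    for gene in targets:
        for s in sample_ids:
            ct0, censored = ct_from_fpkm(float(expression.values.loc[gene, s]), config)
            for rep in (1, 2, 3):
                ct = ct0 if censored else ct0 + (
                    rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd > 0 else 0.0
                )
                rows.append(
                    {
                        "sample_id": s,
                        "gene_id": gene,
                        "replicate": rep,
                        "ct": round(float(np.clip(ct, 1.0, 45.0)), 6),
                        "censored": censored,
                    }
                )
    for ref in ("GAPDH_REF", "UXT_REF"):
        ct0, _ = ct_from_fpkm(config.reference_fpkm, config)
        for s in sample_ids:
            for rep in (1, 2, 3):
                ct = ct0 + (
                    rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd > 0 else 0.0
                )
                rows.append(
                    {
                        "sample_id": s,
                        "gene_id": ref,
                        "replicate": rep,
                        "ct": round(float(np.clip(ct, 1.0, 45.0)), 6),
                        "censored": False,
                    }
                )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Gene sets and the full dataset
# ---------------------------------------------------------------------------


def generate_gene_sets(
    truth: TruthTables, config: SimulationConfig, rng: np.random.Generator
) -> GeneSetCollection:
    """Random gene sets over the coding universe, category round-robin."""
    genes = sorted(
        set(truth.transcripts.loc[truth.transcripts["kind"] == "coding", "gene_id"])
    )
    categories = ("BP", "MF", "CC", "pathway")
    sets = []
    for i in range(config.n_gene_sets):
        size = int(rng.integers(5, max(6, min(40, len(genes)))))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        cat = categories[i % len(categories)]
        sets.append(
            GeneSet(f"SET{i + 1:03d}", frozenset(map(str, members)), f"{cat}:synthetic", cat)
        )
    return GeneSetCollection(sets)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: list[TranscriptModel]
    assembled: list[TranscriptModel]
    sequences: dict[str, str]
    training_coding: list[str]
    training_noncoding: list[str]
    expression: ExpressionMatrix
    ct_table: pd.DataFrame
    truth: TruthTables
    gene_sets: GeneSetCollection
    panel_genes: list[str]


def simulate(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run every generation step in a fixed order from one seeded generator."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    reference, assembled, truth = generate_annotation(config, rng)
    model = build_sequence_model(config, rng)
    sequences = generate_sequences(assembled, truth, config, rng, model)
    training_coding, training_noncoding = generate_training_sequences(config, rng, model)
    expression, truth = generate_expression(assembled, truth, config, rng)
    ct_table, truth = generate_qpcr(expression, truth, config, rng)
    gene_sets = generate_gene_sets(truth, config, rng)
    n_panel = min(len(DEFAULT_MILK_PANEL), config.n_coding_genes)
    return SimulatedDataset(
        config=config,
        reference=reference,
        assembled=assembled,
        sequences=sequences,
        training_coding=training_coding,
        training_noncoding=training_noncoding,
        expression=expression,
        ct_table=ct_table,
        truth=truth,
        gene_sets=gene_sets,
        panel_genes=list(DEFAULT_MILK_PANEL[:n_panel]),
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every input a pipeline run needs into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": out / "reference.gtf",
        "assembled_gtf": out / "assembled.gtf",
        "transcripts_fasta": out / "transcripts.fa",
        "training_coding_fasta": out / "training_coding.fa",
        "training_noncoding_fasta": out / "training_noncoding.fa",
        "expression_tsv": out / "expression.tsv",
        "design_tsv": out / "design.tsv",
        "ct_tsv": out / "ct.tsv",
        "panel_txt": out / "panel.txt",
        "gene_sets_gmt": out / "gene_sets.gmt",
        "truth_transcripts_tsv": out / "truth_transcripts.tsv",
        "truth_de_tsv": out / "truth_de.tsv",
        "truth_edges_tsv": out / "truth_edges.tsv",
    }
    lio.write_gtf(dataset.reference, paths["reference_gtf"])
    lio.write_gtf(dataset.assembled, paths["assembled_gtf"])
    lio.write_fasta(dataset.sequences, paths["transcripts_fasta"])
    lio.write_fasta(
        {f"codtrain{i + 1:04d}": s for i, s in enumerate(dataset.training_coding)},
        paths["training_coding_fasta"],
    )
    lio.write_fasta(
        {f"nctrain{i + 1:04d}": s for i, s in enumerate(dataset.training_noncoding)},
        paths["training_noncoding_fasta"],
    )
    lio.write_expression(dataset.expression, paths["expression_tsv"])
    lio.write_design(dataset.expression.samples, paths["design_tsv"])
    dataset.ct_table.to_csv(paths["ct_tsv"], sep="\t", index=False)
    lio.write_gene_list(dataset.panel_genes, paths["panel_txt"])
    lio.write_gmt(dataset.gene_sets, paths["gene_sets_gmt"])
    dataset.truth.transcripts.to_csv(paths["truth_transcripts_tsv"], sep="\t", index=False)
    dataset.truth.de.to_csv(paths["truth_de_tsv"], sep="\t", index=False)
    dataset.truth.edges.to_csv(paths["truth_edges_tsv"], sep="\t", index=False)
    return paths
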