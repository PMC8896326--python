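"""Coding-potential assessment from sequence alone.

Four features of a transcript sequence — longest-ORF size, ORF coverage,
the Fickett TESTCODE statistic, and hexamer usage bias — feed a logistic
regression that outputs a coding probability in [0, 1].  Transcripts below
a stringent probability cutoff (default 0.02) are called noncoding.  The
built-in model can be combined with external predictors (e.g. precomputed
CNCI/PLEK/Pfam call tables) through an intersection consensus rule: a
transcript is noncoding only if every enabled predictor says so.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ValidationError

STOP_CODONS = ("TAA", "TAG", "TGA")
FEATURE_NAMES = ("orf_size", "orf_coverage", "fickett", "hexamer")

# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfResult:
    """Longest ATG..stop open reading frame of a transcript (sense strand).

    ``length_nt`` includes the stop codon; a transcript without any complete
    ORF yields a zero-length result with coverage 0.
    """

    start: int
    end: int
    length_nt: int
    coverage: float


def find_longest_orf(sequence: str) -> OrfResult:
    """Longest ATG-initiated, stop-terminated ORF over the 3 forward frames.

    Ties are broken by the smallest start offset.  Length includes the stop
    codon.  Raises ValidationError on an empty sequence.
    """
    if not sequence:
        raise ValidationError("cannot search an empty sequence for ORFs")
    seq = sequence.upper()
    n = len(seq)
    best_len = 0
    best_start = n + 1
    for frame in range(3):
        open_start = -1
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start < 0:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if length > best_len or (length == best_len and open_start < best_start):
                    best_len = length
                    best_start = open_start
                open_start = -1
    if best_len == 0:
        return OrfResult(0, 0, 0, 0.0)
    return OrfResult(best_start, best_start + best_len, best_len, best_len / n)


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------

# Published TESTCODE lookup tables: probability that a sequence is coding
# given the value range of each parameter, and the weight (predictive power)
# of each parameter.  Position parameter: for each base, max over the three
# codon positions of its count divided by (min + 1).  Content parameter:
# overall fraction of the base.
_POSITION_PROB = {
    "A": (0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36),
    "C": (0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38),
    "G": (0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.72, 0.83, 0.51),
    "T": (0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19),
    "C": (0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.33, 0.29, 0.33, 0.23),
    "G": (0.21, 0.40, 0.58, 0.58, 0.61, 0.66, 0.76, 0.83, 0.93, 0.90),
    "T": (0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.09, 0.09),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def _lookup(value: float, edges: tuple, probs: tuple) -> float:
    for edge, prob in zip(edges, probs):
        if value >= edge:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Classical Fickett TESTCODE statistic.

    Per base: the position parameter (asymmetry of occurrence across the
    three positions mod 3) and the content parameter (base fraction), each
    mapped through the published lookup tables and combined with the
    published weights.  Case-insensitive; N bases are ignored in the counts.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValidationError("Fickett statistic requires length >= 2")
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    for i, base in enumerate(seq):
        if base in pos_counts:
            pos_counts[base][i % 3] += 1
            totals[base] += 1
    usable = sum(totals.values())
    score = 0.0
    for base in "ACGT":
        c = pos_counts[base]
        position_value = max(c) / (min(c) + 1)
        score += (
            _lookup(position_value, _POSITION_EDGES, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        content_value = totals[base] / usable if usable else 0.0
        score += (
            _lookup(content_value, _CONTENT_EDGES, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_ALL_HEXAMERS = tuple("".join(p) for p in itertools.product("ACGT", repeat=6))
_HEX_INDEX = {h: i for i, h in enumerate(_ALL_HEXAMERS)}


@dataclass
class HexamerTable:
    """In-frame hexamer frequencies under coding and noncoding models.

    Both columns are pseudocount-smoothed and normalized to sum to 1.
    """

    coding: np.ndarray
    noncoding: np.ndarray

    def __post_init__(self) -> None:
        for name, col in (("coding", self.coding), ("noncoding", self.noncoding)):
            if col.shape != (4096,):
                raise ValidationError(f"hexamer table {name} column must have 4096 entries")
            if not np.all(col > 0):
                raise ValidationError(f"hexamer table {name} column must be positive")
            if abs(col.sum() - 1.0) > 1e-9:
                raise ValidationError(f"hexamer table {name} column must sum to 1")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.coding / self.noncoding)


def _count_hexamers(window: str, counts: np.ndarray) -> None:
    for i in range(0, len(window) - 5, 3):
        idx = _HEX_INDEX.get(window[i : i + 6])
        if idx is not None:
            counts[idx] += 1


def build_hexamer_table(
    coding_sequences: Iterable[str],
    noncoding_sequences: Iterable[str],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Count in-frame hexamers (step 3) and smooth into frequency columns.

    Coding sequences are counted within their longest ORF; noncoding
    sequences from position 0.  Either training class being empty is an
    error.
    """
    coding_counts = np.zeros(4096)
    noncoding_counts = np.zeros(4096)
    n_cod = n_non = 0
    for seq in coding_sequences:
        n_cod += 1
        s = seq.upper()
        orf = find_longest_orf(s)
        window = s[orf.start : orf.end] if orf.length_nt else s
        _count_hexamers(window, coding_counts)
    for seq in noncoding_sequences:
        n_non += 1
        _count_hexamers(seq.upper(), noncoding_counts)
    if n_cod == 0 or n_non == 0:
        raise ValidationError("both training classes must be nonempty")
    coding_counts += pseudocount
    noncoding_counts += pseudocount
    return HexamerTable(
        coding_counts / coding_counts.sum(), noncoding_counts / noncoding_counts.sum()
    )


def uniform_hexamer_table() -> HexamerTable:
    col = np.full(4096, 1 / 4096)
    return HexamerTable(col.copy(), col.copy())


def hexamer_bias(sequence: str, table: HexamerTable) -> float:
    """Mean log(f_coding / f_noncoding) over in-frame hexamers.

    The scoring window is the longest ORF when one exists, otherwise the
    whole sequence; hexamers step by 3.  Fewer than 6 usable nt gives 0.
    """
    seq = sequence.upper()
    orf = find_longest_orf(seq) if seq else OrfResult(0, 0, 0, 0.0)
    window = seq[orf.start : orf.end] if orf.length_nt else seq
    log_ratio = table.log_ratio
    total = 0.0
    n = 0
    for i in range(0, len(window) - 5, 3):
        idx = _HEX_INDEX.get(window[i : i + 6])
        if idx is not None:
            total += log_ratio[idx]
            n += 1
    return total / n if n else 0.0


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------


def compute_features(sequence: str, table: HexamerTable) -> np.ndarray:
    orf = find_longest_orf(sequence)
    return np.array(
        [
            float(orf.length_nt),
            orf.coverage,
            fickett_score(sequence),
            hexamer_bias(sequence, table),
        ]
    )


@dataclass
class LogisticModel:
    """Standardized-feature logistic regression over the four features."""

    intercept: float
    coefficients: np.ndarray  # aligned with FEATURE_NAMES
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_auc: float = float("nan")

    def __post_init__(self) -> None:
        if not np.all(self.feature_sds > 0):
            raise ValidationError("feature standardization sds must be positive")

    def probability(self, features: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(features) - self.feature_means) / self.feature_sds
        eta = self.intercept + z @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"intercept\t{float(self.intercept)!r}\n")
            for name, c, m, s in zip(
                FEATURE_NAMES, self.coefficients, self.feature_means, self.feature_sds
            ):
                fh.write(f"coef_{name}\t{float(c)!r}\n")
                fh.write(f"mean_{name}\t{float(m)!r}\n")
                fh.write(f"sd_{name}\t{float(s)!r}\n")
            fh.write(f"training_auc\t{float(self.training_auc)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        kv = {}
        with open(path) as fh:
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                kv[k] = float(v)
        return cls(
            intercept=kv["intercept"],
            coefficients=np.array([kv[f"coef_{n}"] for n in FEATURE_NAMES]),
            feature_means=np.array([kv[f"mean_{n}"] for n in FEATURE_NAMES]),
            feature_sds=np.array([kv[f"sd_{n}"] for n in FEATURE_NAMES]),
            training_auc=kv.get("training_auc", float("nan")),
        )


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def train_model(
    coding_sequences: Sequence[str],
    noncoding_sequences: Sequence[str],
    table: HexamerTable | None = None,
    pseudocount: float = 1.0,
    min_per_class: int = 20,
) -> tuple[LogisticModel, HexamerTable]:
    """Fit the four-feature logistic model on labeled training sequences.

    Features are standardized before the (deterministic, Newton/IRLS) fit.
    The hexamer table is built from the same training data unless supplied.
    """
    if len(coding_sequences) < min_per_class or len(noncoding_sequences) < min_per_class:
        raise ValidationError(
            f"need >= {min_per_class} sequences per class "
            f"(got {len(coding_sequences)} coding, {len(noncoding_sequences)} noncoding)"
        )
    if table is None:
        table = build_hexamer_table(coding_sequences, noncoding_sequences, pseudocount)
    X = np.array(
        [compute_features(s, table) for s in list(coding_sequences) + list(noncoding_sequences)]
    )
    y = np.concatenate(
        [np.ones(len(coding_sequences)), np.zeros(len(noncoding_sequences))]
    )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds
    design = sm.add_constant(Z, has_constant="add")
    # Ridge-stabilized fit: synthetic training classes are often perfectly
    # separable, where plain maximum likelihood diverges.
    import warnings

    with warnings.catch_warnings():
        # the l1 QC/trim checks are irrelevant for a pure ridge penalty
        warnings.filterwarnings("ignore", message="QC check did not pass")
        warnings.filterwarnings("ignore", message="Could not trim params")
        fit = sm.Logit(y, design).fit_regularized(
            alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500, cnvrg_tol=1e-10
        )
    params = np.asarray(fit.params, dtype=float)
    model = LogisticModel(
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        feature_means=means,
        feature_sds=sds,
    )
    model.training_auc = _rank_auc(model.probability(X), y)
    return model, table


@dataclass
class CodingPotentialResult:
    transcript_id: str
    orf_size: float
    orf_coverage: float
    fickett: float
    hexamer: float
    probability: float
    predictor_calls: dict[str, str] = field(default_factory=dict)
    consensus_noncoding: bool = False


def score_transcripts(
    model: LogisticModel,
    table: HexamerTable,
    sequences: Mapping[str, str],
    transcript_ids: Sequence[str] | None = None,
    threshold: float = 0.02,
) -> dict[str, CodingPotentialResult]:
    """Score transcripts; the built-in predictor votes noncoding iff p < threshold."""
    ids = list(sequences) if transcript_ids is None else list(transcript_ids)
    out: dict[str, CodingPotentialResult] = {}
    for tid in ids:
        if tid not in sequences:
            raise KeyError(f"no sequence available for transcript {tid!r}")
        feats = compute_features(sequences[tid], table)
        p = float(model.probability(feats)[0])
        call = "noncoding" if p < threshold else "coding"
        out[tid] = CodingPotentialResult(
            transcript_id=tid,
            orf_size=feats[0],
            orf_coverage=feats[1],
            fickett=feats[2],
            hexamer=feats[3],
            probability=p,
            predictor_calls={"cpat_like": call},
        )
    return out


def consensus_noncoding(
    calls: Mapping[str, str], enabled_predictors: Sequence[str]
) -> bool:
    """Intersection rule: noncoding only if every enabled predictor agrees.

    External predictors (CNCI/PLEK/Pfam surrogates) contribute through
    precomputed call tables merged into ``calls``.
    """
    if not enabled_predictors:
        raise ValidationError("at least one predictor must be enabled")
    for name in enabled_predictors:
        if name not in calls:
            raise KeyError(f"missing call for enabled predictor {name!r}")
        if calls[name] not in ("coding", "noncoding"):
            raise ValidationError(f"invalid call {calls[name]!r} for {name!r}")
    return all(calls[name] == "noncoding" for name in enabled_predictors)


def read_call_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a predictor call TSV (transcript_id, predictor, call)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "predictor", "call"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: call table requires columns {sorted(required)}")
    out: dict[str, dict[str, str]] = {}
    for r in df.itertuples():
        out.setdefault(r.transcript_id, {})[r.predictor] = r.call
    return out
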