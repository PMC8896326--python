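"""FPKM normalization and stage-wise differential expression.

Pairwise comparisons between lactation stages within a breed use a Welch
two-sample t-test on log2(FPKM + epsilon), Benjamini-Hochberg FDR within
each comparison, and a combined FDR < alpha with |log2 fold change| >
threshold call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SampleDesign, ValidationError


def fpkm(counts: pd.DataFrame, transcript_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    FPKM[t, s] = counts[t, s] * 1e9 / (library_size[s] * length[t]) with
    library size the per-sample column sum.
    """
    lengths = np.array([transcript_lengths[t] for t in counts.index], dtype=float)
    if (lengths < 1).any():
        raise ValidationError("transcript lengths must be >= 1")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    values = counts.to_numpy(dtype=float) * 1e9 / (lib[None, :] * lengths[:, None])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def log2_fold_change(mean_a: float, mean_b: float, epsilon: float = 0.01) -> float:
    """log2((mean_b + eps) / (mean_a + eps)); antisymmetric in its arguments."""
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("group means must be nonnegative")
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    return float(np.log2((mean_b + epsilon) / (mean_a + epsilon)))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment with monotone (cummin) enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialExpressionRecord:
    transcript_id: str
    breed: str
    stage_a: str
    stage_b: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    fdr: float
    is_de: bool


def de_test(
    matrix: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    epsilon: float = 0.01,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    breed: str = "",
    stage_a: str = "",
    stage_b: str = "",
) -> list[DifferentialExpressionRecord]:
    """Welch t-test on log2(FPKM + eps) per transcript, BH-FDR per comparison.

    Transcripts with zero variance in both groups and equal means receive
    p = 1.  ``is_de`` requires fdr < alpha and |log2fc| > lfc_threshold.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    ga, gb = list(group_a), list(group_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if set(ga) & set(gb):
        raise ValidationError("groups must be disjoint")
    a = np.log2(values[ga].to_numpy(dtype=float) + epsilon)
    b = np.log2(values[gb].to_numpy(dtype=float) + epsilon)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & equal_means] = 1.0
    # zero variance but different means: evidence is infinite under the
    # Welch model; report the smallest representable p rather than NaN
    p[degenerate & ~equal_means] = 0.0
    p[np.isnan(p)] = 1.0
    fdr = benjamini_hochberg(p)
    mean_a = values[ga].mean(axis=1).to_numpy()
    mean_b = values[gb].mean(axis=1).to_numpy()
    records = []
    for i, tid in enumerate(values.index):
        lfc = log2_fold_change(mean_a[i], mean_b[i], epsilon)
        records.append(
            DifferentialExpressionRecord(
                transcript_id=str(tid),
                breed=breed,
                stage_a=stage_a,
                stage_b=stage_b,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2fc=lfc,
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                is_de=bool(fdr[i] < alpha and abs(lfc) > lfc_threshold),
            )
        )
    return records


def stage_comparisons(
    samples: Sequence[SampleDesign], stages: Sequence[str] | None = None
) -> list[tuple[str, str, str]]:
    """Ordered (breed, stageA, stageB) pairs: consecutive stages plus first-last."""
    breeds = sorted({s.breed for s in samples})
    if stages is None:
        stages = sorted({s.stage for s in samples})
    pairs = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) > 2:
        pairs.append((stages[0], stages[-1]))
    return [(b, sa, sb) for b in breeds for sa, sb in pairs]


def run_comparisons(
    matrix: ExpressionMatrix,
    comparisons: Sequence[tuple[str, str, str]] | None = None,
    epsilon: float = 0.01,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Run every stage-pair comparison and return one tidy results table."""
    if comparisons is None:
        stages = list(dict.fromkeys(s.stage for s in matrix.samples))
        comparisons = stage_comparisons(matrix.samples, stages)
    rows = []
    for breed, sa, sb in comparisons:
        ga = matrix.samples_for(breed=breed, stage=sa)
        gb = matrix.samples_for(breed=breed, stage=sb)
        for r in de_test(
            matrix, ga, gb, epsilon=epsilon, alpha=alpha,
            lfc_threshold=lfc_threshold, breed=breed, stage_a=sa, stage_b=sb,
        ):
            rows.append(r.__dict__)
    return pd.DataFrame(rows)


def common_de(de_sets: Sequence[Sequence[str]]) -> set[str]:
    """Transcripts flagged DE in every supplied comparison."""
    if len(de_sets) < 2:
        raise ValidationError("need >= 2 comparisons to intersect")
    out = set(de_sets[0])
    for s in de_sets[1:]:
        out &= set(s)
    return out


def common_de_table(
    results: pd.DataFrame, matrix: ExpressionMatrix, breed: str
) -> pd.DataFrame:
    """Per-breed intersection of DE sets with per-stage mean FPKM appended."""
    sub = results[results["breed"] == breed]
    sets = [
        set(g.loc[g["is_de"], "transcript_id"])
        for _, g in sub.groupby(["stage_a", "stage_b"], sort=True)
    ]
    ids = sorted(common_de(sets)) if len(sets) >= 2 else []
    stages = list(dict.fromkeys(s.stage for s in matrix.samples))
    rows = []
    for tid in ids:
        row = {"transcript_id": tid}
        for st in stages:
            cols = matrix.samples_for(breed=breed, stage=st)
            row[f"mean_fpkm_{st}"] = float(matrix.values.loc[tid, cols].mean())
        rows.append(row)
    cols = ["transcript_id"] + [f"mean_fpkm_{st}" for st in stages]
    return pd.DataFrame(rows, columns=cols)
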