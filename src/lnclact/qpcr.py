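"""Relative qPCR quantification (2^-ddCt) and RNA-seq concordance.

Target Ct values are normalized against the mean of two reference
(housekeeping) genes, then against a calibrator sample; the relative
quantity is 2 to the minus double-delta-Ct.  Concordance compares qPCR and
RNA-seq log2 fold changes across validated transcripts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

DEFAULT_REFERENCE_GENES = ("GAPDH", "UXT")


def _mean_ct(ct: pd.DataFrame, sample: str, gene: str) -> tuple[float, bool]:
    sub = ct[(ct["sample_id"] == sample) & (ct["gene_id"] == gene)]
    if sub.empty:
        raise KeyError(f"no Ct measurement for gene {gene!r} in sample {sample!r}")
    return float(sub["ct"].mean()), bool(sub["censored"].any())


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    calibrator_sample: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative quantity of one target by the 2^-ddCt method.

    Technical replicates are averaged first.  dCt is the target mean Ct
    minus the mean of the per-reference mean Cts; ddCt subtracts the
    calibrator's dCt, so the calibrator has RQ = 1 by construction.
    Samples with a censored Ct are flagged unreliable.
    """
    samples = sorted(ct_table["sample_id"].unique())
    if calibrator_sample is None:
        calibrator_sample = samples[0]
    if calibrator_sample not in samples:
        raise ValidationError(f"calibrator sample {calibrator_sample!r} not measured")
    dct = {}
    unreliable = {}
    for s in samples:
        t_ct, t_cens = _mean_ct(ct_table, s, target_gene)
        ref_cts = []
        ref_cens = False
        for ref in reference_genes:
            c, cens = _mean_ct(ct_table, s, ref)
            ref_cts.append(c)
            ref_cens |= cens
        dct[s] = t_ct - float(np.mean(ref_cts))
        unreliable[s] = t_cens or ref_cens
    rows = []
    for s in samples:
        dd = dct[s] - dct[calibrator_sample]
        rows.append(
            {
                "sample_id": s,
                "gene_id": target_gene,
                "delta_ct": dct[s],
                "delta_delta_ct": dd,
                "rq": 2.0 ** (-dd),
                "log2_rq": -dd,
                "unreliable": unreliable[s] or unreliable[calibrator_sample],
            }
        )
    return pd.DataFrame(rows)


def qpcr_log2fc(
    rq: pd.DataFrame, samples_a: Sequence[str], samples_b: Sequence[str]
) -> float:
    """qPCR log2 fold change of group B over group A from per-sample log2 RQ."""
    la = rq.loc[rq["sample_id"].isin(list(samples_a)), "log2_rq"]
    lb = rq.loc[rq["sample_id"].isin(list(samples_b)), "log2_rq"]
    if la.empty or lb.empty:
        raise ValidationError("both sample groups must have RQ values")
    return float(lb.mean() - la.mean())


def concordance(
    qpcr_log2fc_values: Sequence[float], rnaseq_log2fc_values: Sequence[float]
) -> tuple[float, pd.DataFrame]:
    """Pearson r between qPCR and RNA-seq log2 fold changes (>= 3 pairs)."""
    q = np.asarray(qpcr_log2fc_values, dtype=float)
    r = np.asarray(rnaseq_log2fc_values, dtype=float)
    if q.shape != r.shape or q.ndim != 1:
        raise ValidationError("paired fold-change vectors must match in length")
    if q.size < 3:
        raise ValidationError("concordance requires >= 3 shared transcripts")
    if np.ptp(q) == 0 and np.ptp(r) == 0 and np.allclose(q, r):
        coef = 1.0
    else:
        coef = float(stats.pearsonr(q, r)[0])
    paired = pd.DataFrame({"qpcr_log2fc": q, "rnaseq_log2fc": r})
    return coef, paired
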