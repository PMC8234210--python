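"""Differential expression with the rank-sum test and the DEG inclusion filter.

A gene is called differentially expressed when FDR < ``q_max`` (default 0.01)
and |log2 fold change| > ``fc_min`` (default 2).  The per-gene test is the
Wilcoxon rank-sum on TPM values with Benjamini–Hochberg adjustment across all
tested genes; the fold change is the ratio of group means with a small
pseudocount.  (Count-model engines such as DESeq2 estimate the same contrast
with a negative-binomial GLM; this module deliberately uses the
distribution-free test so the threshold logic is self-contained.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nfypipe.data_model import ExpressionMatrix
from nfypipe.stats_core import bh_adjust, rank_sum_test

DEFAULT_FC_MIN = 2.0
DEFAULT_Q_MAX = 0.01
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DEGResult:
    gene_id: str
    log2_fc: float
    p_value: float
    q_value: float
    direction: str  # up / down / ns


def log2_fold_change(group_a, group_b, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((mean_a + pc) / (mean_b + pc)) on linear TPM values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.min() < 0 or b.min() < 0:
        raise ValueError("negative TPM values")
    return float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))


def differential_expression(expr: ExpressionMatrix, tumor_ids, normal_ids,
                            fc_min: float = DEFAULT_FC_MIN,
                            q_max: float = DEFAULT_Q_MAX,
                            pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene tumor-vs-normal comparison with the DEG inclusion filter.

    Returns a frame indexed by gene with columns log2_fc, p_value, q_value,
    direction.  ``direction`` is "up" when q < q_max and log2_fc > fc_min,
    "down" when q < q_max and log2_fc < -fc_min, else "ns".  Genes with zero
    variance across both groups (including all-zero genes) are excluded from
    testing and reported as ns with p = q = 1.
    """
    tumor_ids, normal_ids = list(tumor_ids), list(normal_ids)
    if not tumor_ids or not normal_ids:
        raise ValueError("both sample groups must be non-empty")
    if set(tumor_ids) & set(normal_ids):
        raise ValueError("tumor and normal sample sets overlap")
    if expr.log_transformed:
        raise ValueError("differential_expression expects linear TPM values")
    a_mat = expr.data[tumor_ids].to_numpy()
    b_mat = expr.data[normal_ids].to_numpy()

    genes = expr.gene_ids
    log_fcs = np.empty(len(genes))
    p_values = np.ones(len(genes))
    tested = np.zeros(len(genes), dtype=bool)
    for i in range(len(genes)):
        a, b = a_mat[i], b_mat[i]
        log_fcs[i] = log2_fold_change(a, b, pseudocount)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            continue
        tested[i] = True
        p_values[i] = rank_sum_test(a, b, alternative="two_sided").p_value

    q_values = np.ones(len(genes))
    if tested.any():
        q_values[tested] = bh_adjust(p_values[tested])

    direction = np.full(len(genes), "ns", dtype=object)
    up = tested & (q_values < q_max) & (log_fcs > fc_min)
    down = tested & (q_values < q_max) & (log_fcs < -fc_min)
    direction[up] = "up"
    direction[down] = "down"

    return pd.DataFrame(
        {"log2_fc": log_fcs, "p_value": p_values, "q_value": q_values,
         "direction": direction},
        index=pd.Index(genes, name="gene_id"),
    )


def deg_results(table: pd.DataFrame) -> list[DEGResult]:
    """View a differential_expression frame as a list of DEGResult records."""
    return [DEGResult(g, r.log2_fc, r.p_value, r.q_value, r.direction)
            for g, r in table.iterrows()]
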