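"""Gene-signature scoring by median Z and the High/Low 40/40/20 partition.

For each signature: per-gene Z-scores of log2(TPM+1) are computed over the
relevant sample subset, each sample receives the median Z over the
signature's genes, and samples are ranked by score and split into High (top
40%), Low (bottom 40%) and a discarded middle 20%.  The subset is chosen
*before* standardisation (e.g. CAF signatures scored within Mesenchymal
tumors; the p-EMT signature scored after removing fibroblast-rich samples).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from nfypipe.data_model import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

DEFAULT_HIGH_FRAC = 0.40
DEFAULT_LOW_FRAC = 0.40


def zscore_matrix(expr: ExpressionMatrix, sample_subset=None) -> pd.DataFrame:
    """Per-gene Z-scores of log2(TPM+1) over the given sample subset.

    Standardisation statistics (mean, sd) are computed on the subset itself.
    Zero-variance genes yield an all-zero row.  Requires >=2 samples.
    """
    if sample_subset is None:
        sample_subset = expr.sample_ids
    sample_subset = list(sample_subset)
    if len(sample_subset) == 0:
        raise ValueError("sample subset is empty")
    if len(sample_subset) < 2:
        raise ValueError("z-scores need >=2 samples (sd undefined for 1)")
    log_mat = expr.to_log2().subset_samples(sample_subset).data
    mean = log_mat.mean(axis=1)
    sd = log_mat.std(axis=1, ddof=1)
    z = log_mat.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def score_signature(z: pd.DataFrame, genes: GeneSet) -> pd.Series:
    """Per-sample median Z over the signature's genes present in the matrix."""
    present = [g for g in dict.fromkeys(genes) if g in z.index]
    absent = [g for g in genes if g not in z.index]
    if not present:
        raise KeyError(f"no genes of signature {genes.name!r} present in matrix")
    if absent:
        logger.info("signature %s: %d/%d genes absent from matrix",
                    genes.name, len(absent), len(genes))
    return z.loc[present].median(axis=0).rename(genes.name)


def partition_high_low(scores: pd.Series,
                       high_frac: float = DEFAULT_HIGH_FRAC,
                       low_frac: float = DEFAULT_LOW_FRAC) -> pd.Series:
    """Rank samples by score: top floor(high_frac·n) High, bottom
    floor(low_frac·n) Low, remainder discarded.

    Ties are broken by stable input order, making the partition
    deterministic.  A warning (not an error) is issued below n=5.
    """
    if high_frac < 0 or low_frac < 0 or high_frac + low_frac > 1:
        raise ValueError("need high_frac, low_frac >= 0 with sum <= 1")
    scores = pd.Series(scores)
    n = len(scores)
    if n == 0:
        raise ValueError("no scores to partition")
    if n < 5:
        warnings.warn(f"partitioning only {n} samples; groups will be tiny")
    n_high = int(np.floor(high_frac * n))
    n_low = int(np.floor(low_frac * n))
    order = np.argsort(scores.to_numpy(), kind="stable")  # ascending
    labels = np.full(n, "discarded", dtype=object)
    if n_low:
        labels[order[:n_low]] = "Low"
    if n_high:
        labels[order[n - n_high:]] = "High"
    return pd.Series(labels, index=scores.index, name="group")


def signature_table(expr: ExpressionMatrix, signatures: dict[str, GeneSet],
                    subsets: dict[str, list] | None = None,
                    high_frac: float = DEFAULT_HIGH_FRAC,
                    low_frac: float = DEFAULT_LOW_FRAC) -> pd.DataFrame:
    """Tidy score/group table for several signatures at once.

    ``subsets`` optionally maps a signature name to the sample subset it is
    scored on (restriction happens before standardisation); signatures not
    listed are scored on all samples.
    """
    rows = []
    for name, genes in signatures.items():
        subset = (subsets or {}).get(name)
        z = zscore_matrix(expr, subset)
        scores = score_signature(z, genes)
        groups = partition_high_low(scores, high_frac, low_frac)
        for sample_id in scores.index:
            rows.append({"sample_id": sample_id, "signature": name,
                         "median_z": scores[sample_id], "group": groups[sample_id]})
    return pd.DataFrame(rows)
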