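"""Nearest-centroid molecular subtype classification.

Tumors are assigned to one of the four HNSCC expression subtypes (Atypical,
Basal, Classical, Mesenchymal) by (1) median-centering each signature gene
across all samples in log2(TPM+1) space, (2) correlating each sample's
centered signature profile with per-subtype predictor centroids, and
(3) assigning the subtype attaining the largest Pearson correlation.

Centroids are either supplied precomputed or rebuilt as per-subtype means of
centered expression over labelled training samples — the simplest estimator
consistent with a "predictor centroid".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nfypipe.data_model import (
    SUBTYPES,
    UNASSIGNED,
    DataFormatError,
    ExpressionMatrix,
    GeneSet,
)

#: a sample must have at least this fraction of the signature genes
#: non-missing to be classified
MIN_GENE_FRACTION = 0.5
#: correlation is undefined below this many shared genes
MIN_SHARED_GENES = 3


@dataclass
class CentroidMatrix:
    """Signature-genes × subtypes matrix of centered predictor profiles."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise DataFormatError("need >=2 subtype centroids")
        if self.data.index.has_duplicates:
            raise DataFormatError("duplicate genes in centroid matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SubtypeCall:
    """Per-sample classification outcome with all centroid correlations."""

    sample_id: str
    assigned_subtype: str
    correlations: dict[str, float] = field(default_factory=dict)
    tie: bool = False


def median_center(matrix: ExpressionMatrix, gene_subset: GeneSet) -> ExpressionMatrix:
    """Median-center each signature gene across all samples.

    Input should be in log2(TPM+1) space (converted if flagged linear).  The
    output retains only the genes of ``gene_subset``; each retained row has
    median zero across the full sample set.
    """
    missing = [g for g in gene_subset if g not in matrix.data.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing[:10]}"
                       f"{'...' if len(missing) > 10 else ''}")
    log_mat = matrix.to_log2()
    sub = log_mat.data.loc[list(gene_subset)]
    centered = sub.sub(sub.median(axis=1), axis=0)
    return ExpressionMatrix(centered, log_transformed=True)


def build_centroids(centered: ExpressionMatrix, labels: pd.Series) -> CentroidMatrix:
    """Per-subtype mean of centered expression over labelled training samples.

    ``labels`` maps sample id -> subtype; every label must be one of the four
    subtypes and every subtype must have at least one sample.
    """
    labels = pd.Series(labels)
    bad = set(labels) - set(SUBTYPES)
    if bad:
        raise ValueError(f"unknown subtype labels: {sorted(bad)}")
    missing_samples = [s for s in labels.index if s not in centered.data.columns]
    if missing_samples:
        raise KeyError(f"labelled samples absent from matrix: {missing_samples[:5]}")
    empty = [s for s in SUBTYPES if s not in set(labels)]
    if empty:
        raise ValueError(f"no training samples for subtype(s): {empty}")
    cols = {}
    for subtype in SUBTYPES:
        members = labels.index[labels == subtype]
        cols[subtype] = centered.data[list(members)].mean(axis=1)
    return CentroidMatrix(pd.DataFrame(cols))


def classify(centered: ExpressionMatrix, centroids: CentroidMatrix) -> list[SubtypeCall]:
    """Assign each sample to the centroid with the largest Pearson correlation.

    Correlations are computed over the genes shared between the sample matrix
    and the centroid matrix.  Samples with zero variance over the shared
    genes, or with fewer than half of the centroid genes available
    (non-missing), are marked ``unassigned``.  Exact ties at the argmax are
    broken by centroid column order and flagged.
    """
    shared = [g for g in centroids.gene_ids if g in centered.data.index]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between matrix and centroids "
            f"(need >= {MIN_SHARED_GENES})")
    sample_mat = centered.data.loc[shared]
    cent_mat = centroids.data.loc[shared]
    names = centroids.subtype_names
    calls: list[SubtypeCall] = []
    for sample_id in sample_mat.columns:
        profile = sample_mat[sample_id].to_numpy()
        available = ~np.isnan(profile)
        if available.sum() < max(MIN_SHARED_GENES,
                                 MIN_GENE_FRACTION * len(centroids.gene_ids)):
            calls.append(SubtypeCall(sample_id, UNASSIGNED, {}))
            continue
        x = profile[available]
        if np.ptp(x) == 0:
            calls.append(SubtypeCall(sample_id, UNASSIGNED,
                                     {s: float("nan") for s in names}))
            continue
        corrs: dict[str, float] = {}
        for subtype in names:
            c = cent_mat[subtype].to_numpy()[available]
            corrs[subtype] = _pearson(x, c)
        finite = {s: r for s, r in corrs.items() if np.isfinite(r)}
        if not finite:
            calls.append(SubtypeCall(sample_id, UNASSIGNED, corrs))
            continue
        best = max(finite.values())
        winners = [s for s in names if np.isfinite(corrs[s]) and corrs[s] == best]
        calls.append(SubtypeCall(sample_id, winners[0], corrs, tie=len(winners) > 1))
    return calls


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def classify_cohort(expr: ExpressionMatrix, signature: GeneSet,
                    training_labels: pd.Series | None = None,
                    centroids: CentroidMatrix | None = None) -> pd.DataFrame:
    """End-to-end convenience: center, (re)build centroids, classify.

    Exactly one of ``training_labels`` (to rebuild centroids from labelled
    samples) or ``centroids`` (precomputed) must be given.  Returns a tidy
    frame with the assignment and all four correlations per sample.
    """
    if (training_labels is None) == (centroids is None):
        raise ValueError("supply exactly one of training_labels or centroids")
    centered = median_center(expr, signature)
    if centroids is None:
        centroids = build_centroids(centered, training_labels)
    calls = classify(centered, centroids)
    rows = []
    for call in calls:
        row = {"sample_id": call.sample_id, "subtype": call.assigned_subtype,
               "tie": call.tie}
        for s in centroids.subtype_names:
            row[f"r_{s}"] = call.correlations.get(s, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
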