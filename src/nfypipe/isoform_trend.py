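"""Splice-isoform ratio analysis: per-sample long/short ratios, rank binning
into equal-size groups, trend tests across bins, and per-bin subtype
composition.

The central statistic is the NF-YAl/NF-YAs TPM ratio (long over short NF-YA
isoform), stabilised by a small epsilon so zero denominators stay finite.
Samples are ranked by ratio and split into ``n_bins`` contiguous groups of
(as near as possible) equal size; a Jonckheere–Terpstra test then asks
whether a marker increases monotonically across the ordered bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nfypipe.data_model import IsoformTable
from nfypipe.stats_core import TestResult, jonckheere_test

DEFAULT_EPSILON = 0.01
DEFAULT_N_BINS = 10


def isoform_ratio(iso: IsoformTable, epsilon: float = DEFAULT_EPSILON,
                  long_role: str = "NFYA_long",
                  short_role: str = "NFYA_short") -> pd.DataFrame:
    """Per-sample (long + eps) / (short + eps) TPM ratio.

    Returns a frame indexed by sample with columns long_tpm, short_tpm,
    ratio.  Raises KeyError when either role tag is absent from the table.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    long_tpm = iso.role_values(long_role)
    short_tpm = iso.role_values(short_role)
    ratio = (long_tpm + epsilon) / (short_tpm + epsilon)
    return pd.DataFrame({"long_tpm": long_tpm, "short_tpm": short_tpm,
                         "ratio": ratio}).rename_axis("sample_id")


def bin_by_rank(values, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Partition values into ``n_bins`` contiguous rank-ordered groups.

    Bin 1 holds the smallest values.  Sizes differ by at most one, with the
    larger bins placed at the low end when n is not divisible.  Ties in value
    are broken by stable input order, so the partition is deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > n:
        raise ValueError(f"cannot split {n} values into {n_bins} bins")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    bins = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(sizes, start=1):
        bins[order[start:start + size]] = k
        start += size
    return bins


def trend_across_bins(marker_values, bins,
                      alternative: str = "two_sided") -> TestResult:
    """Jonckheere–Terpstra trend of a marker across ordered rank bins.

    ``marker_values`` is one value per sample, ``bins`` the labels from
    :func:`bin_by_rank` (1..n_bins).  With ``alternative="increasing"`` the
    test rejects when the marker rises with the bin order.
    """
    marker_values = np.asarray(marker_values, dtype=float)
    bins = np.asarray(bins)
    if marker_values.size != bins.size:
        raise ValueError("marker values and bin labels differ in length")
    labels = np.unique(bins)
    groups = [marker_values[bins == k] for k in labels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty bin")
    return jonckheere_test(groups, alternative=alternative)


def subtype_composition_by_bin(bins, subtype_labels) -> pd.DataFrame:
    """Per-bin subtype fractions (rows are bins, each summing to one)."""
    bins = np.asarray(bins)
    labels = pd.Series(list(subtype_labels))
    if len(labels) != bins.size:
        raise ValueError("need one subtype label per binned sample")
    frame = pd.DataFrame({"bin": bins, "subtype": labels.to_numpy()})
    counts = frame.groupby(["bin", "subtype"]).size().unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return fractions.sort_index()
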