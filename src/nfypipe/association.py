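"""Mutation- and HPV-stratified comparisons of NF-Y subunit/isoform levels.

For each stratifier (a frequently mutated gene, or HPV status) and each
target quantity (a subunit gene TPM, an isoform TPM or the isoform ratio),
samples carrying the stratum are compared with the rest by the Wilcoxon
rank-sum test; the direction is the sign of the median difference.  Only
genes mutated in strictly more than ``min_samples`` samples are considered
"frequent".  Significance stars follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nfypipe.data_model import SampleAnnotation
from nfypipe.stats_core import bh_adjust, rank_sum_test

DEFAULT_MIN_MUTATION_SAMPLES = 80


@dataclass
class AssociationResult:
    stratifier: str  # gene symbol or "HPV"
    target: str
    n_group1: int  # carriers / HPV-positive
    n_group2: int
    p_value: float
    direction: int  # sign of median(group1) - median(group2)


def frequent_mutation_genes(annotation: SampleAnnotation,
                            min_samples: int = DEFAULT_MIN_MUTATION_SAMPLES) -> list[str]:
    """Genes mutated in strictly more than ``min_samples`` tumors,
    sorted by descending carrier count (alphabetical within ties)."""
    counts: dict[str, int] = {}
    for mutations in annotation.mutation_sets():
        for gene in mutations:
            counts[gene] = counts.get(gene, 0) + 1
    frequent = [(gene, n) for gene, n in counts.items() if n > min_samples]
    frequent.sort(key=lambda item: (-item[1], item[0]))
    return [gene for gene, _ in frequent]


def compare_by_stratum(values: pd.Series, stratum_mask: pd.Series,
                       stratifier: str = "", target: str = "") -> AssociationResult | None:
    """Rank-sum comparison of target values inside vs outside a stratum.

    Returns None (with a warning) when either stratum is empty.
    """
    values = pd.Series(values)
    mask = pd.Series(stratum_mask).reindex(values.index).astype(bool)
    in_group = values[mask].to_numpy(dtype=float)
    out_group = values[~mask].to_numpy(dtype=float)
    if in_group.size == 0 or out_group.size == 0:
        warnings.warn(f"empty stratum for {stratifier!r} vs {target!r}; skipped")
        return None
    res = rank_sum_test(in_group, out_group, alternative="two_sided")
    direction = int(np.sign(np.median(in_group) - np.median(out_group)))
    return AssociationResult(stratifier=stratifier, target=target,
                             n_group1=in_group.size, n_group2=out_group.size,
                             p_value=res.p_value, direction=direction)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def association_table(targets: dict[str, pd.Series],
                      annotation: SampleAnnotation,
                      min_samples: int = DEFAULT_MIN_MUTATION_SAMPLES,
                      include_hpv: bool = True,
                      adjust: bool = False) -> pd.DataFrame:
    """One row per (stratifier, target): mutation cohorts and optionally HPV.

    ``targets`` maps a target name to per-tumor values indexed by sample id.
    HPV comparisons use positive vs negative tumors; unknown-status samples
    are excluded.  Raw p-values are reported by default; ``adjust=True``
    appends BH q-values.
    """
    rows = []
    for gene in frequent_mutation_genes(annotation, min_samples):
        carriers = annotation.mutation_carriers(gene)
        for target_name, values in targets.items():
            common = values.index.intersection(carriers.index)
            res = compare_by_stratum(values.loc[common], carriers.loc[common],
                                     stratifier=gene, target=target_name)
            if res is not None:
                rows.append(res)
    if include_hpv:
        hpv = annotation.hpv_labels()
        known = hpv[hpv.isin(["positive", "negative"])]
        for target_name, values in targets.items():
            common = values.index.intersection(known.index)
            if len(common) == 0:
                continue
            res = compare_by_stratum(values.loc[common],
                                     known.loc[common] == "positive",
                                     stratifier="HPV", target=target_name)
            if res is not None:
                rows.append(res)
    table = pd.DataFrame([vars(r) for r in rows])
    if len(table):
        table["stars"] = table["p_value"].map(significance_stars)
        if adjust:
            table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table
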