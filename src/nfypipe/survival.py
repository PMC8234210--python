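"""Kaplan–Meier estimation, log-rank testing and expression-based
stratification of the progression-free interval (PFI).

Stratification follows the quartile rule: samples are ranked by expression;
the bottom three quartiles (floor(0.75·n) samples) are Low and the top
quartile High.  Two-gene stratifications join the two independent rankings
into four groups (Low/Low … High/High).  Estimation and testing are
delegated to lifelines behind this module's interface; deaths are processed
before censorings tied at the same time (the standard product-limit
convention).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from nfypipe.stats_core import TestResult, bh_adjust

QUARTILE_LOW_FRAC = 0.75


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the observed event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    group_label: str = ""

    def probability_at(self, t: float) -> float:
        """S(t): right-continuous step function, 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def quartile_stratify(values: pd.Series) -> pd.Series:
    """Low = bottom floor(0.75·n) samples by value, High = the rest.

    Ties are resolved by stable input order.  Requires n >= 4.
    """
    values = pd.Series(values)
    n = len(values)
    if n < 4:
        raise ValueError("quartile stratification needs >=4 samples")
    order = np.argsort(values.to_numpy(), kind="stable")
    n_low = int(math.floor(QUARTILE_LOW_FRAC * n))
    labels = np.full(n, "High", dtype=object)
    labels[order[:n_low]] = "Low"
    return pd.Series(labels, index=values.index, name="group")


def combine_two_gene_groups(labels_a: pd.Series, labels_b: pd.Series) -> pd.Series:
    """Join two Low/High rankings into four groups 'A/B' per sample."""
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    if set(labels_a.index) != set(labels_b.index):
        missing = set(labels_a.index) ^ set(labels_b.index)
        raise KeyError(f"sample sets differ between the two rankings: "
                       f"{sorted(missing)[:5]}")
    joined = labels_a + "/" + labels_b.reindex(labels_a.index)
    return joined.rename("group")


def km_estimate(times, events, group_label: str = "") -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate S(t) at the distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size:
        raise ValueError("times and events differ in length")
    if times.size == 0:
        raise ValueError("no subjects")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0 (censored) or 1 (event)")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    event_times = with_events.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival_prob = np.array([float(surv.loc[t]) for t in event_times])
    return SurvivalCurve(
        event_times=event_times,
        survival_prob=survival_prob,
        n_at_risk=with_events["at_risk"].to_numpy(dtype=int),
        n_events=with_events["observed"].to_numpy(dtype=int),
        group_label=group_label,
    )


def logrank_test(times, events, groups) -> TestResult:
    """Two-group log-rank test (1 df chi-square over pooled event times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {labels.size}")
    mask = groups == labels[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups need >=1 subject")
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="normal_approx",
                      group_sizes=(int(mask.sum()), int((~mask).sum())))


def pairwise_logrank(times, events, groups) -> pd.DataFrame:
    """All pairwise two-group log-rank tests with BH-adjusted q-values."""
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        sel = np.isin(groups, [a, b])
        res = logrank_test(np.asarray(times, dtype=float)[sel],
                           np.asarray(events, dtype=int)[sel], groups[sel])
        rows.append({"group_a": a, "group_b": b,
                     "statistic": res.statistic, "p_value": res.p_value})
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table


def km_by_group(times, events, groups) -> dict[str, SurvivalCurve]:
    """One Kaplan–Meier curve per stratum label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    return {
        str(label): km_estimate(times[groups == label], events[groups == label],
                                group_label=str(label))
        for label in np.unique(groups)
    }
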