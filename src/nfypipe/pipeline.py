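"""End-to-end orchestration of the seven analysis stages on one cohort.

Stage order matches the analysis flow: (1) subtype classification,
(2) differential expression (global, per-subtype, HPV-positive),
(3) isoform ratios / binning / trend tests, (4) deconvolution + fibroblast
filter, (5) signature scoring + High/Low partitions, (6) mutation & HPV
associations, (7) survival stratification.  Every stage writes its table(s)
under the output directory, and a run log records the config hash and seed
so any table can be reproduced.  All stage outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nfypipe import __version__
from nfypipe.association import association_table
from nfypipe.data_model import SUBTYPES, ExpressionMatrix, GeneSet, write_table
from nfypipe.deconvolution import estimate_proportions, fibroblast_filter
from nfypipe.diffexpr import differential_expression
from nfypipe.isoform_trend import (
    bin_by_rank,
    isoform_ratio,
    subtype_composition_by_bin,
    trend_across_bins,
)
from nfypipe.signature_scoring import signature_table
from nfypipe.subtype_classifier import classify_cohort
from nfypipe.survival import (
    combine_two_gene_groups,
    km_by_group,
    logrank_test,
    pairwise_logrank,
    quartile_stratify,
)
from nfypipe.synthetic_data import CohortConfig, SyntheticCohort, generate_cohort


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds and provenance for one pipeline run.

    Threshold defaults are the analysis' stated values: DEG filter FDR<0.01
    with |log2FC|>2, ten ratio bins, 40/40/20 signature partition, <30%
    fibroblast retention, top-quartile High stratification, >80-sample
    mutation filter.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fc_min: float = 2.0
    q_max: float = 0.01
    n_bins: int = 10
    high_frac: float = 0.40
    low_frac: float = 0.40
    fibroblast_max: float = 0.30
    min_mutation_samples: int = 80
    ratio_epsilon: float = 0.01
    training_fraction: float = 0.5
    seed: int = 0
    output_dir: str = "pipeline_output"

    def __post_init__(self) -> None:
        for name in ("fc_min", "q_max", "high_frac", "low_frac",
                     "fibroblast_max", "ratio_epsilon", "training_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.high_frac + self.low_frac > 1:
            raise ValueError("high_frac + low_frac must not exceed 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def content_hash(self) -> str:
        """Hash of the analysis-defining fields (output location excluded)."""
        payload = asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortConfig(**raw.pop("cohort", {}))
    valid = set(PipelineConfig.__dataclass_fields__) - {"cohort"}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(cohort=cohort, **raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig,
                 cohort: SyntheticCohort | None = None) -> dict:
    """Execute all seven stages; write every table plus a run log.

    ``cohort`` may be supplied directly (e.g. read from disk); by default it
    is generated from ``config.cohort`` with the pipeline seed folded in.
    Returns a dict of the in-memory stage results keyed by stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort_config = CohortConfig(**{**asdict(config.cohort), "seed": config.seed})
        cohort = generate_cohort(cohort_config)

    results: dict = {"cohort": cohort}
    write_table(cohort.expression, outdir / "expression_tpm.tsv")
    write_table(cohort.isoforms, outdir / "isoform_tpm.tsv")
    write_table(cohort.annotation, outdir / "annotation.tsv")

    calls = _stage("classify")(_run_classify)(config, cohort)
    results["classify"] = calls
    write_table(calls, outdir / "subtype_calls.tsv")

    deg = _stage("diffexpr")(_run_diffexpr)(config, cohort)
    results["diffexpr"] = deg
    for name, table in deg.items():
        write_table(table, outdir / f"deg_{name}.tsv")

    iso = _stage("isoform_trend")(_run_isoform)(config, cohort, calls)
    results["isoform_trend"] = iso
    write_table(iso["ratios"], outdir / "isoform_ratios.tsv")
    write_table(iso["trend_tests"], outdir / "trend_tests.tsv")
    write_table(iso["bin_composition"], outdir / "bin_composition.tsv")

    deconv = _stage("deconvolution")(_run_deconvolution)(config, cohort)
    results["deconvolution"] = deconv
    write_table(deconv["proportions"], outdir / "cell_proportions.tsv")
    (outdir / "retained_samples.txt").write_text(
        "\n".join(deconv["retained"]) + "\n")

    scores = _stage("signature_scoring")(_run_signatures)(config, cohort, calls, deconv)
    results["signature_scoring"] = scores
    write_table(scores.set_index("sample_id"), outdir / "signature_scores.tsv")

    assoc = _stage("association")(_run_association)(config, cohort)
    results["association"] = assoc
    write_table(assoc.set_index("stratifier") if len(assoc) else assoc,
                outdir / "associations.tsv")

    surv = _stage("survival")(_run_survival)(config, cohort)
    results["survival"] = surv
    write_table(surv["tests"], outdir / "survival_tests.tsv")
    write_table(surv["curves"], outdir / "km_curves.tsv")

    log = {
        "nfypipe_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_tumor": len(cohort.annotation.tumor_ids),
        "n_normal": len(cohort.annotation.normal_ids),
        "stages": ["classify", "diffexpr", "isoform_trend", "deconvolution",
                   "signature_scoring", "association", "survival"],
        "config": {k: v for k, v in asdict(config).items() if k != "output_dir"},
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return results


# --- individual stages ------------------------------------------------------

def _run_classify(config: PipelineConfig, cohort: SyntheticCohort) -> pd.DataFrame:
    truth = cohort.truth["subtype_labels"]
    n_train = max(len(SUBTYPES), int(round(config.training_fraction * len(truth))))
    train_rng = np.random.default_rng(config.seed + 101)
    train_ids = list(pd.Index(truth.index)[
        train_rng.permutation(len(truth))[:n_train]])
    signature = GeneSet("subtype_signature", [
        g for s in SUBTYPES for g in cohort.signature_gene_sets[s]])
    tumor_expr = cohort.expression.subset_samples(cohort.annotation.tumor_ids)
    return classify_cohort(tumor_expr, signature,
                           training_labels=truth.loc[train_ids])


def _run_diffexpr(config: PipelineConfig,
                  cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    ann = cohort.annotation
    expr = cohort.expression
    out = {"tumor_vs_normal": differential_expression(
        expr, ann.tumor_ids, ann.normal_ids, config.fc_min, config.q_max)}
    labels = ann.subtype_labels()
    for s in SUBTYPES:
        members = list(labels.index[labels == s])
        if members:
            out[s] = differential_expression(expr, members, ann.normal_ids,
                                             config.fc_min, config.q_max)
    hpv = ann.hpv_labels()
    positives = [sid for sid in ann.tumor_ids if hpv.get(sid) == "positive"]
    if positives:
        out["hpv_positive"] = differential_expression(
            expr, positives, ann.normal_ids, config.fc_min, config.q_max)
    return out


def _run_isoform(config: PipelineConfig, cohort: SyntheticCohort,
                 calls: pd.DataFrame) -> dict:
    tumor_ids = cohort.annotation.tumor_ids
    ratios = isoform_ratio(cohort.isoforms, config.ratio_epsilon).loc[tumor_ids]
    bins = bin_by_rank(ratios["ratio"].to_numpy(), config.n_bins)
    ratios = ratios.assign(bin=bins)
    markers = {
        "NFYB": cohort.expression.data.loc["NFYB", tumor_ids],
        "NFYC": cohort.expression.data.loc["NFYC", tumor_ids],
        "pEMT_mean": cohort.expression.data.loc[
            list(cohort.signatures["pEMT"]), tumor_ids].mean(axis=0),
    }
    rows = []
    for name, values in markers.items():
        res = trend_across_bins(values.to_numpy(), bins, alternative="increasing")
        rows.append({"marker": name, "J": res.statistic, "p_value": res.p_value,
                     "method": res.method})
    composition = subtype_composition_by_bin(
        bins, calls.loc[tumor_ids, "subtype"])
    return {"ratios": ratios,
            "trend_tests": pd.DataFrame(rows).set_index("marker"),
            "bin_composition": composition}


def _run_deconvolution(config: PipelineConfig, cohort: SyntheticCohort) -> dict:
    props = estimate_proportions(cohort.mixture_expression, cohort.reference,
                                 gene_selection="markers")
    retained = fibroblast_filter(props, "Fibroblast", config.fibroblast_max)
    return {"proportions": props.data, "retained": retained}


def _run_signatures(config: PipelineConfig, cohort: SyntheticCohort,
                    calls: pd.DataFrame, deconv: dict) -> pd.DataFrame:
    tumor_expr = cohort.expression.subset_samples(cohort.annotation.tumor_ids)
    mesenchymal = list(calls.index[calls["subtype"] == "Mesenchymal"])
    subsets = {"CAF1": mesenchymal, "CAF2": mesenchymal,
               "pEMT": deconv["retained"]}
    return signature_table(tumor_expr, cohort.signatures, subsets,
                           config.high_frac, config.low_frac)


def _run_association(config: PipelineConfig, cohort: SyntheticCohort) -> pd.DataFrame:
    tumor_ids = cohort.annotation.tumor_ids
    ratios = isoform_ratio(cohort.isoforms, config.ratio_epsilon).loc[tumor_ids]
    targets = {
        "NFYA": cohort.expression.data.loc["NFYA", tumor_ids],
        "NFYB": cohort.expression.data.loc["NFYB", tumor_ids],
        "NFYC": cohort.expression.data.loc["NFYC", tumor_ids],
        "NFYAl": ratios["long_tpm"],
        "NFYAs": ratios["short_tpm"],
        "NFYAl_NFYAs_ratio": ratios["ratio"],
    }
    return association_table(targets, cohort.annotation,
                             min_samples=config.min_mutation_samples)


def _run_survival(config: PipelineConfig, cohort: SyntheticCohort) -> dict:
    surv = cohort.annotation.survival_frame()
    ids = list(surv.index)
    ratios = isoform_ratio(cohort.isoforms, config.ratio_epsilon).loc[ids]
    targets = {
        "NFYA": cohort.expression.data.loc["NFYA", ids],
        "NFYAs": ratios["short_tpm"],
        "NFYAl": ratios["long_tpm"],
    }
    times = surv["pfi_time"].to_numpy()
    events = surv["pfi_event"].to_numpy().astype(int)
    test_rows, curve_rows = [], []
    strata = {}
    for name, values in targets.items():
        labels = quartile_stratify(values)
        strata[name] = labels
        res = logrank_test(times, events, labels.to_numpy())
        test_rows.append({"stratifier": name, "comparison": "High vs Low",
                          "statistic": res.statistic, "p_value": res.p_value})
        for label, curve in km_by_group(times, events, labels.to_numpy()).items():
            for t, s_prob, at_risk, d in zip(curve.event_times, curve.survival_prob,
                                             curve.n_at_risk, curve.n_events):
                curve_rows.append({"stratifier": name, "group": label, "time": t,
                                   "survival": s_prob, "n_at_risk": at_risk,
                                   "n_events": d})
    combined = combine_two_gene_groups(strata["NFYAs"], strata["NFYA"])
    pw = pairwise_logrank(times, events, combined.to_numpy())
    for row in pw.itertuples(index=False):
        test_rows.append({"stratifier": "NFYAs+NFYA",
                          "comparison": f"{row.group_a} vs {row.group_b}",
                          "statistic": row.statistic, "p_value": row.p_value})
    return {"tests": pd.DataFrame(test_rows).set_index("stratifier"),
            "curves": pd.DataFrame(curve_rows).set_index("stratifier"),
            "strata": strata, "combined": combined}
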