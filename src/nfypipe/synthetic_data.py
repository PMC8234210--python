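"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Emulates a TCGA-HNSCC-style cohort: negative-binomial RNA-seq counts scaled
to TPM, four molecular subtypes with subtype-specific signature genes
elevated in their own subtype, two NF-YA splice isoforms whose long/short
ratio has a subtype-dependent mean (high in Mesenchymal, low in Atypical),
HPV positivity concentrated in the Atypical subtype, per-gene somatic
mutation flags, a labelled cell-type reference with per-tumor mixture
profiles and known proportions (fibroblast-rich Mesenchymal tumors), and
censored exponential progression-free-interval times whose hazard depends on
an expression-defined group.

Everything is deterministic under a fixed seed, and every piece of planted
structure is returned as ground truth so downstream stages can be tested for
recovery — null configurations (zero effect sizes) plant no structure at all
and calibrate the tests instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from nfypipe.data_model import (
    SENTINEL,
    SUBTYPES,
    ExpressionMatrix,
    GeneSet,
    IsoformTable,
    SampleAnnotation,
)
from nfypipe.deconvolution import CellTypeReference
from nfypipe.survival import quartile_stratify


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _default_subtype_proportions() -> dict[str, float]:
    # approximate published frequency order: Basal > Mesenchymal ~ Atypical > Classical
    return {"Atypical": 0.24, "Basal": 0.31, "Classical": 0.17, "Mesenchymal": 0.28}


def _default_isoform_ratio() -> dict[str, float]:
    # long/short mean ratio: high in Mesenchymal, low in Atypical
    return {"Atypical": 0.3, "Basal": 0.6, "Classical": 0.6, "Mesenchymal": 1.5}


def _default_hpv_fractions() -> dict[str, float]:
    # HPV positivity concentrated in the Atypical subtype
    return {"Atypical": 0.50, "Basal": 0.10, "Classical": 0.12, "Mesenchymal": 0.08}


def _default_mutation_rates() -> dict[str, float]:
    # carrier frequencies in the spirit of the most common HNSCC mutations
    return {
        "TP53": 0.65, "TTN": 0.36, "FAT1": 0.22, "CDKN2A": 0.21,
        "MUC16": 0.18, "SYNE1": 0.19, "CSMD3": 0.17, "PIK3CA": 0.17,
        "NOTCH1": 0.17, "PCLO": 0.16, "KMT2D": 0.16, "NSD1": 0.12,
    }


def _default_hazards() -> dict[str, float]:
    # events/day; the short-isoform-High group is protective
    return {"High": 1.0 / 2400.0, "Low": 1.0 / 1000.0}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the real cohort's scale (522 tumors, 44 normals) and the
    qualitative structure of the analyses: a log2 signature effect of 2 per
    subtype, Mesenchymal-high/Atypical-low isoform ratios, HPV concentrated
    in Atypical tumors, TP53 carriers shifted toward the long isoform, and a
    protective effect of high short-isoform expression on PFI hazard.
    """

    n_tumor: int = 522
    n_normal: int = 44
    subtype_proportions: dict[str, float] = field(default_factory=_default_subtype_proportions)
    n_genes: int = 2000
    n_signature_genes_per_subtype: int = 50
    signature_log2_effect: float = 2.0
    isoform_ratio_by_subtype: dict[str, float] = field(default_factory=_default_isoform_ratio)
    normal_isoform_ratio: float = 0.4
    hpv_positive_fraction_by_subtype: dict[str, float] = field(default_factory=_default_hpv_fractions)
    mutation_rates: dict[str, float] = field(default_factory=_default_mutation_rates)
    mutation_ratio_log2_effects: dict[str, float] = field(
        default_factory=lambda: {"TP53": 0.585})
    hpv_isoform_log2_effects: dict[str, float] = field(
        default_factory=lambda: {"NFYA_long": -0.3, "NFYA_short": 0.4})
    hazard_by_group: dict[str, float] = field(default_factory=_default_hazards)
    censor_rate: float = 1.0 / 1500.0
    nb_dispersion: float = 0.2
    sequencing_depth: float = 5e5
    n_pemt_genes: int = 30
    pemt_log2_slope: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor <= 0 or self.n_normal <= 0 or self.n_genes <= 0:
            raise ConfigError("cohort sizes must be positive")
        props = [self.subtype_proportions.get(s, 0.0) for s in SUBTYPES]
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError("subtype proportions must be non-negative and sum to 1")
        for name, frac in self.hpv_positive_fraction_by_subtype.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"HPV fraction for {name} outside [0,1]")
        for gene, rate in self.mutation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"mutation rate for {gene} outside [0,1]")
        if any(h <= 0 for h in self.hazard_by_group.values()):
            raise ConfigError("hazards must be positive")
        if self.censor_rate <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("censor_rate and nb_dispersion must be positive")
        needed = 3 + 4 * self.n_signature_genes_per_subtype + self.n_pemt_genes
        if self.n_genes < needed:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for 3 subunit genes, "
                f"4x{self.n_signature_genes_per_subtype} signature genes and "
                f"{self.n_pemt_genes} p-EMT genes (need >= {needed})")


@dataclass
class SyntheticCohort:
    """A generated cohort plus every piece of planted ground truth."""

    expression: ExpressionMatrix
    isoforms: IsoformTable
    annotation: SampleAnnotation
    reference: CellTypeReference
    mixture_expression: ExpressionMatrix
    true_proportions: pd.DataFrame
    truth: dict

    @property
    def signature_gene_sets(self) -> dict[str, GeneSet]:
        return self.truth["signature_genes"]

    @property
    def signatures(self) -> dict[str, GeneSet]:
        return self.truth["signatures"]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws with the mean/dispersion parameterisation
    Var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def _to_tpm(counts: np.ndarray) -> np.ndarray:
    """Library-size normalisation to transcripts-per-million columns."""
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    return counts / totals * 1e6


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)

    tumor_ids = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, config.n_normal + 1)]
    sample_ids = tumor_ids + normal_ids

    props = np.array([config.subtype_proportions.get(s, 0.0) for s in SUBTYPES])
    subtype_of = pd.Series(
        rng.choice(list(SUBTYPES), size=config.n_tumor, p=props / props.sum()),
        index=tumor_ids, name="subtype")
    for s in SUBTYPES:
        if config.subtype_proportions.get(s, 0.0) > 0 and (subtype_of == s).sum() == 0:
            warnings.warn(f"subtype {s} has nonzero proportion but drew 0 tumors")

    # --- gene panel: 3 subunit genes, 4 signature blocks, a p-EMT block, background
    n_sig = config.n_signature_genes_per_subtype
    gene_ids = ["NFYA", "NFYB", "NFYC"] + [
        f"G{i:05d}" for i in range(1, config.n_genes - 2)]
    signature_genes: dict[str, GeneSet] = {}
    cursor = 3
    for s in SUBTYPES:
        signature_genes[s] = GeneSet(f"{s}_signature", gene_ids[cursor:cursor + n_sig])
        cursor += n_sig
    pemt_genes = GeneSet("pEMT", gene_ids[cursor:cursor + config.n_pemt_genes])

    # --- HPV and mutations (needed before expression: they shift isoforms)
    hpv = pd.Series("negative", index=tumor_ids, name="hpv_status")
    for s, frac in config.hpv_positive_fraction_by_subtype.items():
        members = subtype_of.index[subtype_of == s]
        positive = rng.random(len(members)) < frac
        hpv.loc[members[positive]] = "positive"

    mutation_sets = pd.Series([set() for _ in tumor_ids], index=tumor_ids)
    for gene in sorted(config.mutation_rates):
        carriers = rng.random(config.n_tumor) < config.mutation_rates[gene]
        for sid in np.asarray(tumor_ids)[carriers]:
            mutation_sets[sid].add(gene)

    # --- isoform ratios per tumor (log2-normal around the subtype mean)
    log2_ratio = pd.Series(0.0, index=sample_ids)
    for sid in tumor_ids:
        mu = math.log2(config.isoform_ratio_by_subtype[subtype_of[sid]])
        log2_ratio[sid] = rng.normal(mu, 0.5)
        for gene, eff in config.mutation_ratio_log2_effects.items():
            if gene in mutation_sets[sid]:
                log2_ratio[sid] += eff
        if hpv[sid] == "positive":
            log2_ratio[sid] += (config.hpv_isoform_log2_effects.get("NFYA_long", 0.0)
                                - config.hpv_isoform_log2_effects.get("NFYA_short", 0.0))
    for sid in normal_ids:
        log2_ratio[sid] = rng.normal(math.log2(config.normal_isoform_ratio), 0.5)

    # --- gene-level expression: NB counts around a structured mean, then TPM
    base_mu = rng.lognormal(mean=math.log(20.0), sigma=1.2, size=config.n_genes)
    mu = np.tile(base_mu[:, None], (1, len(sample_ids)))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    is_tumor = np.array([sid in set(tumor_ids) for sid in sample_ids])

    # subunit-level tumor elevation (strong for NFYA, moderate NFYB, slight NFYC)
    for gene, fold in (("NFYA", 2.0), ("NFYB", 1.6), ("NFYC", 1.2)):
        mu[gene_index[gene], is_tumor] *= fold
    # subtype signature blocks
    effect = 2.0 ** config.signature_log2_effect
    for s in SUBTYPES:
        cols = [sample_ids.index(sid) for sid in subtype_of.index[subtype_of == s]]
        rows = [gene_index[g] for g in signature_genes[s]]
        mu[np.ix_(rows, cols)] *= effect
    # p-EMT block: expression rises with the planted isoform log-ratio
    z_ratio = (log2_ratio[tumor_ids] - log2_ratio[tumor_ids].mean())
    sd = z_ratio.std(ddof=0)
    if sd > 0:
        z_ratio = z_ratio / sd
    pemt_rows = [gene_index[g] for g in pemt_genes]
    tumor_cols = [sample_ids.index(sid) for sid in tumor_ids]
    mu[np.ix_(pemt_rows, tumor_cols)] *= 2.0 ** (
        config.pemt_log2_slope * z_ratio.to_numpy()[None, :])

    mu = mu / mu.sum(axis=0, keepdims=True) * config.sequencing_depth
    counts = _nb_counts(rng, mu, config.nb_dispersion)
    expression = ExpressionMatrix(
        pd.DataFrame(_to_tpm(counts), index=gene_ids, columns=sample_ids))

    # --- isoform table (four tagged isoforms; TPM on their own scale)
    short_base = rng.lognormal(mean=math.log(25.0), sigma=0.4, size=len(sample_ids))
    short_tpm = pd.Series(short_base, index=sample_ids)
    short_tpm[is_tumor] *= 1.8  # both NF-YA isoforms rise in tumors
    hpv_short = config.hpv_isoform_log2_effects.get("NFYA_short", 0.0)
    for sid in tumor_ids:
        if hpv[sid] == "positive":
            short_tpm[sid] *= 2.0 ** hpv_short
    long_tpm = short_tpm * 2.0 ** log2_ratio
    nfyc1 = pd.Series(rng.lognormal(math.log(3.0), 0.4, len(sample_ids)), index=sample_ids)
    atypical_cols = list(subtype_of.index[subtype_of == "Atypical"])
    nfyc1[atypical_cols] *= 2.0
    nfyc2 = pd.Series(rng.lognormal(math.log(40.0), 0.3, len(sample_ids)), index=sample_ids)
    iso_data = pd.DataFrame(
        {sid: [long_tpm[sid], short_tpm[sid], nfyc1[sid], nfyc2[sid]]
         for sid in sample_ids},
        index=["NFYA-long", "NFYA-short", "NFYC-1", "NFYC-2"])
    isoforms = IsoformTable(
        iso_data,
        parent_gene=pd.Series({"NFYA-long": "NFYA", "NFYA-short": "NFYA",
                               "NFYC-1": "NFYC", "NFYC-2": "NFYC"}),
        roles={"NFYA_long": "NFYA-long", "NFYA_short": "NFYA-short",
               "NFYC1": "NFYC-1", "NFYC2": "NFYC-2"})

    # --- survival: hazard depends on the short-isoform quartile group
    if config.n_tumor >= 4:
        groups = quartile_stratify(short_tpm[tumor_ids])
    else:  # cohort too small for a quartile split
        groups = pd.Series("Low", index=tumor_ids, name="group")
    hazards = groups.map(config.hazard_by_group).astype(float)
    event_times = rng.exponential(1.0 / hazards.to_numpy())
    censor_times = rng.exponential(1.0 / config.censor_rate, size=config.n_tumor)
    pfi_time = np.minimum(event_times, censor_times)
    pfi_event = (event_times <= censor_times).astype(int)

    # --- annotation table
    ann_rows = []
    for i, sid in enumerate(tumor_ids):
        ann_rows.append({
            "sample_id": sid, "tissue": "tumor", "subtype": subtype_of[sid],
            "hpv_status": hpv[sid],
            "mutations": ";".join(sorted(mutation_sets[sid])) or SENTINEL,
            "pfi_time": f"{pfi_time[i]:.6g}", "pfi_event": str(pfi_event[i]),
        })
    for sid in normal_ids:
        ann_rows.append({
            "sample_id": sid, "tissue": "normal", "subtype": SENTINEL,
            "hpv_status": "unknown", "mutations": SENTINEL,
            "pfi_time": np.nan, "pfi_event": np.nan,
        })
    annotation = SampleAnnotation(pd.DataFrame(ann_rows))

    # --- cell-type reference and per-tumor mixtures (fibroblast-rich Mesenchymal)
    ref_seed = int(rng.integers(0, 2**31 - 1))
    mix_seed = int(rng.integers(0, 2**31 - 1))
    reference = generate_reference(
        n_genes=500, cell_types=["Cancer", "Fibroblast", "Immune"],
        n_markers_per_type=40, marker_log2_effect=3.0, seed=ref_seed)
    alpha_by_subtype = {
        "Mesenchymal": np.array([4.0, 4.5, 1.5]),
        "Basal": np.array([8.0, 1.5, 2.0]),
        "Atypical": np.array([8.0, 1.0, 2.5]),
        "Classical": np.array([8.0, 1.5, 2.0]),
    }
    mix_rng = np.random.default_rng(mix_seed)
    proportions = np.vstack([
        mix_rng.dirichlet(alpha_by_subtype[subtype_of[sid]]) for sid in tumor_ids])
    mixture_expression, true_proportions = generate_mixtures(
        reference, n_samples=config.n_tumor, dirichlet_alpha=(1.0, 1.0, 1.0),
        noise="nb", depth=1e6, seed=mix_seed, proportions=proportions,
        sample_ids=tumor_ids)

    # --- stand-in signature gene lists for the scoring stage
    mes_genes = list(signature_genes["Mesenchymal"])
    half = max(1, len(mes_genes) // 2)
    signatures = {
        "pEMT": pemt_genes,
        "CAF1": GeneSet("CAF1", mes_genes[:half]),
        "CAF2": GeneSet("CAF2", mes_genes[half:]),
    }

    truth = {
        "subtype_labels": subtype_of,
        "signature_genes": signature_genes,
        "signatures": signatures,
        "log2_ratio": log2_ratio,
        "survival_groups": groups,
        "hazards": dict(config.hazard_by_group),
        "mutation_sets": mutation_sets,
    }
    return SyntheticCohort(expression=expression, isoforms=isoforms,
                           annotation=annotation, reference=reference,
                           mixture_expression=mixture_expression,
                           true_proportions=true_proportions, truth=truth)


def generate_reference(n_genes: int, cell_types: list[str],
                       n_markers_per_type: int, marker_log2_effect: float,
                       seed: int) -> CellTypeReference:
    """Genes × cell-types mean-profile basis with planted marker blocks.

    Each cell type gets ``n_markers_per_type`` genes elevated by
    ``marker_log2_effect`` (log2) over a shared lognormal baseline; columns
    are scaled to TPM (sum 1e6).
    """
    if len(cell_types) < 2:
        raise ConfigError("need >=2 cell types")
    if n_genes < n_markers_per_type * len(cell_types):
        raise ConfigError(
            f"{n_genes} genes cannot hold {len(cell_types)}x{n_markers_per_type} markers")
    rng = np.random.default_rng(seed)
    gene_ids = [f"R{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.lognormal(mean=math.log(20.0), sigma=1.0, size=n_genes)
    basis = np.tile(base[:, None], (1, len(cell_types)))
    markers: dict[str, GeneSet] = {}
    cursor = 0
    for k, cell_type in enumerate(cell_types):
        rows = slice(cursor, cursor + n_markers_per_type)
        basis[rows, k] *= 2.0 ** marker_log2_effect
        markers[cell_type] = GeneSet(f"{cell_type}_markers", gene_ids[rows])
        cursor += n_markers_per_type
    basis = basis / basis.sum(axis=0, keepdims=True) * 1e6
    return CellTypeReference(
        pd.DataFrame(basis, index=gene_ids, columns=list(cell_types)),
        marker_genes=markers)


def generate_mixtures(reference: CellTypeReference, n_samples: int,
                      dirichlet_alpha, noise: str = "none", depth: float = 1e6,
                      seed: int = 0, dispersion: float = 0.05,
                      proportions: np.ndarray | None = None,
                      sample_ids: list[str] | None = None,
                      ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk profiles as known mixtures of the reference basis.

    Each sample's profile is basis · p with p ~ Dirichlet(alpha) (or the
    explicitly supplied ``proportions`` rows).  With ``noise="nb"`` the
    profile is re-drawn as negative-binomial counts at the stated sequencing
    depth and re-normalised to TPM; ``noise="none"`` returns the exact
    mixture.  Returns the bulk matrix and the true proportions per sample.
    """
    k = len(reference.cell_type_names)
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if proportions is None:
        if alpha.size != k:
            raise ConfigError(f"alpha length {alpha.size} != {k} cell types")
        if (alpha <= 0).any():
            raise ConfigError("dirichlet alpha must be positive")
    if noise not in ("none", "nb"):
        raise ConfigError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = rng.dirichlet(alpha, size=n_samples)
    else:
        proportions = np.asarray(proportions, dtype=float)
        if proportions.shape != (n_samples, k):
            raise ConfigError("explicit proportions must be n_samples × n_types")
    basis = reference.data.to_numpy()
    bulk = basis @ proportions.T
    if noise == "nb":
        scale = bulk.sum(axis=0, keepdims=True)
        mean_counts = bulk / scale * depth
        bulk = _to_tpm(_nb_counts(rng, mean_counts, dispersion))
    if sample_ids is None:
        sample_ids = [f"M{i:04d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(pd.DataFrame(bulk, index=reference.gene_ids,
                                         columns=sample_ids))
    props = pd.DataFrame(proportions, index=pd.Index(sample_ids, name="sample_id"),
                         columns=reference.cell_type_names)
    return expr, props


def load_cohort_config(path) -> CohortConfig:
    """Read a CohortConfig from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(CohortConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**raw)
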