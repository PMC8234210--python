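import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from nfypipe.data_model import SUBTYPES
from nfypipe.deconvolution import estimate_proportions
from nfypipe.stats_core import rank_sum_test
from nfypipe.synthetic_data import (
    CohortConfig,
    ConfigError,
    generate_cohort,
    generate_mixtures,
    generate_reference,
)


def test_same_seed_identical_cohorts():
    config = CohortConfig(n_tumor=40, n_normal=10, n_genes=400, seed=5)
    a = generate_cohort(config)
    b = generate_cohort(config)
    assert a.expression.equals(b.expression)
    assert a.isoforms.data.equals(b.isoforms.data)
    assert a.annotation.table.equals(b.annotation.table)
    assert a.true_proportions.equals(b.true_proportions)


def test_null_effect_means_no_subtype_structure():
    """With zero signature effect, per-gene subtype differences are sampling
    noise: the rank-sum test rejects at alpha=0.01 for <=5% of genes."""
    config = CohortConfig(n_tumor=160, n_normal=10, n_genes=400,
                          signature_log2_effect=0.0, pemt_log2_slope=0.0,
                          seed=29)
    cohort = generate_cohort(config)
    labels = cohort.truth["subtype_labels"]
    mes = list(labels.index[labels == "Mesenchymal"])
    rest = list(labels.index[labels != "Mesenchymal"])
    tpm = cohort.expression.data
    sig_genes = [g for s in SUBTYPES for g in cohort.signature_gene_sets[s]]
    rejected = sum(
        rank_sum_test(tpm.loc[g, mes], tpm.loc[g, rest]).p_value < 0.01
        for g in sig_genes)
    assert rejected / len(sig_genes) <= 0.05


def test_subtype_counts_within_binomial_interval():
    config = CohortConfig(n_tumor=400, n_normal=10, n_genes=300,
                          subtype_proportions={s: 0.25 for s in SUBTYPES},
                          seed=17)
    cohort = generate_cohort(config)
    counts = cohort.truth["subtype_labels"].value_counts()
    lo, hi = binom.ppf([0.005, 0.995], 400, 0.25)
    for s in SUBTYPES:
        assert lo <= counts[s] <= hi


def test_truth_covers_every_tumor(small_cohort):
    assert set(small_cohort.truth["subtype_labels"].index) == set(
        small_cohort.annotation.tumor_ids)
    assert set(small_cohort.truth["survival_groups"].index) == set(
        small_cohort.annotation.tumor_ids)


def test_isoform_ratio_subtype_means(small_cohort):
    """Planted log2-ratio means follow the configured subtype ordering."""
    labels = small_cohort.truth["subtype_labels"]
    ratio = small_cohort.truth["log2_ratio"]
    mes = ratio[labels.index[labels == "Mesenchymal"]].mean()
    aty = ratio[labels.index[labels == "Atypical"]].mean()
    assert mes > aty


def test_hpv_concentrated_in_atypical(small_cohort):
    labels = small_cohort.truth["subtype_labels"]
    hpv = small_cohort.annotation.hpv_labels().loc[labels.index]
    frac_atypical = (hpv[labels == "Atypical"] == "positive").mean()
    frac_other = (hpv[labels != "Atypical"] == "positive").mean()
    assert frac_atypical > frac_other


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        CohortConfig(subtype_proportions={"Basal": 0.9, "Mesenchymal": 0.2,
                                          "Atypical": 0.0, "Classical": 0.0})
    with pytest.raises(ConfigError):
        CohortConfig(mutation_rates={"TP53": 1.4})
    with pytest.raises(ConfigError):
        CohortConfig(n_genes=10)
    with pytest.raises(ConfigError):
        CohortConfig(nb_dispersion=-1.0)


def test_reference_markers_and_determinism():
    ref = generate_reference(200, ["A", "B"], n_markers_per_type=10,
                             marker_log2_effect=4.0, seed=3)
    again = generate_reference(200, ["A", "B"], n_markers_per_type=10,
                               marker_log2_effect=4.0, seed=3)
    assert ref.data.equals(again.data)
    # columns differ beyond noise on exactly the 20 marker genes
    ratio = np.log2((ref.data["A"] + 1) / (ref.data["B"] + 1))
    marker_ids = (list(ref.marker_genes["A"]) + list(ref.marker_genes["B"]))
    big = set(ratio.index[ratio.abs() > 1.0])
    assert big == set(marker_ids)
    with pytest.raises(ConfigError):
        generate_reference(15, ["A", "B"], 10, 2.0, seed=0)
    with pytest.raises(ConfigError):
        generate_reference(100, ["A"], 10, 2.0, seed=0)


def test_reference_null_effect_columns_exchangeable():
    """With zero marker effect the two basis columns are identical profiles
    (the generator plants no difference)."""
    ref = generate_reference(300, ["A", "B", "C"], 20, 0.0, seed=9)
    assert np.allclose(ref.data["A"], ref.data["B"])
    assert np.allclose(ref.data["B"], ref.data["C"])


def test_mixtures_simplex_and_identity():
    ref = generate_reference(150, ["A", "B", "C"], 15, 3.0, seed=2)
    expr, props = generate_mixtures(ref, n_samples=25,
                                    dirichlet_alpha=(1.0, 1.0, 1.0),
                                    noise="none", seed=4)
    assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
    # a forced pure sample equals the corresponding basis column
    pure = np.zeros((1, 3))
    pure[0, 1] = 1.0
    expr_pure, _ = generate_mixtures(ref, 1, (1, 1, 1), noise="none",
                                     seed=4, proportions=pure)
    assert np.allclose(expr_pure.values[:, 0], ref.data["B"], atol=1e-9)
    with pytest.raises(ConfigError):
        generate_mixtures(ref, 5, (1.0, -1.0, 1.0))
    with pytest.raises(ConfigError):
        generate_mixtures(ref, 5, (1.0, 1.0))


def test_noiseless_mixtures_recovered_by_deconvolution():
    """The constructing equation is the oracle: solving the noiseless system
    returns the true proportions to 1e-6."""
    ref = generate_reference(300, ["A", "B", "C"], 30, 3.0, seed=8)
    expr, props = generate_mixtures(ref, n_samples=40,
                                    dirichlet_alpha=(2.0, 2.0, 2.0),
                                    noise="none", seed=8)
    est = estimate_proportions(expr, ref, gene_selection="all")
    err = np.abs(est.data.to_numpy() - props.to_numpy()).max()
    assert err < 1e-6


def test_tiny_cohort_empty_subtype_warns():
    config = CohortConfig(n_tumor=3, n_normal=2, n_genes=300, seed=1)
    with pytest.warns(UserWarning, match="0 tumors"):
        generate_cohort(config)
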