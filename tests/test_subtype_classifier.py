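import numpy as np
import pandas as pd
import pytest

from nfypipe.data_model import SUBTYPES, ExpressionMatrix, GeneSet
from nfypipe.subtype_classifier import (
    CentroidMatrix,
    build_centroids,
    classify,
    classify_cohort,
    median_center,
)


def _centered(frame):
    return ExpressionMatrix(frame, log_transformed=True)


def test_median_center_examples():
    frame = pd.DataFrame([[1.0, 2.0, 3.0], [7.0, 7.0, 7.0]],
                         index=["g1", "g2"], columns=["a", "b", "c"])
    mat = ExpressionMatrix(frame, log_transformed=True)
    centered = median_center(mat, GeneSet("s", ["g1", "g2"]))
    assert centered.data.loc["g1"].tolist() == [-1.0, 0.0, 1.0]
    assert centered.data.loc["g2"].tolist() == [0.0, 0.0, 0.0]
    twice = median_center(centered, GeneSet("s", ["g1", "g2"]))
    assert np.allclose(twice.values, centered.values)


def test_median_center_missing_gene_listed():
    frame = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"])
    with pytest.raises(KeyError, match="gX"):
        median_center(ExpressionMatrix(frame, log_transformed=True),
                      GeneSet("s", ["g1", "gX"]))


def _four_sample_training():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.normal(size=(10, 4)),
                         index=[f"g{i}" for i in range(10)],
                         columns=["sA", "sB", "sC", "sD"])
    labels = pd.Series(dict(zip(frame.columns, SUBTYPES)))
    return _centered(frame), labels


def test_build_centroids_mean_of_one_and_duplication_invariance():
    centered, labels = _four_sample_training()
    cents = build_centroids(centered, labels)
    for sample, subtype in labels.items():
        assert np.allclose(cents.data[subtype], centered.data[sample])
    doubled = ExpressionMatrix(
        pd.concat([centered.data, centered.data.add_suffix("_copy")], axis=1),
        log_transformed=True)
    labels2 = pd.concat([labels, labels.rename(lambda s: s + "_copy")])
    cents2 = build_centroids(doubled, labels2)
    assert np.allclose(cents.data, cents2.data)


def test_build_centroids_label_permutation_equivariance():
    centered, labels = _four_sample_training()
    cents = build_centroids(centered, labels)
    rotated = pd.Series(dict(zip(labels.index, np.roll(labels.to_numpy(), 1))))
    cents_rot = build_centroids(centered, rotated)
    for sample, subtype in labels.items():
        assert np.allclose(cents_rot.data[rotated[sample]], cents.data[subtype])


def test_build_centroids_empty_subtype_named():
    centered, labels = _four_sample_training()
    with pytest.raises(ValueError, match="Mesenchymal"):
        build_centroids(centered, labels[labels != "Mesenchymal"])


def test_classify_self_correlation():
    centered, labels = _four_sample_training()
    cents = build_centroids(centered, labels)
    calls = {c.sample_id: c for c in classify(centered, cents)}
    for sample, subtype in labels.items():
        assert calls[sample].assigned_subtype == subtype
        assert calls[sample].correlations[subtype] == pytest.approx(1.0)


def test_classify_anticorrelated_sample_not_assigned_to_negation():
    rng = np.random.default_rng(1)
    a = rng.normal(size=12)
    b = rng.normal(size=12)
    cents = CentroidMatrix(pd.DataFrame(
        {"A": a, "B": b}, index=[f"g{i}" for i in range(12)]))
    sample = ExpressionMatrix(
        pd.DataFrame({"s": -a}, index=cents.data.index), log_transformed=True)
    (call,) = classify(sample, cents)
    assert call.assigned_subtype != "A"


def test_classify_zero_variance_sample_unassigned():
    cents = CentroidMatrix(pd.DataFrame(
        np.random.default_rng(2).normal(size=(5, 2)),
        index=[f"g{i}" for i in range(5)], columns=["A", "B"]))
    flat = ExpressionMatrix(pd.DataFrame({"s": np.ones(5)},
                                         index=cents.data.index),
                            log_transformed=True)
    (call,) = classify(flat, cents)
    assert call.assigned_subtype == "unassigned"


def test_classification_invariant_under_affine_transform():
    """Pearson correlation ignores per-sample scale and offset."""
    centered, labels = _four_sample_training()
    cents = build_centroids(centered, labels)
    warped = ExpressionMatrix(centered.data * 3.7 + 2.0, log_transformed=True)
    raw = [c.assigned_subtype for c in classify(centered, cents)]
    aff = [c.assigned_subtype for c in classify(warped, cents)]
    assert raw == aff


def test_classify_matches_bruteforce_argmax(rng):
    genes = [f"g{i}" for i in range(8)]
    cents = CentroidMatrix(pd.DataFrame(rng.normal(size=(8, 4)), index=genes,
                                        columns=list(SUBTYPES)))
    samples = pd.DataFrame(rng.normal(size=(8, 6)), index=genes,
                           columns=[f"s{i}" for i in range(6)])
    calls = classify(_centered(samples), cents)
    for call in calls:
        brute = {s: np.corrcoef(samples[call.sample_id], cents.data[s])[0, 1]
                 for s in SUBTYPES}
        assert call.assigned_subtype == max(brute, key=brute.get)


def test_cohort_recovery_at_large_effect(small_cohort):
    """With a log2 signature effect of 2 the classifier recovers >=95% of
    the true subtype labels."""
    truth = small_cohort.truth["subtype_labels"]
    signature = GeneSet("sig", [g for s in SUBTYPES
                                for g in small_cohort.signature_gene_sets[s]])
    tumor_expr = small_cohort.expression.subset_samples(list(truth.index))
    calls = classify_cohort(tumor_expr, signature, training_labels=truth)
    accuracy = (calls["subtype"] == truth.loc[calls.index]).mean()
    assert accuracy >= 0.95
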