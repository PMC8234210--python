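import numpy as np
import pandas as pd
import pytest

from nfypipe.data_model import ExpressionMatrix
from nfypipe.deconvolution import (
    CellTypeReference,
    ProportionMatrix,
    build_basis,
    estimate_proportions,
    fibroblast_filter,
    nnls_solve,
)
from nfypipe.synthetic_data import generate_mixtures, generate_reference


def _sc_matrix(rng, n_genes=30, cells_per_type=4, types=("A", "B", "C")):
    cols, labels = [], {}
    data = {}
    for t in types:
        for i in range(cells_per_type):
            cid = f"{t}{i}"
            cols.append(cid)
            labels[cid] = t
            data[cid] = rng.lognormal(1.0, 0.5, n_genes)
    frame = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])
    return ExpressionMatrix(frame), pd.Series(labels)


def test_build_basis_mean_of_one_and_invariances(rng):
    sc, labels = _sc_matrix(rng, cells_per_type=1)
    ref = build_basis(sc, labels)
    for cid, t in labels.items():
        assert np.allclose(ref.data[t], sc.data[cid])
    sc4, labels4 = _sc_matrix(rng, cells_per_type=4)
    ref4 = build_basis(sc4, labels4)
    doubled = ExpressionMatrix(
        pd.concat([sc4.data, sc4.data.add_suffix("_d")], axis=1))
    labels_d = pd.concat([labels4, labels4.rename(lambda c: c + "_d")])
    assert np.allclose(build_basis(doubled, labels_d).data, ref4.data)
    shuffled_cols = list(rng.permutation(sc4.data.columns))
    shuffled = ExpressionMatrix(sc4.data[shuffled_cols])
    assert np.allclose(build_basis(shuffled, labels4).data, ref4.data)


def test_build_basis_min_cells_enforced(rng):
    sc, labels = _sc_matrix(rng, cells_per_type=2)
    with pytest.raises(ValueError, match="min_cells_per_type"):
        build_basis(sc, labels, min_cells_per_type=3)


def test_nnls_identity_and_construction_oracle(rng):
    coef = nnls_solve(np.eye(2), np.array([2.0, 3.0]))
    assert np.allclose(coef, [2.0, 3.0])
    design = rng.lognormal(0, 1, size=(50, 4))
    x_true = np.array([0.5, 0.0, 2.0, 1.2])
    est = nnls_solve(design, design @ x_true)
    assert np.abs(est - x_true).max() < 1e-6


def test_nnls_negative_orthogonal_target_zero_solution():
    design = np.array([[1.0, 0.5], [0.0, 1.0]])
    coef = nnls_solve(design, np.array([-3.0, -1.0]))
    assert np.allclose(coef, 0.0)


def test_nnls_zero_column_warns(rng):
    design = np.column_stack([rng.lognormal(0, 1, 10), np.zeros(10)])
    with pytest.warns(UserWarning, match="all-zero"):
        coef = nnls_solve(design, design[:, 0] * 2.0)
    assert coef[1] == 0.0


def test_pure_sample_gets_proportion_one():
    ref = generate_reference(120, ["A", "B", "C"], 12, 3.0, seed=1)
    bulk = ExpressionMatrix(ref.data[["B"]].rename(columns={"B": "s1"}))
    props = estimate_proportions(bulk, ref, gene_selection="all")
    assert props.data.loc["s1", "B"] == pytest.approx(1.0, abs=1e-9)


def test_noiseless_recovery_to_machine_precision():
    ref = generate_reference(250, ["A", "B", "C"], 25, 3.0, seed=5)
    expr, truth = generate_mixtures(ref, 30, (2.0, 2.0, 2.0), noise="none",
                                    seed=6)
    est = estimate_proportions(expr, ref, gene_selection="all")
    assert np.abs(est.data.to_numpy() - truth.to_numpy()).max() < 1e-6


def test_nb_noise_recovery_rmse():
    """3 cell types, 200 marker genes, depth 1e6, 100 samples: mean
    per-sample RMSE of recovered proportions below 0.05."""
    ref = generate_reference(700, ["A", "B", "C"], 200, 3.0, seed=7)
    expr, truth = generate_mixtures(ref, 100, (2.0, 2.0, 2.0), noise="nb",
                                    depth=1e6, seed=8)
    est = estimate_proportions(expr, ref, gene_selection="markers")
    err = est.data.to_numpy() - truth.to_numpy()
    rmse = np.sqrt((err ** 2).mean(axis=1))
    assert rmse.mean() < 0.05


def test_proportions_invariant_to_bulk_rescaling():
    ref = generate_reference(150, ["A", "B"], 15, 3.0, seed=9)
    expr, _ = generate_mixtures(ref, 10, (2.0, 2.0), noise="none", seed=10)
    scaled = ExpressionMatrix(expr.data * 37.5)
    a = estimate_proportions(expr, ref, "all").data
    b = estimate_proportions(scaled, ref, "all").data
    assert np.allclose(a, b, atol=1e-9)


def test_fibroblast_filter_boundary_rule():
    frame = pd.DataFrame({"Cancer": [0.71, 0.70, 0.69],
                          "Fibroblast": [0.29, 0.30, 0.31]},
                         index=["a", "b", "c"])
    props = ProportionMatrix(frame)
    assert fibroblast_filter(props, "Fibroblast", 0.30) == ["a"]
    assert fibroblast_filter(props, "Fibroblast", 1.0) == ["a", "b", "c"]
    removed = set(frame.index) - set(fibroblast_filter(props, "Fibroblast", 0.30))
    assert removed == {"b", "c"}
    with pytest.raises(KeyError, match="CAF"):
        fibroblast_filter(props, "CAF")


def test_proportion_matrix_invariants():
    with pytest.raises(Exception):
        ProportionMatrix(pd.DataFrame({"A": [0.5], "B": [0.6]}))
    with pytest.raises(Exception):
        ProportionMatrix(pd.DataFrame({"A": [-0.1], "B": [1.1]}))


def test_reference_rejects_negative_or_single_type():
    with pytest.raises(Exception):
        CellTypeReference(pd.DataFrame({"A": [1.0]}))
    with pytest.raises(Exception):
        CellTypeReference(pd.DataFrame({"A": [1.0], "B": [-1.0]}))
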