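"""Reference-based cell-type deconvolution of bulk expression profiles.

A labelled single-cell expression matrix is collapsed into a basis of
per-type mean profiles (linear TPM — mixing is linear in abundance); each
bulk sample is then decomposed by non-negative least squares (NNLS) over a
selected gene set, and the coefficients are normalised to the simplex to
give cell-type proportions.  A fibroblast-fraction filter removes samples
dominated by stroma (predicted fibroblast proportion at or above 30% by
default) before malignant-cell signature scoring.

This is a single-reference NNLS deconvolution: ensemble/tree-guided
weighting schemes used by some deconvolution packages are intentionally out
of scope, and an optional one-step variance-reweighted refinement is
provided instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from nfypipe.data_model import DataFormatError, ExpressionMatrix, GeneSet


@dataclass
class CellTypeReference:
    """Genes × cell-types basis of mean linear-scale expression profiles."""

    data: pd.DataFrame
    marker_genes: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise DataFormatError("need >=2 cell types in reference basis")
        if (self.data.to_numpy() < 0).any():
            raise DataFormatError("negative values in reference basis")
        if self.data.index.has_duplicates:
            raise DataFormatError("duplicate genes in reference basis")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_type_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ProportionMatrix:
    """Samples × cell-types proportions; every row on the unit simplex."""

    data: pd.DataFrame
    degenerate_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if (values < -1e-12).any():
            raise DataFormatError("negative proportions")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise DataFormatError("proportion rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_type_names(self) -> list[str]:
        return list(self.data.columns)


def build_basis(sc_expr: ExpressionMatrix, cell_labels: pd.Series,
                min_cells_per_type: int = 1) -> CellTypeReference:
    """Collapse a labelled single-cell matrix into per-type mean profiles."""
    labels = pd.Series(cell_labels)
    missing = [c for c in labels.index if c not in sc_expr.data.columns]
    if missing:
        raise KeyError(f"labelled cells absent from matrix: {missing[:5]}")
    if sc_expr.log_transformed:
        raise ValueError("basis must be built from linear-scale expression")
    counts = labels.value_counts()
    thin = counts[counts < min_cells_per_type]
    if len(thin):
        raise ValueError(
            f"cell type(s) below min_cells_per_type={min_cells_per_type}: "
            f"{sorted(thin.index)}")
    cols = {
        str(cell_type): sc_expr.data[list(labels.index[labels == cell_type])].mean(axis=1)
        for cell_type in counts.index.sort_values()
    }
    return CellTypeReference(pd.DataFrame(cols))


def nnls_solve(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Non-negative least squares: argmin_{x>=0} ||design·x − target||²."""
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float)
    if design.ndim != 2 or target.ndim != 1 or design.shape[0] != target.size:
        raise ValueError("design (m×k) and target (m) dimensions must conform")
    zero_cols = ~design.any(axis=0)
    if zero_cols.any():
        warnings.warn(f"{int(zero_cols.sum())} all-zero design column(s); "
                      "their coefficients are fixed at 0")
    coef, _ = scipy.optimize.nnls(design, target)
    return coef


def select_genes(bulk: ExpressionMatrix, reference: CellTypeReference,
                 gene_selection: str = "markers", top_k: int = 500) -> list[str]:
    """Choose the genes the per-sample NNLS is solved over.

    ``markers``: union of the reference's per-type marker sets when present,
    otherwise the top ``top_k``-per-type genes ranked by fold of the type's
    basis value over the mean of the other types.  ``top_variance_k``: the
    ``top_k`` highest-variance basis genes.  ``all``: every shared gene.
    """
    shared = [g for g in reference.gene_ids if g in bulk.data.index]
    if gene_selection == "all":
        return shared
    basis = reference.data.loc[shared]
    if gene_selection == "markers":
        if reference.marker_genes:
            union: list[str] = []
            for gs in reference.marker_genes.values():
                union.extend(g for g in gs if g in basis.index and g not in union)
            return union
        per_type = max(1, top_k // len(reference.cell_type_names))
        chosen: list[str] = []
        for cell_type in reference.cell_type_names:
            others = basis.drop(columns=cell_type).mean(axis=1)
            fold = (basis[cell_type] + 1.0) / (others + 1.0)
            for g in fold.nlargest(per_type).index:
                if g not in chosen:
                    chosen.append(g)
        return chosen
    if gene_selection == "top_variance_k":
        return list(basis.var(axis=1).nlargest(top_k).index)
    raise ValueError(f"unknown gene_selection {gene_selection!r}")


def estimate_proportions(bulk: ExpressionMatrix, reference: CellTypeReference,
                         gene_selection: str = "markers",
                         top_k: int = 500,
                         reweight: bool = False) -> ProportionMatrix:
    """Per-sample NNLS proportions of each reference cell type.

    Coefficients are normalised to sum to one.  A sample whose NNLS solution
    is identically zero gets uniform proportions and is listed in
    ``degenerate_samples``.  With ``reweight=True`` a second NNLS pass
    down-weights genes by the residual scale of the first fit (a one-step
    variance reweighting).
    """
    genes = select_genes(bulk, reference, gene_selection, top_k)
    k = len(reference.cell_type_names)
    if len(genes) < k:
        raise ValueError(
            f"only {len(genes)} usable shared genes for {k} cell types")
    design = reference.data.loc[genes].to_numpy()
    targets = bulk.data.loc[genes].to_numpy()
    rows = np.empty((bulk.shape[1], k))
    degenerate: list[str] = []
    for j, sample_id in enumerate(bulk.sample_ids):
        coef = nnls_solve(design, targets[:, j])
        if reweight and coef.sum() > 0:
            resid = targets[:, j] - design @ coef
            scale = np.sqrt(np.abs(design @ coef) + np.median(np.abs(resid)) + 1e-9)
            coef = nnls_solve(design / scale[:, None], targets[:, j] / scale)
        total = coef.sum()
        if total <= 0:
            rows[j] = np.full(k, 1.0 / k)
            degenerate.append(sample_id)
        else:
            rows[j] = coef / total
    frame = pd.DataFrame(rows, index=pd.Index(bulk.sample_ids, name="sample_id"),
                         columns=reference.cell_type_names)
    return ProportionMatrix(frame, degenerate)


def fibroblast_filter(props: ProportionMatrix, fibroblast_type: str = "Fibroblast",
                      max_fraction: float = 0.30) -> list[str]:
    """Sample ids with predicted fibroblast proportion strictly below the cap.

    The boundary value (exactly ``max_fraction``) is excluded, matching the
    "lower than 30%" selection rule.
    """
    if fibroblast_type not in props.data.columns:
        raise KeyError(f"cell type {fibroblast_type!r} not in proportion matrix "
                       f"(have {props.cell_type_names})")
    mask = props.data[fibroblast_type] < max_fraction
    return list(props.data.index[mask])
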