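"""Typed containers for expression, isoform, annotation and gene-set tables.

All on-disk formats are tab-separated text, matching the layout of
firebrowse-style matrices (first row sample identifiers, first column gene
identifiers).  TPM values are stored on the linear scale; the log2 transform
is applied lazily and recorded in a flag so it can never be applied twice
silently.  Missing annotation fields are encoded by the sentinel ``NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SENTINEL = "NA"

TISSUES = ("tumor", "normal")
SUBTYPES = ("Atypical", "Basal", "Classical", "Mesenchymal")
UNASSIGNED = "unassigned"
HPV_STATUSES = ("positive", "negative", "unknown")

#: role tags an IsoformTable may carry for the NF-Y splice isoforms
ISOFORM_ROLES = ("NFYA_long", "NFYA_short", "NFYC1", "NFYC2")


class DataFormatError(ValueError):
    """Structural problem in an input table (duplicates, bad shape, bad value)."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names the offending row/column."""


def _check_unique(ids, what: str) -> None:
    index = pd.Index(ids)
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of expression values (TPM or log2(TPM+1)).

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, all numeric.
    log_transformed : bool
        True if values are log2(TPM + pseudocount); False for linear TPM,
        in which case values must be non-negative.
    """

    data: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataFormatError("expression matrix contains non-numeric values")
        if not self.log_transformed and np.nanmin(values, initial=0.0) < 0:
            raise DataFormatError("negative values in a linear-scale TPM matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(TPM + pseudocount) copy; no-op if already in log space."""
        if self.log_transformed:
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), log_transformed=True)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.log_transformed)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.log_transformed)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.log_transformed == other.log_transformed
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass
class IsoformTable:
    """Isoforms × samples TPM table with a parent-gene map and optional role tags.

    ``roles`` maps a role name (see :data:`ISOFORM_ROLES`) to the isoform id
    that plays it, e.g. ``{"NFYA_long": "NFYA-202", "NFYA_short": "NFYA-201"}``.
    """

    data: pd.DataFrame
    parent_gene: pd.Series  # isoform id -> gene id
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "isoform ids")
        _check_unique(self.data.columns, "sample ids")
        if np.nanmin(self.data.to_numpy(), initial=0.0) < 0:
            raise DataFormatError("negative isoform TPM values")
        unmapped = self.data.index.difference(self.parent_gene.index)
        if len(unmapped):
            raise DataFormatError(f"isoforms without a parent gene: {list(unmapped)[:5]}")
        for role, iso in self.roles.items():
            if iso not in self.data.index:
                raise DataFormatError(f"role {role!r} points at unknown isoform {iso!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def role_values(self, role: str) -> pd.Series:
        """TPM row (per sample) of the isoform carrying ``role``."""
        if role not in self.roles:
            raise KeyError(f"isoform role {role!r} not tagged in table")
        return self.data.loc[self.roles[role]]


ANNOTATION_COLUMNS = [
    "sample_id",
    "tissue",
    "subtype",
    "hpv_status",
    "mutations",
    "pfi_time",
    "pfi_event",
]


@dataclass
class SampleAnnotation:
    """Per-sample clinical/molecular metadata for a cohort.

    One row per sample: tissue (tumor/normal), molecular subtype (tumors
    only), HPV status, the set of genes carrying at least one somatic
    mutation, and the progression-free-interval endpoint (time in days plus
    a 0/1 event indicator, 1 = progression observed).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"annotation missing columns: {missing}")
        _check_unique(self.table["sample_id"], "sample ids")
        bad_tissue = set(self.table["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise DataFormatError(f"unknown tissue values: {sorted(bad_tissue)}")
        valid_subtypes = set(SUBTYPES) | {UNASSIGNED, SENTINEL}
        bad_sub = set(self.table["subtype"].astype(str)) - valid_subtypes
        if bad_sub:
            raise DataFormatError(f"unknown subtype values: {sorted(bad_sub)}")
        normals = self.table[self.table["tissue"] == "normal"]
        labelled_normals = normals[normals["subtype"].isin(SUBTYPES)]
        if len(labelled_normals):
            raise DataFormatError("subtype labels present on normal samples")
        times = pd.to_numeric(self.table["pfi_time"], errors="coerce")
        if (times.dropna() < 0).any():
            raise DataFormatError("negative pfi_time")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.table.loc[self.table["tissue"] == "tumor", "sample_id"])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.table.loc[self.table["tissue"] == "normal", "sample_id"])

    def subtype_labels(self) -> pd.Series:
        """Subtype per tumor sample (sentinel rows excluded)."""
        tumors = self.table[self.table["tissue"] == "tumor"]
        labels = tumors.set_index("sample_id")["subtype"]
        return labels[labels.isin(SUBTYPES)]

    def hpv_labels(self) -> pd.Series:
        return self.table.set_index("sample_id")["hpv_status"]

    def mutation_carriers(self, gene: str) -> pd.Series:
        """Boolean per tumor sample: carries >=1 somatic mutation in ``gene``."""
        tumors = self.table[self.table["tissue"] == "tumor"].set_index("sample_id")
        return tumors["mutations"].map(lambda s: gene in _split_mutations(s))

    def mutation_sets(self) -> pd.Series:
        tumors = self.table[self.table["tissue"] == "tumor"].set_index("sample_id")
        return tumors["mutations"].map(_split_mutations)

    def survival_frame(self) -> pd.DataFrame:
        """Tumor samples with a usable PFI record (time, event as numbers)."""
        tumors = self.table[self.table["tissue"] == "tumor"].copy()
        tumors["pfi_time"] = pd.to_numeric(tumors["pfi_time"], errors="coerce")
        tumors["pfi_event"] = pd.to_numeric(tumors["pfi_event"], errors="coerce")
        tumors = tumors.dropna(subset=["pfi_time", "pfi_event"])
        return tumors.set_index("sample_id")[["pfi_time", "pfi_event"]]


def _split_mutations(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if text in ("", SENTINEL):
        return frozenset()
    return frozenset(text.split(";"))


@dataclass
class GeneSet:
    """Named non-empty list of gene identifiers (duplicates forbidden)."""

    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataFormatError(f"gene set {self.name!r} is empty")
        _check_unique(self.gene_ids, f"gene ids in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_numeric_table(path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    _check_unique(df.index, f"row ids in {path.name}")
    _check_unique(df.columns, f"column ids in {path.name}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TableParseError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"in {path}: {df.iloc[r, c]!r}"
        )
    return numeric.astype(float)


def read_expression_matrix(path, delimiter: str = "\t",
                           log_transformed: bool = False) -> ExpressionMatrix:
    """Read a genes×samples TSV (first row sample ids, first column gene ids)."""
    return ExpressionMatrix(_read_numeric_table(path, delimiter), log_transformed)


def read_isoform_table(path, parent_path, delimiter: str = "\t",
                       roles: dict[str, str] | None = None) -> IsoformTable:
    """Read an isoforms×samples TSV plus a two-column isoform→gene map TSV."""
    data = _read_numeric_table(path, delimiter)
    parents = pd.read_csv(parent_path, sep=delimiter, index_col=0, dtype=str).iloc[:, 0]
    return IsoformTable(data, parents, roles or {})


def read_annotation(path, delimiter: str = "\t") -> SampleAnnotation:
    table = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if "pfi_time" in table.columns:
        table["pfi_time"] = table["pfi_time"].replace(SENTINEL, np.nan)
        table["pfi_event"] = table["pfi_event"].replace(SENTINEL, np.nan)
    return SampleAnnotation(table)


def read_gene_set(path, delimiter: str = "\t") -> list[GeneSet]:
    """Read a two-column TSV (set name, gene id) into one GeneSet per name."""
    table = pd.read_csv(path, sep=delimiter, header=None,
                        names=["name", "gene_id"], dtype=str)
    sets = []
    for name, chunk in table.groupby("name", sort=False):
        sets.append(GeneSet(str(name), list(chunk["gene_id"])))
    return sets


_FLOAT_FORMAT = "%.10g"


def write_table(obj, path, delimiter: str = "\t") -> None:
    """Write any nfypipe tabular object so that the matching reader recovers it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ExpressionMatrix):
        obj.data.to_csv(path, sep=delimiter, float_format=_FLOAT_FORMAT)
    elif isinstance(obj, IsoformTable):
        obj.data.to_csv(path, sep=delimiter, float_format=_FLOAT_FORMAT)
    elif isinstance(obj, SampleAnnotation):
        out = obj.table.copy()
        out["pfi_time"] = out["pfi_time"].fillna(SENTINEL)
        out["pfi_event"] = out["pfi_event"].fillna(SENTINEL)
        out.to_csv(path, sep=delimiter, index=False)
    elif isinstance(obj, GeneSet):
        pd.DataFrame({"name": obj.name, "gene_id": obj.gene_ids}).to_csv(
            path, sep=delimiter, index=False, header=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=delimiter, float_format=_FLOAT_FORMAT)
    else:
        raise TypeError(f"cannot serialise object of type {type(obj).__name__}")


def write_isoform_parent_map(iso: IsoformTable, path, delimiter: str = "\t") -> None:
    iso.parent_gene.rename("gene_id").to_csv(path, sep=delimiter,
                                             index_label="isoform_id")
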