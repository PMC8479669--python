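"""Core in-memory containers shared across the pipeline stages.

Everything downstream operates on an :class:`ExpressionMatrix` (genes in
rows, samples in columns) and, once a network has been built, a
:class:`CoexpressionNetwork` holding the gene→module assignment, the module
eigengenes and the module-membership matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


def _find_duplicates(labels) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in labels:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


class ExpressionMatrix:
    """Genes × samples numeric expression matrix with unique identifiers.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample. Values must
        be numeric and free of missing entries; gene and sample identifiers
        must be unique; at least 2 genes and 2 samples are required.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("ExpressionMatrix expects a pandas DataFrame")
        dup_g = _find_duplicates(data.index)
        if dup_g:
            raise ValueError(f"duplicate gene identifiers: {dup_g}")
        dup_s = _find_duplicates(data.columns)
        if dup_s:
            raise ValueError(f"duplicate sample identifiers: {dup_s}")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                f"need at least 2 genes and 2 samples, got {data.shape}"
            )
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression value: {exc}") from exc
        if np.isnan(values).any():
            ii, jj = np.where(np.isnan(values))
            loc = (data.index[ii[0]], data.columns[jj[0]])
            raise ValueError(f"missing value at gene {loc[0]!r}, sample {loc[1]!r}")
        self.data = pd.DataFrame(values, index=data.index.astype(str),
                                 columns=data.columns.astype(str))
        self.data.index.name = "gene_id"
        self.data.columns.name = None

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
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes × {self.n_samples} samples)"


@dataclass
class CovariateTable:
    """Per-sample covariates (age, sex, RIN, PMI, ...) to regress out.

    ``data`` is indexed by sample id; columns may be numeric or categorical.
    """

    data: pd.DataFrame

    def validate_against(self, expr: ExpressionMatrix) -> None:
        cov_samples = set(self.data.index.astype(str))
        expr_samples = set(expr.sample_ids)
        if cov_samples != expr_samples:
            diff = cov_samples.symmetric_difference(expr_samples)
            raise ValueError(
                f"covariate samples do not match expression samples; "
                f"{len(diff)} differing ids, e.g. {sorted(diff)[:5]}"
            )
        for col in self.data.columns:
            s = self.data[col]
            if not pd.api.types.is_numeric_dtype(s) and s.nunique() < 2:
                raise ValueError(
                    f"categorical covariate {col!r} has fewer than 2 levels"
                )


@dataclass
class TOMMatrix:
    """Topological overlap: symmetric, unit diagonal, entries in [0, 1]."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.gene_ids):
            raise ValueError("TOM shape does not match gene list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("TOM not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("TOM diagonal must be 1")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("TOM entries must lie in [0, 1]")


@dataclass
class CoexpressionNetwork:
    """A built co-expression network (primary or secondary).

    Attributes
    ----------
    soft_power
        Soft-threshold exponent used for the adjacency.
    assignment
        Series gene id → module label; ``"unassigned"`` is reserved for
        genes in no module.
    eigengenes
        DataFrame samples × modules: each column is a module eigengene
        (unit-variance first principal component, sign-anchored so that its
        mean correlation with member genes is non-negative).
    membership
        DataFrame genes × modules of Pearson correlations in [−1, 1].
    provenance
        ``"primary"`` or ``"secondary:<cell type>"``.
    """

    soft_power: int
    assignment: pd.Series
    eigengenes: pd.DataFrame
    membership: pd.DataFrame
    provenance: str = "primary"
    params: dict = field(default_factory=dict)

    def modules(self) -> dict[str, list[str]]:
        """Module label → member gene ids, excluding ``unassigned``."""
        out: dict[str, list[str]] = {}
        for gene, label in self.assignment.items():
            if label == UNASSIGNED:
                continue
            out.setdefault(label, []).append(gene)
        return out

    @property
    def gene_ids(self) -> list[str]:
        return list(self.assignment.index)

    def module_of(self, gene: str) -> str:
        return self.assignment[gene]


@dataclass
class MarkerSet:
    """A named cell-type marker gene set (one GMT record)."""

    cell_type: str
    genes: set
    source: str = ""

    def __post_init__(self):
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"marker set {self.cell_type!r} is empty")


@dataclass
class SignalRemovalReport:
    """Bookkeeping for one module's principal-component signal removal."""

    module: str
    cell_type: str
    n_components_90: int
    variance_removed: float
    genes: int

    def __post_init__(self):
        if not (0 < self.variance_removed <= 1):
            raise ValueError("variance_removed must be in (0, 1]")
        if self.n_components_90 < 1:
            raise ValueError("n_components_90 must be ≥ 1")


@dataclass
class PreservationResult:
    """Permutation Z statistics for module preservation in a test dataset."""

    module: str
    z_summary: float
    z_density: float
    z_connectivity: float
    n_permutations: int


ModuleCellTypes = Mapping[str, str]
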