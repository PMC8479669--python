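"""Load expression/covariate tables and residualize covariates out.

Networks are built from OLS residuals: for every gene independently, its
expression row is regressed on an intercept plus all covariates (age, sex,
RIN, PMI, ...) and the residual row replaces the original. Categorical
covariates are expanded to treatment-coded indicators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CovariateTable, ExpressionMatrix
from .io import read_table

logger = logging.getLogger(__name__)


def read_expression(path: str, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    ``orientation`` says whether rows of the file are genes or samples; the
    returned matrix is always genes × samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = read_table(path)
    if orientation == "samples_in_rows":
        df = df.T
    return ExpressionMatrix(df)


def read_covariates(path: str) -> CovariateTable:
    return CovariateTable(read_table(path))


def _design_matrix(cov: CovariateTable) -> pd.DataFrame:
    """Intercept + numeric columns + treatment-coded categorical indicators."""
    pieces = [pd.Series(1.0, index=cov.data.index, name="intercept")]
    for col in cov.data.columns:
        s = cov.data[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            pieces.append(dummies.astype(float))
    return pd.concat(pieces, axis=1)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that are (numerically) linear combinations of the preceding ones."""
    bad = []
    for j in range(1, X.shape[1]):
        sub = X[:, :j]
        coef, _, _, _ = np.linalg.lstsq(sub, X[:, j], rcond=None)
        if np.linalg.norm(X[:, j] - sub @ coef) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j])
    return bad


def residualize(expr: ExpressionMatrix, cov: CovariateTable) -> ExpressionMatrix:
    """Replace every gene row by its OLS residual on the covariate design.

    The residual rows have zero mean and zero sample correlation with every
    covariate column; applying the operation twice is a no-op.
    """
    cov.validate_against(expr)
    X_df = _design_matrix(cov).loc[expr.sample_ids]
    X = X_df.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p - 1:
        raise ValueError(
            f"need more samples ({n}) than expanded covariate columns ({p - 1})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _collinear_columns(X, list(X_df.columns))
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Y = expr.values.T  # samples × genes
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid.T, index=expr.gene_ids, columns=expr.sample_ids)
    return ExpressionMatrix(out)


def drop_zero_variance(expr: ExpressionMatrix, tol: float = 1e-12) -> ExpressionMatrix:
    """Drop constant gene rows (they carry no co-expression signal)."""
    sd = expr.values.std(axis=1)
    keep = sd > tol
    n_drop = int((~keep).sum())
    if n_drop:
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance genes (e.g. %s)",
                       n_drop, dropped[:5])
        if keep.sum() < 2:
            raise ValueError("fewer than 2 genes left after zero-variance filter")
        return ExpressionMatrix(expr.data.loc[keep])
    return expr
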