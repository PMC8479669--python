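"""Secondary networks: principal-component removal of a cell type's signal.

Gene expression is modeled additively, e = Σ_c α_c·x_c + β·x_0: each
sample's value for a gene is a weighted sum of latent per-cell-type
contributions plus a shared residual factor. Within a module enriched for
one cell type, that type's contribution dominates the first principal
component; removing PC1 (and the >90%-variance tail) from the module
submatrix and rebuilding the network on the corrected full matrix exposes
the co-expression structure the dominant signal was masking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gcn
from .containers import (CoexpressionNetwork, ExpressionMatrix,
                         SignalRemovalReport)

logger = logging.getLogger(__name__)


@dataclass
class SecondaryResult:
    """One cell type's secondary network plus its removal bookkeeping."""

    cell_type: str
    network: CoexpressionNetwork
    reports: list[SignalRemovalReport]


def remove_cell_signal(submatrix: ExpressionMatrix,
                       variance_target: float = 0.90,
                       module: str = "", cell_type: str = ""
                       ) -> tuple[ExpressionMatrix, SignalRemovalReport]:
    """Strip PC1 from a module's expression and rebuild it in original units.

    Rows are gene-centered, the principal components of the centered
    submatrix are taken, k is the smallest count of components reaching
    ``variance_target`` cumulative explained variance, and the matrix is
    reconstructed from components 2..k only, with gene means added back.
    A rank-1 module (k = 1) degenerates to constant per-gene means and is
    flagged with a warning: its genes become inert in the secondary network.
    """
    if submatrix.n_genes < 2:
        raise ValueError("signal removal needs ≥ 2 genes")
    if submatrix.n_samples < 3:
        raise ValueError("signal removal needs ≥ 3 samples")
    X = submatrix.values
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("module has zero variance; nothing to remove")
    share = var / total
    k = int(np.searchsorted(np.cumsum(share), variance_target - 1e-12) + 1)
    k = min(k, len(s))
    if k == 1:
        warnings.warn(
            f"module {module or '<anon>'}: PC1 alone reaches "
            f"{variance_target:.0%} variance; corrected rows are constant"
        )
        recon = np.zeros_like(Xc)
    else:
        recon = U[:, 1:k] @ np.diag(s[1:k]) @ Vt[1:k]
    corrected = pd.DataFrame(recon + means, index=submatrix.gene_ids,
                             columns=submatrix.sample_ids)
    report = SignalRemovalReport(
        module=module, cell_type=cell_type, n_components_90=k,
        variance_removed=float(share[0]), genes=submatrix.n_genes,
    )
    return ExpressionMatrix(corrected), report


def build_secondary_matrix(expr: ExpressionMatrix,
                           network: CoexpressionNetwork,
                           module_celltypes: dict[str, str], cell_type: str,
                           variance_target: float = 0.90
                           ) -> tuple[ExpressionMatrix, list[SignalRemovalReport]]:
    """Full-gene-pool copy of ``expr`` with the cell type's modules corrected.

    Every module mapped to ``cell_type`` is replaced by its
    :func:`remove_cell_signal` output; all other genes are untouched.
    """
    targets = [m for m, ct in module_celltypes.items() if ct == cell_type]
    if not targets:
        raise ValueError(
            f"cell type {cell_type!r} has no enriched module; available: "
            f"{sorted(set(module_celltypes.values()))}"
        )
    out = expr.data.copy()
    modules = network.modules()
    reports = []
    for label in sorted(targets):
        members = modules.get(label, [])
        sub = expr.subset(members)
        corrected, report = remove_cell_signal(
            sub, variance_target=variance_target, module=label, cell_type=cell_type
        )
        out.loc[members] = corrected.data.values
        reports.append(report)
        logger.info("removed %s signal from module %s (%d genes, PC1 share %.2f, k=%d)",
                    cell_type, label, report.genes, report.variance_removed,
                    report.n_components_90)
    return ExpressionMatrix(out), reports


def build_all_secondary(expr: ExpressionMatrix, network: CoexpressionNetwork,
                        module_celltypes: dict[str, str],
                        params: "gcn.GCNParams | None" = None,
                        variance_target: float = 0.90
                        ) -> dict[str, SecondaryResult]:
    """One secondary network per enriched cell type.

    The soft power is re-selected per secondary matrix (the corrected
    matrices differ materially from the primary one).
    """
    cell_types = sorted(set(module_celltypes.values()))
    if not cell_types:
        warnings.warn("no enriched cell type; no secondary network to build")
        return {}
    out: dict[str, SecondaryResult] = {}
    for ct in cell_types:
        corrected, reports = build_secondary_matrix(
            expr, network, module_celltypes, ct, variance_target=variance_target
        )
        net = gcn.build_network(corrected, params=params,
                                provenance=f"secondary:{ct}")
        out[ct] = SecondaryResult(cell_type=ct, network=net, reports=reports)
    return out
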