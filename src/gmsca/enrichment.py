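"""Module annotation: cell-type marker enrichment and generic gene-set tests.

Every (module, cell type) pair gets a one-sided Fisher's exact test of the
module/marker overlap against the network gene pool, Bonferroni correction
over the whole table, and a module-size adjustment: −log10 of the corrected
p-value is regressed on module size and the residual must be positive for a
call (large modules otherwise accumulate spuriously small p-values). A
module may keep at most one cell type — when several pass, only the most
significant survives and the marginal signal is dropped.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom

from .containers import UNASSIGNED, CoexpressionNetwork, MarkerSet

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # guard for log10 on underflowed p-values


def hypergeom_tail(overlap, module_size, marker_size, background_size):
    """P(X ≥ overlap) for X ~ Hypergeom(N=background, K=markers, n=module).

    Vectorized over array inputs; this is the p-value kernel every Fisher
    test in the package delegates to.
    """
    overlap = np.asarray(overlap)
    return hypergeom.sf(overlap - 1, background_size, marker_size, module_size)


def marker_fisher(module_genes, markers, background) -> tuple[int, float]:
    """One-sided (enrichment) Fisher's exact test of a module/marker overlap.

    Marker genes are intersected with the background before testing; the
    module is expected to be a subset of the background (extraneous genes
    are dropped). Returns ``(overlap, p_raw)``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    marker_genes = (markers.genes if isinstance(markers, MarkerSet) else set(markers))
    marker_genes = set(marker_genes) & background
    module_genes = set(module_genes) & background
    overlap = len(module_genes & marker_genes)
    p = float(hypergeom_tail(overlap, len(module_genes), len(marker_genes),
                             len(background)))
    return overlap, min(1.0, p)


def enrichment_table(modules: dict[str, set], marker_sets: list[MarkerSet],
                     background, alpha: float = 0.05,
                     size_adjusted: bool = True) -> pd.DataFrame:
    """Raw Fisher tests + Bonferroni + size adjustment for every pair.

    ``modules`` maps module label → gene set (the ``unassigned`` pool, if
    present, contributes to the background but is never tested).
    """
    background = set(background)
    rows = []
    for ms in marker_sets:
        if not (ms.genes & background):
            warnings.warn(f"marker set {ms.cell_type!r} has no genes in background; skipped")
            continue
        for label, genes in sorted(modules.items()):
            if label == UNASSIGNED:
                continue
            overlap, p = marker_fisher(genes, ms, background)
            rows.append((label, ms.cell_type, len(set(genes) & background), overlap, p))
    table = pd.DataFrame(
        rows, columns=["module", "cell_type", "module_size", "overlap", "p_raw"]
    )
    if table.empty:
        table["p_bonferroni"] = pd.Series(dtype=float)
        table["neglog10_adjusted"] = pd.Series(dtype=float)
        table["enriched"] = pd.Series(dtype=bool)
        return table
    n_tests = len(table)
    table["p_bonferroni"] = np.minimum(1.0, table["p_raw"] * n_tests)
    table = size_adjust(table, alpha=alpha) if size_adjusted else _no_adjust(table, alpha)
    return table


def _no_adjust(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    table = table.copy()
    table["neglog10_adjusted"] = -np.log10(np.maximum(table["p_bonferroni"], _P_FLOOR))
    table["enriched"] = table["p_bonferroni"] < alpha
    return table


def size_adjust(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Regress −log10(p_bonferroni) on module size; keep positive residuals.

    A test is ``enriched`` when its Bonferroni p-value beats ``alpha`` AND
    its −log10 p lies above the size trend (residual > 0). With fewer than
    3 tests the adjustment is skipped (residual = −log10 p). When every
    module has the same size the slope is dropped and residuals are the
    centered −log10 values.
    """
    table = table.copy()
    y = -np.log10(np.maximum(table["p_bonferroni"].to_numpy(float), _P_FLOOR))
    sizes = table["module_size"].to_numpy(float)
    if len(table) < 3:
        warnings.warn("fewer than 3 tests; module-size adjustment skipped")
        resid = y
    elif np.ptp(sizes) == 0:
        resid = y - y.mean()
    else:
        X = sm.add_constant(sizes)
        resid = sm.OLS(y, X).fit().resid
    table["neglog10_adjusted"] = resid
    # residual must be positive beyond float noise of the OLS solve
    table["enriched"] = (table["p_bonferroni"] < alpha) & \
        (table["neglog10_adjusted"] > 1e-9)
    return table


def _single_cell_type_rule(table: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one enriched cell type per module (drop marginal signals)."""
    table = table.copy()
    for module, grp in table[table["enriched"]].groupby("module"):
        if len(grp) <= 1:
            continue
        ranked = grp.sort_values(
            ["p_bonferroni", "neglog10_adjusted", "cell_type"],
            ascending=[True, False, True],
        )
        winner = ranked.index[0]
        losers = [i for i in grp.index if i != winner]
        table.loc[losers, "enriched"] = False
        logger.info(
            "module %s enriched for %d cell types; keeping %s, dropping marginal %s",
            module, len(grp), table.loc[winner, "cell_type"],
            list(table.loc[losers, "cell_type"]),
        )
    return table


def assign_cell_types(network: CoexpressionNetwork,
                      marker_sets: list[MarkerSet], alpha: float = 0.05,
                      size_adjusted: bool = True
                      ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Full module → cell-type annotation of a network.

    Background is the complete network gene pool (unassigned genes
    included). Returns the enrichment table and the module → cell type
    mapping induced by its ``enriched`` column (at most one type per
    module by construction).
    """
    background = set(network.gene_ids)
    modules = {lab: set(genes) for lab, genes in network.modules().items()}
    table = enrichment_table(modules, marker_sets, background, alpha=alpha,
                             size_adjusted=size_adjusted)
    if not table.empty:
        table = _single_cell_type_rule(table)
    mapping = {
        row["module"]: row["cell_type"]
        for _, row in table[table["enriched"]].iterrows()
    } if not table.empty else {}
    return table, mapping


def function_enrichment(modules: dict[str, set], function_sets: list[MarkerSet],
                        background, alpha: float = 0.05) -> dict[str, list[str]]:
    """Generic GMT over-representation per module (gProfiler stand-in).

    Bonferroni-corrected one-sided Fisher tests; returns module → sorted
    list of significant term names (no size adjustment and no single-term
    rule: a module may carry many functions).
    """
    table = enrichment_table(modules, function_sets, background, alpha=alpha,
                             size_adjusted=False)
    out: dict[str, list[str]] = {lab: [] for lab in modules if lab != UNASSIGNED}
    if table.empty:
        return out
    for _, row in table[table["enriched"]].iterrows():
        out.setdefault(row["module"], []).append(row["cell_type"])
    return {k: sorted(v) for k, v in out.items()}
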