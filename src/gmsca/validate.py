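"""Validation statistics: module preservation, specificity matrices,
overlap tests with marker exclusion, bootstrap expression enrichment and
phenotype-term coverage/fold-change enrichment.

The preservation statistic is a deliberately small two-component version
of the WGCNA Z-summary: a density Z (mean absolute intramodular
correlation in the test data) and a connectivity Z (rank agreement of
intramodular connectivity between reference and test), each standardized
against same-size random gene sets. The published thresholds keep their
meaning: Z ≥ 10 strong preservation, Z ≥ 2 weak, below 2 not preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import ExpressionMatrix, PreservationResult
from .enrichment import hypergeom_tail

logger = logging.getLogger(__name__)


def _abs_cor(values: np.ndarray) -> np.ndarray:
    c = np.corrcoef(values)
    return np.abs(np.clip(c, -1.0, 1.0))


def _density_and_connectivity(ref: np.ndarray, test: np.ndarray
                              ) -> tuple[float, float]:
    """Density in test; Spearman agreement of intramodular connectivity."""
    a_ref = _abs_cor(ref)
    a_test = _abs_cor(test)
    n = a_test.shape[0]
    off = ~np.eye(n, dtype=bool)
    density = float(a_test[off].mean())
    k_ref = a_ref.sum(axis=1) - 1.0
    k_test = a_test.sum(axis=1) - 1.0
    rho = spearmanr(k_ref, k_test).statistic
    return density, float(0.0 if np.isnan(rho) else rho)


def preservation_z(ref_expr: ExpressionMatrix, ref_module,
                   test_expr: ExpressionMatrix, n_perm: int = 200,
                   seed: int = 0, module: str = "") -> PreservationResult:
    """Permutation Z statistics for one module's preservation in test data.

    The observed density and connectivity statistics are standardized
    against ``n_perm`` random gene sets of the module's size drawn from the
    genes shared by both matrices.
    """
    ref_module = list(ref_module)
    if len(ref_module) < 3:
        raise ValueError("preservation needs a module of ≥ 3 genes")
    if n_perm < 100:
        raise ValueError("n_perm must be ≥ 100")
    # sorted so the permutation null is invariant to input gene order
    shared = sorted(set(ref_expr.gene_ids) & set(test_expr.gene_ids))
    missing = [g for g in ref_module if g not in set(shared)]
    if missing:
        raise KeyError(f"module genes absent from one matrix: {missing[:10]}")
    ref_vals = ref_expr.data
    test_vals = test_expr.data
    obs_d, obs_c = _density_and_connectivity(
        ref_vals.loc[ref_module].to_numpy(), test_vals.loc[ref_module].to_numpy()
    )
    rng = np.random.default_rng(seed)
    shared_arr = np.asarray(shared)
    null_d = np.empty(n_perm)
    null_c = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(shared_arr, size=len(ref_module), replace=False)
        null_d[i], null_c[i] = _density_and_connectivity(
            ref_vals.loc[pick].to_numpy(), test_vals.loc[pick].to_numpy()
        )
    sd_d = max(float(null_d.std(ddof=1)), 1e-12)
    sd_c = max(float(null_c.std(ddof=1)), 1e-12)
    z_d = (obs_d - float(null_d.mean())) / sd_d
    z_c = (obs_c - float(null_c.mean())) / sd_c
    return PreservationResult(
        module=module, z_summary=(z_d + z_c) / 2.0, z_density=z_d,
        z_connectivity=z_c, n_permutations=n_perm,
    )


def immunopanning_boolean(profiles: pd.DataFrame,
                          column_celltypes: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Boolean specificity from purified-cell-type expression profiles.

    Replicate columns are averaged per cell type, the matrix is
    log2(x+1)-transformed and centered/scaled as a whole, and an entry is
    TRUE when its transformed value exceeds the whole-matrix mean.
    """
    if (profiles.to_numpy(float) < 0).any():
        raise ValueError("expression profiles must be non-negative")
    if column_celltypes:
        grouped = profiles.T.groupby(
            [column_celltypes.get(c, c) for c in profiles.columns]
        ).mean().T
    else:
        grouped = profiles.astype(float)
    logged = np.log2(grouped + 1.0)
    flat = logged.to_numpy()
    sd = flat.std()
    if sd <= 0:
        return pd.DataFrame(False, index=grouped.index, columns=grouped.columns)
    z = (logged - flat.mean()) / sd
    return z > 0


def singlecell_boolean(counts: pd.DataFrame, cell_labels: dict[str, str],
                       fc_threshold: float = 3.0) -> pd.DataFrame:
    """Boolean specificity from a single-cell count matrix (genes × cells).

    All-zero cells are dropped first. An entry is TRUE when the gene's mean
    in the cell type is ≥ ``fc_threshold`` × its overall mean across
    retained cells (genes with zero overall mean are FALSE everywhere).
    """
    keep = counts.columns[(counts != 0).any(axis=0)]
    n_dropped = counts.shape[1] - len(keep)
    if n_dropped:
        logger.info("dropped %d all-zero cells", n_dropped)
    counts = counts[keep]
    labels = pd.Series({c: cell_labels[c] for c in counts.columns})
    overall = counts.mean(axis=1)
    out = {}
    for ct, cols in labels.groupby(labels).groups.items():
        if len(cols) == 0:
            warnings.warn(f"cell type {ct!r} has no cells after filtering; dropped")
            continue
        type_mean = counts[list(cols)].mean(axis=1)
        out[ct] = (type_mean >= fc_threshold * overall) & (overall > 0)
    return pd.DataFrame(out)


def specificity_fractions(mean_by_type: pd.DataFrame) -> pd.DataFrame:
    """Real-valued specificity: each gene's per-type mean over its row sum.

    Rows with zero total are dropped; remaining rows sum to 1. This is the
    input expected by :func:`bootstrap_enrichment`.
    """
    totals = mean_by_type.sum(axis=1)
    kept = mean_by_type.loc[totals > 0]
    return kept.div(kept.sum(axis=1), axis=0)


@dataclass
class OverlapResult:
    overlap: int
    p_value: float
    n_pred: int
    n_reference: int
    n_background: int


def overlap_test(pred_genes, reference_positive, background,
                 exclude=()) -> OverlapResult:
    """Fisher test of predictions vs a reference set, markers excluded.

    Known marker genes are removed from all three sets before testing so
    that the overlap is not optimistically inflated by the genes the
    predictions were seeded with.
    """
    exclude = set(exclude)
    background = set(background) - exclude
    pred = (set(pred_genes) - exclude) & background
    ref = (set(reference_positive) - exclude) & background
    if not pred:
        warnings.warn("no predicted genes left after marker exclusion; p = 1")
        return OverlapResult(0, 1.0, 0, len(ref), len(background))
    overlap = len(pred & ref)
    p = float(hypergeom_tail(overlap, len(pred), len(ref), len(background)))
    return OverlapResult(overlap, min(1.0, p), len(pred), len(ref), len(background))


def bootstrap_enrichment(target, specificity: pd.DataFrame, cell_type: str,
                         n_boot: int = 10_000, seed: int = 0) -> float:
    """EWCE-style bootstrap: is the target's mean specificity high?

    The statistic is the mean of the ``cell_type`` specificity column over
    the target genes; the null resamples equally sized gene lists
    (without replacement within a list) from the specificity matrix.
    p = (1 + #{null ≥ observed}) / (n_boot + 1).
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if cell_type not in specificity.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    target = list(dict.fromkeys(target))
    present = [g for g in target if g in specificity.index]
    n_dropped = len(target) - len(present)
    if n_dropped:
        logger.info("bootstrap target: %d genes absent from specificity matrix",
                    n_dropped)
    if not present:
        raise ValueError("no target gene present in the specificity matrix")
    col = specificity[cell_type].to_numpy(float)
    obs = float(specificity.loc[present, cell_type].mean())
    k, n_genes = len(present), len(col)
    rng = np.random.default_rng(seed)
    if n_boot * n_genes <= 20_000_000:
        idx = np.argpartition(rng.random((n_boot, n_genes)), k - 1, axis=1)[:, :k]
        null = col[idx].mean(axis=1)
    else:
        null = np.empty(n_boot)
        for i in range(n_boot):
            null[i] = col[rng.choice(n_genes, size=k, replace=False)].mean()
    return float((1 + int((null >= obs - 1e-15).sum())) / (n_boot + 1))


def hpo_enrichment(module_genes, term_annotations: dict[str, set], background,
                   min_coverage: float = 0.02) -> pd.DataFrame:
    """Phenotype-term coverage and fold change over a module.

    coverage = |module ∩ term| / |module|; terms below ``min_coverage``
    are dropped; fold_change = coverage / background rate of the term.
    Terms with no gene in the background are skipped.
    """
    module = set(module_genes)
    background = set(background)
    if not module or not background:
        raise ValueError("module and background must be non-empty")
    rows = []
    for term in sorted(term_annotations):
        genes = set(term_annotations[term])
        bg_hits = len(genes & background)
        if bg_hits == 0:
            continue
        coverage = len(module & genes) / len(module)
        if coverage < min_coverage:
            continue
        fold_change = coverage / (bg_hits / len(background))
        rows.append((term, coverage, fold_change))
    return pd.DataFrame(rows, columns=["term", "coverage", "fold_change"])
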