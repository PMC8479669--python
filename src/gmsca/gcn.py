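"""Weighted co-expression network construction.

The pipeline mirrors the WGCNA + k-means recipe: pick the smallest soft
power whose connectivity distribution is approximately scale-free, raise
the absolute Pearson correlation to that power to form the adjacency,
convert to topological overlap (TOM), cluster on distance 1−TOM with
average-linkage hierarchical clustering (minimum module size 100), then
refine the partition with a k-means-style pass in eigengene-correlation
space (up to 50 iterations). Module eigengenes are first principal
components of the standardized module submatrix; module membership is the
gene-by-eigengene Pearson correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .containers import UNASSIGNED, CoexpressionNetwork, ExpressionMatrix, TOMMatrix

logger = logging.getLogger(__name__)


@dataclass
class GCNParams:
    """Knobs of the network builder; defaults are the published constants."""

    min_module_size: int = 100
    max_kmeans_iter: int = 50
    power: int | str = "auto"          # "auto" → select_soft_power
    network_type: str = "unsigned"     # or "signed_hybrid"
    powers: tuple = tuple(range(1, 31))
    fit_threshold: float = 0.80
    n_bins: int = 10
    reassign_floor: float = 0.3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["powers"] = list(d["powers"])
        return d


def _correlation(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if (sd <= 1e-300).any():
        bad = int(np.argmax(sd <= 1e-300))
        raise ValueError(
            f"constant gene row at position {bad}; run preprocess.drop_zero_variance first"
        )
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(values)
    return np.clip(cor, -1.0, 1.0)


def _adjacency(cor: np.ndarray, power: int, network_type: str) -> np.ndarray:
    if network_type == "unsigned":
        a = np.abs(cor) ** power
    elif network_type == "signed_hybrid":
        a = np.clip(cor, 0.0, None) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log fit of binned connectivity frequency.

    Connectivities are binned into ``n_bins`` equal-width bins; log10 of the
    per-bin frequency is regressed on log10 of the per-bin mean
    connectivity. The R² is sign-corrected: negative slope (the scale-free
    direction) keeps a positive sign.
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2 or np.ptp(k) <= 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    vx = np.var(x)
    if vx <= 0:
        return 0.0
    slope = np.cov(x, y, bias=True)[0, 1] / vx
    r = np.corrcoef(x, y)[0, 1]
    r2 = 0.0 if np.isnan(r) else r * r
    return float(-np.sign(slope) * r2) if slope != 0 else 0.0


def select_soft_power(expr: ExpressionMatrix, powers=tuple(range(1, 31)),
                      fit_threshold: float = 0.80, network_type: str = "unsigned",
                      n_bins: int = 10) -> int:
    """Smallest power on the grid whose scale-free fit R² reaches the threshold.

    Falls back (with a warning) to the power maximizing the fit if none
    qualifies. Fewer than 10 genes is an error: the connectivity histogram
    is meaningless.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("empty power grid")
    if expr.n_genes < 10:
        raise ValueError(
            f"need ≥ 10 genes to assess scale-free topology, got {expr.n_genes}"
        )
    cor = _correlation(expr.values)
    fits = []
    for p in powers:
        a = _adjacency(cor, p, network_type)
        k = a.sum(axis=1) - 1.0  # exclude self-adjacency
        fits.append(scale_free_fit(k, n_bins=n_bins))
    for p, f in zip(powers, fits):
        if f >= fit_threshold:
            return int(p)
    best = int(powers[int(np.argmax(fits))])
    warnings.warn(
        f"no power reaches scale-free fit R² ≥ {fit_threshold}; "
        f"using power {best} (R² = {max(fits):.3f})"
    )
    return best


def tom_matrix(expr: ExpressionMatrix, power: int,
               network_type: str = "unsigned") -> TOMMatrix:
    """Adjacency |cor|^power (unit diagonal) → standard unsigned TOM.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` with
    ``l_ij = Σ_{u≠i,j} a_iu a_uj`` and ``k_i = Σ_{u≠i} a_iu``; diagonal 1.
    """
    if power < 1:
        raise ValueError("power must be ≥ 1")
    a = _adjacency(_correlation(expr.values), power, network_type)
    k = a.sum(axis=1) - 1.0
    # (A @ A)_ij includes the u=i and u=j terms a_ij·(a_ii + a_jj) = 2·a_ij
    numer = a @ a - a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = numer / denom
    tom[denom <= 0] = 1.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(gene_ids=expr.gene_ids, values=tom)


def initial_modules(tom: TOMMatrix, min_module_size: int = 100) -> pd.Series:
    """Average-linkage clustering on 1−TOM, cut to maximize large clusters.

    The dendrogram is cut at the height producing the largest number of
    clusters of size ≥ ``min_module_size`` (ties go to the lower height);
    smaller clusters are relabeled ``unassigned``. Surviving modules are
    named M1, M2, ... in decreasing size order.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be ≥ 2")
    genes = tom.gene_ids
    n = len(genes)
    if min_module_size > n:
        warnings.warn(
            f"min_module_size {min_module_size} exceeds gene count {n}; "
            "all genes unassigned"
        )
        return pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene_id"))
    dist = 1.0 - tom.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    cuts = cut_tree(Z)  # n × n; column j is the partition after j merges
    heights = Z[:, 2]
    # a column is a true height cut only after ALL merges at that height
    candidates = [0] + [j + 1 for j in range(n - 1)
                        if j == n - 2 or heights[j] < heights[j + 1]]
    best_col, best_count = 0, -1
    for j in candidates:
        sizes = np.bincount(cuts[:, j])
        count = int((sizes >= min_module_size).sum())
        if count > best_count:  # strict: ties keep the earlier (lower) height
            best_count, best_col = count, j
    labels = cuts[:, best_col]
    sizes = np.bincount(labels)
    big = [c for c in np.argsort(sizes)[::-1] if sizes[c] >= min_module_size]
    name_of = {c: f"M{i + 1}" for i, c in enumerate(big)}
    assignment = pd.Series(
        [name_of.get(c, UNASSIGNED) for c in labels],
        index=pd.Index(genes, name="gene_id"),
    )
    if best_count == 0:
        warnings.warn("no cluster reaches min_module_size; all genes unassigned")
    return assignment


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if (sd <= 1e-300).any():
        raise ValueError("constant gene row; run preprocess.drop_zero_variance first")
    return (values - mean) / sd


def module_eigengene(expr: ExpressionMatrix, member_genes) -> pd.Series:
    """First principal component of the row-standardized module submatrix.

    Returned as unit-variance sample scores; the sign is anchored so the
    mean correlation with member gene rows is non-negative.
    """
    member_genes = list(member_genes)
    missing = [g for g in member_genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
    if len(member_genes) < 2:
        raise ValueError("module eigengene needs ≥ 2 member genes")
    X = _standardize_rows(expr.data.loc[member_genes].to_numpy())
    # rows already centered → right singular vectors are PC score directions
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    scores = vt[0]
    sd = scores.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate module: zero-variance principal component")
    scores = scores / sd
    mean_cor = (X @ scores).mean()
    if mean_cor < 0:
        scores = -scores
    return pd.Series(scores, index=expr.sample_ids, name="eigengene")


def _eigengene_frame(expr: ExpressionMatrix, assignment: pd.Series) -> pd.DataFrame:
    cols = {}
    for label, members in sorted(_members(assignment).items()):
        if len(members) >= 2:
            cols[label] = module_eigengene(expr, members)
    return pd.DataFrame(cols, index=expr.sample_ids)


def _members(assignment: pd.Series) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for g, lab in assignment.items():
        if lab != UNASSIGNED:
            out.setdefault(lab, []).append(g)
    return out


def _gene_eigengene_correlation(expr: ExpressionMatrix,
                                eigengenes: pd.DataFrame) -> np.ndarray:
    G = _standardize_rows(expr.values)
    E = eigengenes.to_numpy()
    E = (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)
    n = expr.n_samples
    return np.clip(G @ E / (n - 1), -1.0, 1.0)


def kmeans_refine(expr: ExpressionMatrix, assignment: pd.Series,
                  max_iter: int = 50, reassign_floor: float = 0.3,
                  min_module_size: int = 100,
                  return_history: bool = False):
    """k-means-style refinement with module eigengenes as centroids.

    Each iteration recomputes the module eigengenes and moves every gene
    (including unassigned ones) to the module whose eigengene it correlates
    with most strongly in absolute value, provided |r| ≥ ``reassign_floor``.
    Stops early when no gene moves; modules below ``min_module_size`` are
    dissolved to unassigned at the end.
    """
    assignment = assignment.copy()
    if not _members(assignment):
        raise ValueError("assignment has no non-unassigned module")
    history: list[int] = []
    if max_iter > 0:
        for _ in range(max_iter):
            eig = _eigengene_frame(expr, assignment)
            if eig.shape[1] == 0:
                break
            C = _gene_eigengene_correlation(expr, eig)
            best_idx = np.abs(C).argmax(axis=1)
            best_val = np.abs(C)[np.arange(C.shape[0]), best_idx]
            labels = np.asarray(eig.columns)
            new = np.where(best_val >= reassign_floor, labels[best_idx], UNASSIGNED)
            new = pd.Series(new, index=assignment.index)
            history.append(int((new != assignment).sum()))
            if history[-1] == 0:
                break
            assignment = new
        for label, members in _members(assignment).items():
            if len(members) < min_module_size:
                assignment[assignment == label] = UNASSIGNED
    if return_history:
        return assignment, history
    return assignment


def module_membership(expr: ExpressionMatrix,
                      eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene row with every module eigengene."""
    if eigengenes.shape[1] == 0:
        return pd.DataFrame(index=expr.gene_ids)
    C = _gene_eigengene_correlation(expr, eigengenes)
    return pd.DataFrame(C, index=expr.gene_ids, columns=eigengenes.columns)


def build_network(expr: ExpressionMatrix, params: GCNParams | None = None,
                  provenance: str = "primary") -> CoexpressionNetwork:
    """Full pipeline: power → adjacency/TOM → clustering → refinement → MM.

    Deterministic given the input matrix and parameters (no stochastic
    step: clustering and refinement are both deterministic).
    """
    params = params or GCNParams()
    if params.power == "auto":
        power = select_soft_power(
            expr, powers=params.powers, fit_threshold=params.fit_threshold,
            network_type=params.network_type, n_bins=params.n_bins,
        )
    else:
        power = int(params.power)
    tom = tom_matrix(expr, power, network_type=params.network_type)
    assignment = initial_modules(tom, min_module_size=params.min_module_size)
    if _members(assignment):
        assignment = kmeans_refine(
            expr, assignment, max_iter=params.max_kmeans_iter,
            reassign_floor=params.reassign_floor,
            min_module_size=params.min_module_size,
        )
    eigengenes = _eigengene_frame(expr, assignment)
    membership = module_membership(expr, eigengenes)
    logger.info("built %s network: power %d, %d modules, %d/%d genes assigned",
                provenance, power, eigengenes.shape[1],
                int((assignment != UNASSIGNED).sum()), expr.n_genes)
    return CoexpressionNetwork(
        soft_power=power, assignment=assignment, eigengenes=eigengenes,
        membership=membership, provenance=provenance, params=params.to_dict(),
    )
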