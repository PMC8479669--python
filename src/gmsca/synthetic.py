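"""Synthetic bulk-expression generator with planted cell-type structure.

The generator follows the additive latent-factor model the secondary-
network step assumes, e = Σ_c α_c·x_c + β·x_0 + ε: every sample carries
one independent standard-normal latent signal per cell type (x_c) plus a
shared residual factor (x_0); a gene in cell type c's module loads on x_c
(α_g ~ |N(loading_primary, 0.1)|), every gene loads on x_0
(β_g ~ |N(loading_background, 0.1)|), a multifunctional gene additionally
loads on a second type's factor (α'_g ~ |N(loading_secondary, 0.1)|), and
i.i.d. Gaussian noise is added. Ground truth (modules, markers,
multifunctional pairs, latent factors and loadings) travels with the
dataset so every pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import UNASSIGNED, CoexpressionNetwork, ExpressionMatrix, MarkerSet

BACKGROUND = "background"


@dataclass
class CellTypeSpec:
    name: str
    n_genes: int = 300
    n_markers: int = 60


def default_cell_types() -> list[CellTypeSpec]:
    return [CellTypeSpec(n) for n in
            ("neuron", "microglia", "astrocyte", "oligodendrocyte")]


@dataclass
class SyntheticConfig:
    """Stated world of the generator; defaults are the documented scenario.

    Four 300-gene cell-type modules (60 markers each), 40 multifunctional
    genes for each of the two disjoint adjacent type pairs, 800 background
    genes and 150 samples: a 2080 × 150 matrix.
    """

    seed: int                                   # mandatory
    n_samples: int = 150
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    n_background_genes: int = 800
    n_multifunctional: int = 40                 # per adjacent (disjoint) type pair
    loading_primary: float = 1.0
    loading_secondary: float = 0.6
    loading_background: float = 0.5
    noise_sd: float = 1.0

    def multifunctional_pairs(self) -> list[tuple[str, str]]:
        names = [ct.name for ct in self.cell_types]
        return [(names[i], names[i + 1]) for i in range(0, len(names) - 1, 2)]


@dataclass
class SyntheticDataset:
    expr: ExpressionMatrix
    truth_modules: pd.Series                    # gene → cell type or "background"
    truth_markers: dict[str, set]
    truth_multifunctional: dict[str, tuple[str, str]]
    latent_factors: pd.DataFrame                # samples × (cell types + shared)
    loadings: pd.DataFrame                      # genes × (cell types + shared)
    config: SyntheticConfig

    def marker_sets(self) -> list[MarkerSet]:
        return [MarkerSet(cell_type=ct, genes=set(genes), source="synthetic")
                for ct, genes in sorted(self.truth_markers.items())]


def simulate_bulk(config: SyntheticConfig,
                  loadings: pd.DataFrame | None = None) -> SyntheticDataset:
    """Draw a synthetic bulk matrix; deterministic given the seed.

    Passing ``loadings`` from a previous dataset redraws only the latent
    factors and the noise — an independent replicate of the same modules,
    as needed for preservation analysis.
    """
    if config.n_samples < 10:
        raise ValueError("need ≥ 10 samples for stable networks")
    rng = np.random.default_rng(config.seed)
    type_names = [ct.name for ct in config.cell_types]
    factor_names = type_names + ["shared"]

    gene_ids: list[str] = []
    truth: list[str] = []
    markers: dict[str, set] = {ct: set() for ct in type_names}
    multifunctional: dict[str, tuple[str, str]] = {}
    rows: list[tuple[str, str | None]] = []  # (primary factor, secondary factor)
    for ct in config.cell_types:
        for i in range(ct.n_genes):
            gid = f"{ct.name}_{i:04d}"
            gene_ids.append(gid)
            truth.append(ct.name)
            rows.append((ct.name, None))
            if i < ct.n_markers:
                markers[ct.name].add(gid)
    for a, b in config.multifunctional_pairs():
        for i in range(config.n_multifunctional):
            gid = f"mf_{a}_{b}_{i:03d}"
            gene_ids.append(gid)
            truth.append(a)  # belongs to its primary type's module
            rows.append((a, b))
            multifunctional[gid] = (a, b)
    for i in range(config.n_background_genes):
        gene_ids.append(f"bg_{i:04d}")
        truth.append(BACKGROUND)
        rows.append((None, None))

    n_genes = len(gene_ids)
    if loadings is None:
        L = np.zeros((n_genes, len(factor_names)))
        col = {name: j for j, name in enumerate(factor_names)}
        for g, (primary, secondary) in enumerate(rows):
            if primary is not None:
                L[g, col[primary]] = abs(rng.normal(config.loading_primary, 0.1))
            if secondary is not None:
                L[g, col[secondary]] = abs(rng.normal(config.loading_secondary, 0.1))
            L[g, col["shared"]] = abs(rng.normal(config.loading_background, 0.1))
        loadings = pd.DataFrame(L, index=gene_ids, columns=factor_names)
    else:
        if list(loadings.index) != gene_ids:
            raise ValueError("supplied loadings do not match this configuration's genes")

    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    F = rng.standard_normal((len(factor_names), config.n_samples))
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, config.n_samples))
    values = loadings.to_numpy() @ F + noise
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))
    return SyntheticDataset(
        expr=expr,
        truth_modules=pd.Series(truth, index=pd.Index(gene_ids, name="gene_id")),
        truth_markers=markers,
        truth_multifunctional=multifunctional,
        latent_factors=pd.DataFrame(F.T, index=samples, columns=factor_names),
        loadings=loadings,
        config=config,
    )


def evaluate_recovery(network: CoexpressionNetwork, truth: SyntheticDataset,
                      module_celltypes: dict[str, str] | None = None,
                      state_table: pd.DataFrame | None = None) -> dict:
    """Score a built network (and optionally a state table) against truth.

    Reports adjusted Rand indices (background included and excluded),
    per-type enrichment hits when a module → cell type mapping is given,
    and multifunctionality sensitivity / false-positive rate when a
    per-gene state table is given.
    """
    truth_series = truth.truth_modules
    pred = network.assignment.reindex(truth_series.index)
    if pred.isna().any():
        raise ValueError("network gene pool does not cover the synthetic genes")
    metrics: dict = {
        "ari_with_background": float(adjusted_rand_score(truth_series, pred)),
    }
    mask = truth_series != BACKGROUND
    metrics["ari_excluding_background"] = float(
        adjusted_rand_score(truth_series[mask], pred[mask])
    )
    if module_celltypes is not None:
        per_type = {
            ct: sorted(m for m, t in module_celltypes.items() if t == ct)
            for ct in truth.truth_markers
        }
        metrics["modules_per_type"] = {ct: len(ms) for ct, ms in per_type.items()}
        metrics["types_recovered_once"] = all(
            len(ms) == 1 for ms in per_type.values()
        )
    if state_table is not None:
        mf_truth = set(truth.truth_multifunctional)
        mf_pred = set(state_table.index[state_table["multifunctional_any"]])
        pure = set(truth_series.index[mask]) - mf_truth
        hits = 0
        for g in mf_truth & mf_pred:
            planted_secondary = truth.truth_multifunctional[g][1]
            assigned = set(str(state_table.at[g, "cell_types"]).split(";"))
            if planted_secondary in assigned:
                hits += 1
        metrics["multifunctional_sensitivity"] = (
            hits / len(mf_truth) if mf_truth else float("nan")
        )
        metrics["multifunctional_false_positive_rate"] = (
            len(mf_pred & pure) / len(pure) if pure else float("nan")
        )
    n_unassigned = int((pred == UNASSIGNED).sum())
    metrics["fraction_unassigned"] = n_unassigned / len(pred)
    return metrics
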