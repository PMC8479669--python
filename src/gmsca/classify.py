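"""Triplet extraction and gene-state classification across networks.

Every gene of a cell-type-enriched module yields one <gene, cell type,
functions> triplet. Comparing where a gene sits in the primary network
(PGCN) versus a secondary network (SGCN) defines its transition state:

================  ==================  =====================
primary module    secondary module    state
================  ==================  =====================
not enriched      enriched            activated
enriched          not enriched        deactivated
enriched (A)      enriched (B ≠ A)    multifunctional
enriched (A)      enriched (A)        strongly_typed
not enriched      not enriched        strongly_non_typed
================  ==================  =====================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import CoexpressionNetwork

ACTIVATED = "activated"
DEACTIVATED = "deactivated"
MULTIFUNCTIONAL = "multifunctional"
STRONGLY_TYPED = "strongly_typed"
STRONGLY_NON_TYPED = "strongly_non_typed"


@dataclass
class Triplet:
    gene: str
    cell_type: str
    functions: list[str] = field(default_factory=list)
    network: str = "primary"
    module: str = ""
    mm: float = float("nan")


def extract_triplets(network: CoexpressionNetwork,
                     module_celltypes: dict[str, str],
                     function_annotations: dict[str, list[str]] | None = None
                     ) -> list[Triplet]:
    """One triplet per gene per enriched module containing it.

    Genes in non-enriched modules (or unassigned) yield nothing. The
    gene's module membership in its own module travels with the triplet.
    """
    function_annotations = function_annotations or {}
    triplets: list[Triplet] = []
    modules = network.modules()
    for label in sorted(module_celltypes):
        cell_type = module_celltypes[label]
        funcs = list(function_annotations.get(label, []))
        for gene in modules.get(label, []):
            mm = float("nan")
            if label in network.membership.columns:
                mm = float(network.membership.at[gene, label])
            triplets.append(Triplet(gene=gene, cell_type=cell_type,
                                    functions=funcs, network=network.provenance,
                                    module=label, mm=mm))
    return triplets


def classify_transition(primary_type: str | None,
                        secondary_type: str | None) -> str:
    """Total function of (primary cell type, secondary cell type) → state."""
    if primary_type is None:
        return ACTIVATED if secondary_type is not None else STRONGLY_NON_TYPED
    if secondary_type is None:
        return DEACTIVATED
    return STRONGLY_TYPED if primary_type == secondary_type else MULTIFUNCTIONAL


def _gene_types(network: CoexpressionNetwork,
                module_celltypes: dict[str, str]) -> pd.Series:
    """Per-gene enriched cell type (None for non-enriched/unassigned genes)."""
    return network.assignment.map(lambda m: module_celltypes.get(m)).astype(object)


def aggregate_states(pgcn: CoexpressionNetwork,
                     pgcn_celltypes: dict[str, str],
                     sgcns: dict[str, tuple[CoexpressionNetwork, dict[str, str]]]
                     ) -> tuple[pd.DataFrame, dict]:
    """Per-gene transition states for every SGCN plus pooled summaries.

    Returns a table indexed by gene with ``primary_type``, one
    ``type_<ct>``/``state_<ct>`` column pair per secondary network, and the
    aggregates ``typed`` (in any enriched module anywhere),
    ``multifunctional_any`` and ``cell_types`` (union of assigned types).
    The summary dict reports primary-typing fractions per cell type (they
    sum to 1 with the non-typed fraction) and the typed-gene gain
    ``(typed_after − typed_pgcn) / pool``.
    """
    pool = set(pgcn.gene_ids)
    table = pd.DataFrame(index=pd.Index(sorted(pool), name="gene"))
    primary = _gene_types(pgcn, pgcn_celltypes).reindex(table.index)
    table["primary_type"] = primary
    typed = primary.notna()
    mf_any = pd.Series(False, index=table.index)
    cell_types = primary.map(lambda t: {t} if isinstance(t, str) else set())

    for ct in sorted(sgcns):
        net, mapping = sgcns[ct]
        if set(net.gene_ids) != pool:
            diff = set(net.gene_ids).symmetric_difference(pool)
            raise ValueError(
                f"secondary network {ct!r} gene pool differs from primary "
                f"by {len(diff)} genes"
            )
        sec = _gene_types(net, mapping).reindex(table.index)
        states = [
            classify_transition(p if isinstance(p, str) else None,
                                s if isinstance(s, str) else None)
            for p, s in zip(primary, sec)
        ]
        table[f"type_{ct}"] = sec
        table[f"state_{ct}"] = states
        typed |= sec.notna()
        mf_any |= pd.Series(states, index=table.index) == MULTIFUNCTIONAL
        cell_types = pd.Series(
            [cs | ({s} if isinstance(s, str) else set())
             for cs, s in zip(cell_types, sec)],
            index=table.index,
        )

    table["typed"] = typed
    table["multifunctional_any"] = mf_any
    table["cell_types"] = cell_types.map(lambda cs: ";".join(sorted(cs)))

    n = len(table)
    primary_counts = primary.value_counts()
    fractions = {str(ct): float(c) / n for ct, c in primary_counts.items()}
    fractions["non_typed"] = float(primary.isna().sum()) / n
    typed_pgcn = float(primary.notna().sum()) / n
    typed_after = float(typed.sum()) / n
    summary = {
        "n_genes": n,
        "primary_fractions": fractions,
        "typed_pgcn_fraction": typed_pgcn,
        "typed_after_fraction": typed_after,
        "gain": typed_after - typed_pgcn,
        "multifunctional_fraction": float(mf_any.sum()) / n,
        "n_secondary_networks": len(sgcns),
    }
    return table, summary
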