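"""End-to-end orchestration: expression → PGCN → enrichment → SGCNs → states.

A single YAML-serializable :class:`RunConfig` drives the whole run; every
artifact is written as plain text under the output directory and a JSON
manifest records parameters, seeds, per-file checksums and the summary
fractions, so that two runs with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import classify, enrichment, preprocess, secondary
from .containers import ExpressionMatrix
from .gcn import GCNParams, build_network
from .io import read_gmt, write_network

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and knobs of one run; defaults are the published constants
    (minimum module size 100, 50 k-means iterations, 90% variance target,
    alpha 0.05)."""

    expression: str = ""
    output_dir: str = "gmsca_out"
    covariates: str | None = None
    markers: str | None = None
    functions: str | None = None
    orientation: str = "genes_in_rows"
    min_module_size: int = 100
    max_kmeans_iter: int = 50
    power: int | str = "auto"
    network_type: str = "unsigned"
    reassign_floor: float = 0.3
    alpha: float = 0.05
    size_adjust: bool = True
    variance_target: float = 0.90
    seed: int = 0

    def gcn_params(self) -> GCNParams:
        return GCNParams(
            min_module_size=self.min_module_size,
            max_kmeans_iter=self.max_kmeans_iter,
            power=self.power,
            network_type=self.network_type,
            reassign_floor=self.reassign_floor,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_triplets(triplets, path: str) -> None:
    rows = [
        {"gene": t.gene, "cell_type": t.cell_type, "network": t.network,
         "module": t.module, "mm": t.mm, "functions": ";".join(t.functions)}
        for t in triplets
    ]
    pd.DataFrame(rows, columns=["gene", "cell_type", "network", "module",
                                "mm", "functions"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def run_gmsca(config: RunConfig,
              expr: ExpressionMatrix | None = None) -> dict:
    """Run the full pipeline and return the manifest dict.

    ``expr`` may be passed directly (e.g. a synthetic matrix) instead of
    ``config.expression``. Any stage failure raises :class:`StageError`
    after writing a FAILED marker next to the partial outputs.
    """
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    failed_marker = os.path.join(outdir, "FAILED")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)
    written: list[str] = []
    stage = "preprocess"
    try:
        if expr is None:
            if not config.expression:
                raise FileNotFoundError("no expression matrix configured")
            expr = preprocess.read_expression(config.expression,
                                              orientation=config.orientation)
        if config.covariates:
            cov = preprocess.read_covariates(config.covariates)
            expr = preprocess.residualize(expr, cov)
        expr = preprocess.drop_zero_variance(expr)

        stage = "gcn"
        pgcn = build_network(expr, params=config.gcn_params(),
                             provenance="primary")
        written += [os.path.join("primary", f)
                    for f in write_network(pgcn, os.path.join(outdir, "primary"))]

        stage = "enrichment"
        if not config.markers:
            raise FileNotFoundError("no marker GMT configured (markers:)")
        marker_sets = read_gmt(config.markers)
        table, mapping = enrichment.assign_cell_types(
            pgcn, marker_sets, alpha=config.alpha,
            size_adjusted=config.size_adjust,
        )
        table.to_csv(os.path.join(outdir, "enrichment_primary.tsv"), sep="\t",
                     index=False, float_format="%.6g")
        written.append("enrichment_primary.tsv")

        function_sets = read_gmt(config.functions) if config.functions else []
        background = set(pgcn.gene_ids)

        def annotate(net):
            if not function_sets:
                return {}
            return enrichment.function_enrichment(
                {m: set(g) for m, g in net.modules().items()},
                function_sets, background, alpha=config.alpha)

        stage = "secondary"
        sgcn_results = secondary.build_all_secondary(
            expr, pgcn, mapping, params=config.gcn_params(),
            variance_target=config.variance_target,
        )
        removal_rows = []
        sgcns: dict[str, tuple] = {}
        for ct, res in sorted(sgcn_results.items()):
            subdir = os.path.join("secondary_" + ct)
            written += [os.path.join(subdir, f)
                        for f in write_network(res.network,
                                               os.path.join(outdir, subdir))]
            sec_table, sec_mapping = enrichment.assign_cell_types(
                res.network, marker_sets, alpha=config.alpha,
                size_adjusted=config.size_adjust,
            )
            sec_table.to_csv(os.path.join(outdir, f"enrichment_{ct}.tsv"),
                             sep="\t", index=False, float_format="%.6g")
            written.append(f"enrichment_{ct}.tsv")
            sgcns[ct] = (res.network, sec_mapping)
            removal_rows += [asdict(r) for r in res.reports]
        pd.DataFrame(removal_rows,
                     columns=["module", "cell_type", "n_components_90",
                              "variance_removed", "genes"]).to_csv(
            os.path.join(outdir, "signal_removal.tsv"), sep="\t", index=False,
            float_format="%.6g")
        written.append("signal_removal.tsv")

        stage = "classify"
        triplets = classify.extract_triplets(pgcn, mapping, annotate(pgcn))
        for ct, (net, sec_mapping) in sorted(sgcns.items()):
            triplets += classify.extract_triplets(net, sec_mapping, annotate(net))
        _write_triplets(triplets, os.path.join(outdir, "triplets.tsv"))
        written.append("triplets.tsv")
        states, summary = classify.aggregate_states(pgcn, mapping, sgcns)
        states.to_csv(os.path.join(outdir, "states.tsv"), sep="\t",
                      float_format="%.6g")
        written.append("states.tsv")
    except Exception as exc:
        with open(failed_marker, "w", encoding="utf-8") as fh:
            fh.write(f"{stage}: {exc}\n")
        if isinstance(exc, StageError):  # pragma: no cover - defensive
            raise
        raise StageError(stage, exc) from exc

    manifest = {
        "tool": "gmsca",
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "n_genes": expr.n_genes,
        "n_samples": expr.n_samples,
        "soft_power_primary": int(pgcn.soft_power),
        "enriched_modules_primary": dict(sorted(mapping.items())),
        "secondary_networks": sorted(sgcns),
        "n_triplets": len(triplets),
        "summary": summary,
        "checksums": {f: _sha256(os.path.join(outdir, f)) for f in sorted(written)},
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %d triplets, gain %.3f",
                len(triplets), summary["gain"])
    return manifest
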