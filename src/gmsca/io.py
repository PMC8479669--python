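"""Reading and writing the tool's plain-text interchange formats.

Expression and covariate tables are tab- or comma-delimited text (delimiter
inferred from the ``.tsv``/``.csv`` extension), UTF-8, ``.`` decimal.
Gene sets travel as GMT: one set per line, ``name<TAB>description<TAB>gene...``.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import pandas as pd

from .containers import CoexpressionNetwork, MarkerSet

_FLOAT_FMT = "%.10g"


def _delimiter_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_table(path: str) -> pd.DataFrame:
    """Read a delimited table with one header row and one identifier column."""
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path: str, index_label: str = "id") -> None:
    df.to_csv(path, sep=_delimiter_for(path), index_label=index_label,
              float_format=_FLOAT_FMT)


def read_gmt(path: str) -> list[MarkerSet]:
    """Parse a GMT file into a list of named gene sets.

    Duplicate set names are a hard error; empty sets are rejected by
    :class:`MarkerSet`.
    """
    sets: list[MarkerSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            sets.append(MarkerSet(cell_type=name, genes=set(genes), source=desc))
    return sets


def write_gmt(sets: Iterable[MarkerSet], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.cell_type, s.source or "na", *sorted(s.genes)]))
            fh.write("\n")


def write_network(network: CoexpressionNetwork, outdir: str) -> list[str]:
    """Serialize a network as assignment/eigengene/membership TSVs + JSON sidecar.

    Returns the list of files written (relative to ``outdir``).
    """
    os.makedirs(outdir, exist_ok=True)
    files = []
    assign = network.assignment.rename("module").to_frame()
    assign.to_csv(os.path.join(outdir, "assignment.tsv"), sep="\t",
                  index_label="gene_id")
    files.append("assignment.tsv")
    network.eigengenes.T.to_csv(os.path.join(outdir, "eigengenes.tsv"), sep="\t",
                                index_label="module", float_format=_FLOAT_FMT)
    files.append("eigengenes.tsv")
    network.membership.to_csv(os.path.join(outdir, "membership.tsv"), sep="\t",
                              index_label="gene_id", float_format=_FLOAT_FMT)
    files.append("membership.tsv")
    sidecar = {
        "soft_power": int(network.soft_power),
        "provenance": network.provenance,
        "params": network.params,
    }
    with open(os.path.join(outdir, "network.json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append("network.json")
    return files


def read_network(outdir: str) -> CoexpressionNetwork:
    assign = pd.read_csv(os.path.join(outdir, "assignment.tsv"), sep="\t",
                         index_col=0)["module"].astype(str)
    assign.index = assign.index.astype(str)
    eig = pd.read_csv(os.path.join(outdir, "eigengenes.tsv"), sep="\t",
                      index_col=0).T
    mm = pd.read_csv(os.path.join(outdir, "membership.tsv"), sep="\t", index_col=0)
    mm.index = mm.index.astype(str)
    with open(os.path.join(outdir, "network.json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    return CoexpressionNetwork(
        soft_power=sidecar["soft_power"], assignment=assign, eigengenes=eig,
        membership=mm, provenance=sidecar.get("provenance", "primary"),
        params=sidecar.get("params", {}),
    )
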