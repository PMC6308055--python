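"""Readers and writers for the pipeline's TSV/JSON/GraphML interchange formats.

All writers are deterministic (fixed row order and float formatting) so
a rerun with identical inputs and seeds is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .cerna import CeRNANetwork, InteractionTable
from .errors import SchemaError
from .expression import ExpressionMatrix
from .synthetic import SyntheticTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_pairing",
    "write_pairing",
    "read_interactions",
    "write_interactions",
    "write_pair_stats",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "write_truth",
    "read_truth",
]

FLOAT_FMT = "%.10g"


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_expression(expr_path: str | Path, pairing_path: str | Path) -> ExpressionMatrix:
    """Expression TSV (first column gene id, header of sample ids) plus
    a pairing TSV with columns tumor_id, normal_id."""
    expr_path, pairing_path = Path(expr_path), Path(pairing_path)
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        raise SchemaError(f"{expr_path}: duplicate gene ids")
    pairing = read_pairing(pairing_path)
    return ExpressionMatrix(values, pairing)


def write_expression(matrix: ExpressionMatrix, expr_path: str | Path, pairing_path: str | Path) -> None:
    matrix.values.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT)
    write_pairing(matrix.pairing, pairing_path)


def read_pairing(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["tumor_id", "normal_id"], path)
    return list(df.itertuples(index=False, name=None))


def write_pairing(pairing: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairing, columns=["tumor_id", "normal_id"]).to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path, rna_class: str) -> InteractionTable:
    """Interaction TSV with columns rna_id, mirna_id (one RNA class per file)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["rna_id", "mirna_id"], path)
    return InteractionTable(df, rna_class=rna_class)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.table.sort_values(["rna_id", "mirna_id"]).to_csv(path, sep="\t", index=False)


def write_pair_stats(pair_stats: pd.DataFrame, path: str | Path) -> None:
    """Pair-stats TSV; the shared miRNA set is comma-joined and sorted."""
    out = pair_stats.copy()
    out["shared_mirnas"] = out["shared_mirnas"].map(lambda s: ",".join(sorted(s)))
    out.sort_values(["lncrna_id", "mrna_id"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_edge_list(network: CeRNANetwork, path: str | Path) -> None:
    """Edge-list TSV: lncrna_id, mrna_id, n_shared, shared_mirnas, p_value."""
    rows = []
    for lnc, mrna in sorted(network.edge_pairs()):
        attrs = network.graph.edges[lnc, mrna]
        rows.append(
            {
                "lncrna_id": lnc,
                "mrna_id": mrna,
                "n_shared": attrs["n_shared"],
                "shared_mirnas": ",".join(sorted(attrs["shared_mirnas"])),
                "p_value": attrs["p_value"],
            }
        )
    pd.DataFrame(
        rows, columns=["lncrna_id", "mrna_id", "n_shared", "shared_mirnas", "p_value"]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path: str | Path) -> CeRNANetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"lncrna_id": str, "mrna_id": str})
    _require_columns(df, ["lncrna_id", "mrna_id", "n_shared", "shared_mirnas", "p_value"], path)
    net = CeRNANetwork()
    for row in df.itertuples(index=False):
        shared = frozenset() if pd.isna(row.shared_mirnas) or not row.shared_mirnas else frozenset(
            str(row.shared_mirnas).split(",")
        )
        net.graph.add_node(row.lncrna_id, node_class="lncRNA")
        net.graph.add_node(row.mrna_id, node_class="mRNA")
        net.graph.add_edge(
            row.lncrna_id,
            row.mrna_id,
            shared_mirnas=shared,
            n_shared=int(row.n_shared),
            p_value=float(row.p_value),
        )
    return net


def write_graphml(network: CeRNANetwork, path: str | Path) -> None:
    """GraphML export for visualization tools; set-valued edge
    attributes are serialized as comma-joined strings."""
    g = nx.Graph()
    for n, data in network.graph.nodes(data=True):
        g.add_node(n, **data)
    for u, v, data in network.graph.edges(data=True):
        attrs = dict(data)
        attrs["shared_mirnas"] = ",".join(sorted(attrs["shared_mirnas"]))
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, str(path))


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "de_genes": sorted(truth.de_genes),
        "up_genes": sorted(truth.up_genes),
        "down_genes": sorted(truth.down_genes),
        "cerna_pairs": sorted(list(p) for p in truth.cerna_pairs),
        "effect_size": truth.effect_size,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        de_genes=frozenset(payload["de_genes"]),
        cerna_pairs=frozenset(tuple(p) for p in payload["cerna_pairs"]),
        effect_size=payload["effect_size"],
        seed=payload["seed"],
        up_genes=frozenset(payload.get("up_genes", [])),
        down_genes=frozenset(payload.get("down_genes", [])),
    )
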