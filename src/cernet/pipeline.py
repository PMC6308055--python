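"""End-to-end orchestration: DEGs -> ceRNA network -> topology -> RWR -> ORA.

``run_pipeline`` binds the stage functions together from a single
config, writes every intermediate table under one run directory, and
records a manifest (parameters + input checksums + record counts) so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .cerna import CeRNANetwork, LNCRNA, build_network, test_all_pairs
from .enrichment import ora_test, read_gmt
from .errors import InvalidArgumentError, NotFoundError
from .expression import screen_degs
from .propagation import PropagationConfig, column_normalize, permutation_test, rwr
from .topology import centrality_table, hub_consensus

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "extract_subnetwork"]


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters in one place.

    Defaults follow the published analysis design: DEG screen at
    p < 0.001, hypergeometric edge test at p < 0.001, top-30 centrality
    consensus, RWR restart 0.8 with L1 tolerance 1e-6, and a
    1000-permutation null at p < 0.05.
    """

    expression_path: str
    pairing_path: str
    lnc_interactions_path: str
    mrna_interactions_path: str
    seeds: list[str]
    gmt_path: str | None = None
    alpha_deg: float = 0.001
    alpha_cerna: float = 0.001
    top_k: int = 30
    restart_r: float = 0.8
    tolerance: float = 1e-6
    max_iterations: int = 1000
    n_permutations: int = 1000
    rng_seed: int = 0
    alpha_perm: float = 0.05
    fdr_threshold: float = 0.05
    closeness_convention: str = "n-1"
    test_universe: str = "deg"  # "deg": test only DEG pairs; "all": test every pair
    perm_pool: str = "mrna"  # "mrna" or "all"
    perm_exclude_seeds: bool = False
    background_size: int | None = None
    include_tie_hubs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write its outputs under ``out_dir``.

    Returns the manifest dict. Outputs: deg_table.tsv, pair_stats.tsv,
    network_edges.tsv, network.graphml, centrality.tsv,
    hub_report.json, propagation.tsv, enrichment.tsv (when a GMT is
    configured), manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = cio.read_expression(config.expression_path, config.pairing_path)
    lnc_table = cio.read_interactions(config.lnc_interactions_path, rna_class="lncRNA")
    mrna_table = cio.read_interactions(config.mrna_interactions_path, rna_class="mRNA")

    # --- differential expression -----------------------------------------
    degs = screen_degs(matrix, alpha=config.alpha_deg)
    degs.sort_index().to_csv(out / "deg_table.tsv", sep="\t", float_format=cio.FLOAT_FMT)
    deg_ids = set(degs.index[degs["significant"]])
    deg_lnc = deg_ids & set(lnc_table.rna_ids)
    deg_mrna = deg_ids & set(mrna_table.rna_ids)
    logger.info("DEG screen: %d significant (%d lncRNA, %d mRNA)", len(deg_ids), len(deg_lnc), len(deg_mrna))

    # --- ceRNA edge inference ---------------------------------------------
    if config.test_universe == "deg":
        lnc_ids, mrna_ids = sorted(deg_lnc), sorted(deg_mrna)
    elif config.test_universe == "all":
        lnc_ids, mrna_ids = lnc_table.rna_ids, mrna_table.rna_ids
    else:
        raise InvalidArgumentError(f"test_universe must be 'deg' or 'all', got {config.test_universe!r}")

    if lnc_ids and mrna_ids:
        pair_stats = test_all_pairs(
            lnc_table,
            mrna_table,
            lnc_ids,
            mrna_ids,
            alpha=config.alpha_cerna,
            background_size=config.background_size,
        )
        network = build_network(pair_stats, deg_lnc, deg_mrna, alpha=config.alpha_cerna)
    else:
        logger.warning("no DEG lncRNAs or mRNAs; network is empty")
        pair_stats = pd.DataFrame(
            columns=["lncrna_id", "mrna_id", "T", "M", "k", "x", "shared_mirnas", "p_value", "significant"]
        )
        network = CeRNANetwork()
    cio.write_pair_stats(pair_stats, out / "pair_stats.tsv")
    cio.write_edge_list(network, out / "network_edges.tsv")
    cio.write_graphml(network, out / "network.graphml")
    logger.info(
        "ceRNA network: %d lncRNAs, %d mRNAs, %d edges",
        len(network.lncrna_nodes),
        len(network.mrna_nodes),
        network.n_edges,
    )

    empty_net = network.n_edges == 0
    hub_nodes: set[str] = set()
    prop_table = pd.DataFrame(
        columns=["node_class", "stationary_probability", "theta", "p_value", "significant"]
    )
    prop_table.index.name = "node"

    if not empty_net:
        # --- topology ------------------------------------------------------
        ctable = centrality_table(network, closeness_convention=config.closeness_convention)
        ctable.to_csv(out / "centrality.tsv", sep="\t", float_format=cio.FLOAT_FMT)
        k = min(config.top_k, len(ctable))
        report = hub_consensus(ctable, k=k, include_ties=config.include_tie_hubs)
        (out / "hub_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        hub_nodes = report.hub_nodes

        # --- propagation ---------------------------------------------------
        adjacency = column_normalize(network)
        missing = [s for s in config.seeds if s not in adjacency.nodes]
        if missing:
            raise NotFoundError(f"RWR seed gene(s) absent from the network: {missing}")
        prop_cfg = PropagationConfig(
            seeds=list(config.seeds),
            restart_r=config.restart_r,
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
        )
        observed = rwr(adjacency, prop_cfg)
        pool = None if config.perm_pool == "mrna" else list(adjacency.nodes)
        perm = permutation_test(
            adjacency,
            prop_cfg,
            observed,
            n_permutations=config.n_permutations,
            rng_seed=config.rng_seed,
            candidate_pool=pool,
            exclude_seeds=config.perm_exclude_seeds,
        )
        prop_table = pd.DataFrame(
            {
                "node_class": [adjacency.node_class[n] for n in adjacency.nodes],
                "stationary_probability": observed.probabilities,
                "theta": perm.theta,
                "p_value": perm.p_g,
                "significant": perm.p_g < config.alpha_perm,
            }
        )
        prop_table.index.name = "node"
        (out / "propagation_meta.json").write_text(
            json.dumps(
                {
                    "restart_r": config.restart_r,
                    "tolerance": config.tolerance,
                    "iterations": observed.iterations,
                    "converged": observed.converged,
                    "seeds": list(config.seeds),
                    "n_permutations": config.n_permutations,
                    "rng_seed": config.rng_seed,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    else:
        (out / "centrality.tsv").write_text("node\tnode_class\tdegree\tbetweenness\tcloseness\n")
        (out / "hub_report.json").write_text(
            json.dumps({"top_k": 0, "hub_nodes": []}, indent=2, sort_keys=True) + "\n"
        )
    prop_table.sort_index().to_csv(out / "propagation.tsv", sep="\t", float_format=cio.FLOAT_FMT)

    # --- enrichment of mRNA partners of propagation-significant lncRNAs ----
    enrich_rows = 0
    if config.gmt_path is not None and not empty_net:
        collection = read_gmt(config.gmt_path)
        sig_lnc = sorted(
            set(prop_table.index[(prop_table["significant"]) & (prop_table["node_class"] == LNCRNA)])
        )
        background = set(network.mrna_nodes)
        partners = {m for l in sig_lnc for m in network.graph.neighbors(l)}
        if partners:
            table = ora_test(partners, collection, background, fdr_threshold=config.fdr_threshold)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format=cio.FLOAT_FMT)
            enrich_rows = len(table)
        else:
            logger.warning("no propagation-significant lncRNA; enrichment skipped")
            pd.DataFrame(
                columns=["set_name", "description", "overlap", "set_size", "p_value", "fdr", "significant"]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    manifest = {
        "parameters": {k: v for k, v in asdict(config).items() if not k.endswith("_path")},
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in {
                "expression": config.expression_path,
                "pairing": config.pairing_path,
                "lnc_interactions": config.lnc_interactions_path,
                "mrna_interactions": config.mrna_interactions_path,
                **({"gene_sets": config.gmt_path} if config.gmt_path else {}),
            }.items()
        },
        "counts": {
            "genes_screened": int(len(degs)),
            "degs": int(len(deg_ids)),
            "deg_lncrnas": int(len(deg_lnc)),
            "deg_mrnas": int(len(deg_mrna)),
            "pairs_tested": int(len(pair_stats)),
            "network_lncrnas": len(network.lncrna_nodes),
            "network_mrnas": len(network.mrna_nodes),
            "network_edges": network.n_edges,
            "hub_nodes": len(hub_nodes),
            "propagation_significant": int(prop_table["significant"].sum()) if len(prop_table) else 0,
            "enriched_sets_tested": enrich_rows,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def extract_subnetwork(network: CeRNANetwork, node_id: str) -> pd.DataFrame:
    """Incident-edge star of one node: its neighbors and mediating miRNAs.

    Returns the same columns as the network edge list, restricted to
    edges touching ``node_id``.
    """
    if node_id not in network.graph:
        raise NotFoundError(f"node {node_id!r} not in network")
    rows = []
    for nbr in network.graph.neighbors(node_id):
        attrs = network.graph.edges[node_id, nbr]
        lnc, mrna = (
            (node_id, nbr)
            if network.graph.nodes[node_id]["node_class"] == LNCRNA
            else (nbr, node_id)
        )
        rows.append(
            {
                "lncrna_id": lnc,
                "mrna_id": mrna,
                "n_shared": attrs["n_shared"],
                "shared_mirnas": ",".join(sorted(attrs["shared_mirnas"])),
                "p_value": attrs["p_value"],
            }
        )
    return (
        pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "n_shared", "shared_mirnas", "p_value"])
        .sort_values(["lncrna_id", "mrna_id"])
        .reset_index(drop=True)
    )
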