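"""Infer competing lncRNA-mRNA pairs by the shared-miRNA hypergeometric
test (p < 0.001) and assemble the bipartite ceRNA network from DEGs.

Writes pair_stats.tsv, network_edges.tsv and network.graphml under
results/, and reports the network composition and planted-pair recovery.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernet import io as cio
from cernet.cerna import build_network, test_all_pairs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.001)
    args = ap.parse_args()

    lnc = cio.read_interactions(args.study / "lnc_interactions.tsv", rna_class="lncRNA")
    mrna = cio.read_interactions(args.study / "mrna_interactions.tsv", rna_class="mRNA")
    degs = pd.read_csv(args.out / "deg_table.tsv", sep="\t", index_col=0)
    deg_ids = set(degs.index[degs["significant"]])
    deg_lnc = sorted(deg_ids & set(lnc.rna_ids))
    deg_mrna = sorted(deg_ids & set(mrna.rna_ids))

    stats = test_all_pairs(lnc, mrna, deg_lnc, deg_mrna, alpha=args.alpha)
    net = build_network(stats, set(deg_lnc), set(deg_mrna), alpha=args.alpha)
    cio.write_pair_stats(stats, args.out / "pair_stats.tsv")
    cio.write_edge_list(net, args.out / "network_edges.tsv")
    cio.write_graphml(net, args.out / "network.graphml")

    truth = cio.read_truth(args.study / "truth.json")
    recovered = truth.cerna_pairs & net.edge_pairs()
    print(f"tested {len(stats)} DEG lncRNA x mRNA pairs at p < {args.alpha}")
    print(
        f"network: {len(net.lncrna_nodes)} lncRNAs, {len(net.mrna_nodes)} mRNAs, "
        f"{net.n_edges} edges"
    )
    print(f"planted sponge pairs recovered: {len(recovered)}/{len(truth.cerna_pairs)}")
    print(f"edge list written to {args.out / 'network_edges.tsv'}")


if __name__ == "__main__":
    main()
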