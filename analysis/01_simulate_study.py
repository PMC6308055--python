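"""Simulate the study inputs: a paired tumor/normal expression cohort and
lncRNA/mRNA-miRNA interaction tables with a planted sponge architecture.

Writes the pipeline's input files plus the ground truth under
results/study/, and a small GMT whose first set collects the planted
sponge-target mRNAs (so downstream enrichment has a true positive).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cernet import io as cio
from cernet.synthetic import simulate_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(seed=args.seed)
    cio.write_expression(study.expression, out / "expression.tsv", out / "pairing.tsv")
    cio.write_interactions(study.lnc_table, out / "lnc_interactions.tsv")
    cio.write_interactions(study.mrna_table, out / "mrna_interactions.tsv")
    cio.write_truth(study.truth, out / "truth.json")

    planted_mrnas = sorted({m for _, m in study.truth.cerna_pairs})
    rng = np.random.default_rng(args.seed + 100)
    lines = ["planted_sponge_targets\tplanted ceRNA partner mRNAs\t" + "\t".join(planted_mrnas)]
    for i in range(3):
        decoy = sorted(rng.choice(study.mrna_ids, size=len(planted_mrnas), replace=False))
        lines.append(f"decoy_{i}\trandom mRNA set\t" + "\t".join(decoy))
    (out / "gene_sets.gmt").write_text("\n".join(lines) + "\n")

    meta = {
        "seed": args.seed,
        "hub_lncrna": study.hub_lncrna,
        "rwr_seed_genes": study.seed_genes,
        "n_genes": len(study.expression.gene_ids),
        "n_sample_pairs": study.expression.n_pairs,
        "n_planted_pairs": len(study.truth.cerna_pairs),
    }
    (out / "study_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    print(f"simulated {meta['n_genes']} genes x {meta['n_sample_pairs']} tumor/normal pairs")
    print(f"planted {meta['n_planted_pairs']} sponge pairs; hub lncRNA: {study.hub_lncrna}")
    print(f"RWR seed genes (hub partners): {', '.join(study.seed_genes)}")
    print(f"inputs written to {out}/")


if __name__ == "__main__":
    main()
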