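# cernet

Competing endogenous RNA (ceRNA) network inference and hub-gene
prioritization, as an importable library plus a numbered analysis
workflow.

## The problem

Many lncRNAs act as miRNA "sponges": by binding the same miRNAs as a
protein-coding transcript they de-repress it, forming a
lncRNA–miRNA–mRNA regulatory axis. Given (a) a paired tumor/normal
expression cohort and (b) RNA–miRNA interaction tables, the analysis
asks which differentially expressed lncRNA–mRNA pairs share improbably
many miRNAs, assembles those pairs into a bipartite network, and asks
which nodes are hubs — both topologically and by proximity to known
disease genes.

The statistical core:

- **Paired DEG screen** — per gene, t = mean(d)/(sd(d)/√n) on the
  within-pair log differences d, two-sided p from t_{n−1}, significant
  at p < 0.001 (strict, uncorrected).
- **Shared-miRNA test** — for a lncRNA with M miRNAs and an mRNA with
  k miRNAs in a background of T, the edge evidence is the
  hypergeometric upper tail
  P(X ≥ x) = 1 − Σ_{i=0}^{x−1} C(k,i)·C(T−k,M−i)/C(T,M), thresholded
  at p < 0.001. Edges carry their mediating miRNA sets; miRNAs are not
  nodes.
- **Centrality consensus** — degree, unnormalized betweenness
  Σ_{s≠t≠v} σ_st(v)/σ_st and closeness (n−1)/Σ dist; hubs are the
  intersection of the three top-30 lists.
- **Random walk with restart** — P_{i+1} = (1−r)·M·P_i + r·P_0 with
  restart r = 0.8 on the column-normalized adjacency M, seeds uniform
  in P_0, iterated to L1 tolerance 1e−6; significance from a 1000-set
  permutation null, p_g = θ_g/1000 (θ counts permuted runs strictly
  beating the observed probability), significant at p < 0.05.
- **Over-representation** — the same hypergeometric tail against GMT
  gene sets with Benjamini–Hochberg FDR < 0.05.

See `docs/methods.md` for conventions, numerics and limitations.

## Worked example

The `analysis/` scripts run the whole workflow on a synthetic study
with planted ground truth: 44 tumor/normal pairs over 5 lncRNAs + 150
mRNAs, and 11 planted sponge pairs with fully overlapping miRNA sets,
spread so that one lncRNA (`lnc_000`) is the unique three-partner hub.

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_screen_degs.py
python analysis/03_build_cerna_network.py
python analysis/04_rank_hubs.py
python analysis/05_propagate_and_test.py --seed 1
python analysis/06_enrich_hub_partners.py
```

which prints (abridged):

```
screened 155 genes at p < 0.001: 39 significant
planted-DE recall 1.000, false-positive rate 0.0000
tested 170 DEG lncRNA x mRNA pairs at p < 0.001
network: 5 lncRNAs, 11 mRNAs, 11 edges
planted sponge pairs recovered: 11/11
planted hub lnc_000: degree 3, betweenness 3.00, closeness 1.0000; in consensus: True
RWR converged in 10 iterations from seeds mrna_0000, mrna_0005, mrna_0010 (r = 0.8)
permutation-significant lncRNAs (p < 0.05): lnc_000
planted hub lnc_000: stationary probability 0.1667, permutation p = 0.000
* planted_sponge_targets: overlap 3/11, p = 0.000299, FDR = 0.0012
```

Reading the numbers: all 39 planted differential genes are recovered
with no false positives; every planted sponge pair passes the
hypergeometric threshold (a full 8/8 miRNA overlap in a background of
150 has p ≈ 2e−12) and no chance pair does; the planted hub is in the
centrality consensus; the walk started from the hub's three mRNA
partners concentrates probability on the hub, and none of 1000 random
seed triples beats it (p = 0.000 < 0.05); and the hub's partners
enrich the planted target gene set at FDR 0.0012 while decoy sets do
not.

The same stages are available programmatically
(`cernet.simulate_study`, `cernet.screen_degs`, `cernet.test_all_pairs`,
`cernet.build_network`, `cernet.hub_consensus`, `cernet.rwr`,
`cernet.permutation_test`, `cernet.ora_test`), and
`cernet.run_pipeline(PipelineConfig(...), out_dir)` runs everything
from one config with a checksummed manifest and byte-identical reruns.

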