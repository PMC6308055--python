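# Methods

`cernet` implements a competing-endogenous-RNA (ceRNA) network analysis
of the kind used to nominate regulatory lncRNAs in cancer cohorts: a
paired differential-expression screen feeds a shared-miRNA
hypergeometric test that defines a bipartite lncRNA–mRNA network, on
which hub genes are ranked by centrality consensus and by network
propagation against a permutation null. This note records the model,
the parameter choices, and the limits of what the synthetic validation
shows.

## Paired differential expression

Input is a genes × samples matrix of log-scale intensities with an
explicit list of (tumor, normal) sample pairs; any platform
preprocessing (RMA or similar) is the caller's responsibility. For each
gene the within-pair differences d are tested with the paired t
statistic t = mean(d) / (sd(d)/√n) (sample sd, n−1 denominator),
two-sided p from Student's t with n−1 degrees of freedom. Sidedness is
two-sided because differential genes are of interest in both
directions.

A gene is called differential when p < `alpha_deg` strictly
(default 0.001). No multiple-testing correction is applied at this
stage: the screen is deliberately a raw hard threshold, and its type-I
behaviour is part of the validated contract (the expected significant
fraction under the null is `alpha_deg`). Genes whose differences have
exactly zero variance are reported as degenerate and non-significant
rather than failing the screen. No fold-change filter is applied on top
of the p-value.

Probe-level inputs are supported by two helpers: `filter_probe_hits`
accepts a transcript only if, after discarding probes that hit more
than one transcript anywhere in the table and probes with any
mismatch, at least `min_probes` probes remain (default 4 — "more than
three" read literally; the threshold is exposed because ≥3 is an
equally common convention), and `aggregate_probes` collapses probe rows
to a gene row by the per-sample arithmetic mean.

## Shared-miRNA hypergeometric test

For a lncRNA with miRNA set of size M and an mRNA with miRNA set of
size k in a background of T miRNAs, the evidence that they compete for
the same miRNAs is the upper tail of the hypergeometric distribution at
the observed shared count x:

    P(X ≥ x) = 1 − Σ_{i=0}^{x−1} C(k, i) · C(T−k, M−i) / C(T, M)

**Background.** T defaults to the number of distinct miRNAs in the
union of the two interaction tables. Per-class miRNA counts generally
differ between lncRNA and mRNA interaction resources, and the union is
the only universe in which both M and k are simultaneously well
defined; `background_size` overrides it when a curated genome-wide
count is preferred. Only set membership matters — interaction records
are de-duplicated, CLIP read multiplicities are ignored.

**Numerics.** The tail is evaluated as Σ_{i=x}^{min(M,k)} of the pmf
with log-space binomial coefficients (`gammaln` + `logsumexp`). This is
algebraically identical to the 1 − Σ form above but does not lose the
answer to cancellation when the tail is ~1e−12 (a fully overlapping
pair in a realistic background), and it is stable for T beyond 1e4.
The implementation is cross-checked in the tests against
`scipy.stats.hypergeom.sf` and against exact subset enumeration for
every valid case with T ≤ 12.

**Network assembly.** Pairs with p < `alpha_cerna` (default 0.001,
strict, uncorrected) whose two endpoints are both differentially
expressed become edges of a bipartite lncRNA–mRNA graph. miRNAs are not
nodes: each edge carries its mediating miRNA set as an attribute. Nodes
with no surviving edge are excluded. By default only DEG lncRNAs ×
DEG mRNAs are tested (`test_universe="deg"`); setting it to `"all"`
tests every pair first and filters later — the two orders give the same
edges, but the option exists because the uncorrected p-values of
untested pairs are sometimes wanted.

## Topology

Three per-node metrics, computed with networkx behind the module
surface and verified against brute-force BFS/path-counting oracles in
the tests:

- **Degree**: incident edge count.
- **Betweenness**: Σ over unordered pairs {s,t} (s ≠ t ≠ v) of
  σ_st(v)/σ_st, *unnormalized* — raw shortest-path counts, which is
  what per-node values in the hundreds-to-thousands range on a
  ~250-node network correspond to.
- **Closeness**: (m−1)/Σ_t dist(v,t) computed within v's connected
  component of m nodes. The numerator constant is a config switch
  (`"n-1"` default, `"n"` alternative) because both conventions are
  in circulation; isolated nodes get NaN. Components are handled
  separately since nothing guarantees the ceRNA graph is connected.

**Hub consensus**: nodes are ranked per metric (descending value, ties
broken lexicographically by id for determinism; an `include_ties` flag
keeps all boundary-tied nodes instead) and the hub set is the
intersection of the three top-k lists, k = 30 by default.

## Random walk with restart

With M the column-stochastic adjacency (A_ij = 1/deg(j) per edge;
columns of isolated nodes are replaced by the uniform distribution) and
P_0 uniform over the seed genes, iterate

    P_{i+1} = (1 − r) M P_i + r P_0,    r = 0.8

until the L1 difference of successive vectors is < 1e−6 (configurable;
the iteration is an L1 contraction with factor 1−r, so convergence to
the unique solution of (I − (1−r)M)P = rP_0 is geometric and the tests
confirm agreement with the direct linear solve within 10× tolerance).
Probability mass is conserved exactly at every step because M is
column-stochastic.

**Permutation null.** Each of `n_permutations` (default 1000) rounds
draws |seeds| distinct nodes uniformly from a candidate pool and reruns
the walk from scratch (no warm start — purity over speed at this
scale). For each gene g, θ_g counts rounds whose stationary probability
*strictly* exceeds the observed one (ties do not count), and
p_g = θ_g / n_permutations, significant at p < 0.05. The pool defaults
to mRNA nodes only, matching the type of typical protein-coding seed
genes; `perm_pool="all"` widens it, and `perm_exclude_seeds` removes
the true seeds from the pool (off by default — a random draw that
happens to coincide with the truth is a legitimate null sample).

## Over-representation analysis

A query gene list is scored against each set of a GMT collection by the
same hypergeometric upper tail (T = |background|, M = |query|,
k = |set ∩ background|, x = |overlap|), one-sided for
over-representation only, with Benjamini–Hochberg FDR across sets and
significance at FDR < 0.05. The pipeline's default background is the
network's mRNA nodes; the enrichment analysis script widens it to the
full mRNA interaction universe, because a query drawn from a small
network measured against that same small network has no room to
enrich.

## Synthetic data: what it emulates and what it does not

`generate_paired_expression` draws value = gene baseline
(N(8, 1)) + pair baseline (N(0, 0.5), shared within a tumor/normal
pair) + condition effect + noise (N(0, noise_sd)). Planted differential
genes — round(n_genes · de_fraction) of them, the first k after a
seeded shuffle, alternating up/down — have paired differences with mean
±effect. Under this additive Gaussian model the paired t-test is exact,
so recovery rates are interpretable as statistical power rather than as
robustness claims.

`generate_interaction_tables` gives every RNA `baseline_mirnas_per_rna`
miRNAs drawn uniformly without replacement, so non-planted pairs
overlap only by chance. Planted sponge pairs are assigned round-robin
over the lncRNAs; each planted lncRNA carries one fixed core of
`planted_overlap` of its own miRNAs inherited by all of its planted
partners, which keeps the overlap guarantee consistent when one lncRNA
has several partners (with full overlap, per-pair independent cores
would be contradictory).

`simulate_study` coordinates the two on one gene universe, forcing the
planted ceRNA genes into the DE set. Default study conditions: 44
tumor/normal pairs, effect 2.0 log-units, noise 0.5; 5 lncRNAs × 150
mRNAs × 150 miRNAs with 8 miRNAs per RNA; 11 planted pairs with full
(8/8) overlap. Eleven pairs round-robin over five lncRNAs leave lncRNA
0 with three partners — the unique planted hub — and its three partners
serve as the known-disease-gene seeds for the walk. At these settings
the planted signals are strong by construction: a full-overlap pair has
p = 1/C(150,8) ≈ 2e−12, far below the 0.001 threshold, and the DEG
screen at effect/noise = 4 with n = 44 has power ≈ 1.

What passing these tests does **not** show: robustness to probe-level
artefacts, count noise or non-Gaussian heavy tails; correct behaviour
under correlated genes (the generator draws genes independently);
realistic interaction-table biases (hub miRNAs, degree-correlated
false positives in CLIP data). The generator is a power and correctness
harness, not a realism benchmark.

## Problem sizes used in the validation suites

Exhaustive hypergeometric enumeration covers all ~3200 valid
(T ≤ 12, M, k, x) cases; centrality oracles run on 200 random graphs of
≤ 12 nodes; the RWR linear-solve comparison on 100 random graphs; the
type-I-error simulation on 50 cohorts of 200 null genes × 44 pairs
(10 000 tests); the end-to-end run uses the default study above with
1000 permutations. These sizes make every oracle exact or statistically
sharp while keeping the whole suite interactive.

## Known limitations

- Strict-threshold screening without multiple-testing correction is
  faithful to the analysis design it reproduces but anticonservative as
  a discovery procedure; the ORA stage is the only FDR-controlled step.
- The permutation p-value has resolution 1/n_permutations and is
  reported as exactly θ/n (no +1 smoothing), so p = 0 means "better
  than every permuted draw", not "impossibly extreme".
- Closeness on disconnected graphs is per-component and values are not
  comparable across components of different sizes.
- The pipeline assumes identifiers are already harmonized between the
  expression matrix and the interaction tables; no symbol mapping is
  attempted.
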