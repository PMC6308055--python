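"""Synthetic data with planted structure for end-to-end validation.

Two generators emulate the pipeline's inputs: paired tumor/normal
log-intensity matrices with planted differential effects, and RNA-miRNA
interaction tables with planted high-overlap "sponging" pairs. Both are
driven by an explicit seed (one RNG stream per call, no global state),
so identical arguments reproduce identical outputs, and both return a
``SyntheticTruth`` describing exactly what was planted.

The expression model is additive Gaussian on the log scale: per-gene
baseline + per-pair baseline + condition effect + i.i.d. noise. Under
this model the paired t-test on tumor-normal differences is exact,
which is what makes planted-recovery rates interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cerna import InteractionTable, LNCRNA, MRNA
from .errors import InvalidArgumentError
from .expression import ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "generate_paired_expression",
    "generate_interaction_tables",
    "SyntheticStudy",
    "simulate_study",
]

# Per-pair baseline spread (log units): biological pair-to-pair variation
# shared by both members of a pair, removed exactly by the paired design.
_PAIR_BASELINE_SD = 0.5
_GENE_BASELINE_MEAN = 8.0
_GENE_BASELINE_SD = 1.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic dataset.

    de_genes: ids planted as differential (50/50 up/down);
    cerna_pairs: (lncRNA, mRNA) pairs planted with high miRNA overlap;
    effect_size: mean paired log-difference magnitude for DE genes.
    """

    de_genes: frozenset[str]
    cerna_pairs: frozenset[tuple[str, str]]
    effect_size: float
    seed: int
    up_genes: frozenset[str] = frozenset()
    down_genes: frozenset[str] = frozenset()


def generate_paired_expression(
    n_genes: int,
    n_pairs: int,
    de_fraction: float,
    effect: float,
    noise_sd: float,
    seed: int,
    *,
    gene_ids: list[str] | None = None,
    de_gene_ids: set[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a paired tumor/normal log-expression matrix.

    ``round(n_genes * de_fraction)`` genes are planted as differential:
    the first k ids after a seeded shuffle, alternating up/down so the
    directions split 50/50. DE genes' tumor-normal differences have
    mean +/-``effect``; all others mean 0. Columns are labelled
    ``T###``/``N###`` per pair and the pairing list is attached to the
    returned matrix.

    Keyword overrides: ``gene_ids`` names the gene universe explicitly
    (length must equal n_genes); ``de_gene_ids`` fixes the planted DE
    set instead of the shuffle rule.
    """
    if n_genes <= 0 or n_pairs < 2:
        raise InvalidArgumentError(
            f"need n_genes > 0 and n_pairs >= 2, got {n_genes}, {n_pairs}"
        )
    if not 0.0 <= de_fraction <= 1.0:
        raise InvalidArgumentError(f"de_fraction must be in [0, 1], got {de_fraction}")
    if noise_sd <= 0:
        raise InvalidArgumentError(f"noise_sd must be positive, got {noise_sd}")

    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise InvalidArgumentError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(seed)

    if de_gene_ids is None:
        k = int(round(n_genes * de_fraction))
        shuffled = list(rng.permutation(gene_ids))
        de_list = shuffled[:k]
    else:
        unknown = set(de_gene_ids) - set(gene_ids)
        if unknown:
            raise InvalidArgumentError(f"de_gene_ids not in gene universe: {sorted(unknown)[:3]}")
        de_list = sorted(de_gene_ids)
    up = frozenset(de_list[0::2])
    down = frozenset(de_list[1::2])

    delta = np.zeros(n_genes)
    pos = {g: i for i, g in enumerate(gene_ids)}
    for g in up:
        delta[pos[g]] = effect
    for g in down:
        delta[pos[g]] = -effect

    gene_base = rng.normal(_GENE_BASELINE_MEAN, _GENE_BASELINE_SD, size=n_genes)
    pair_base = rng.normal(0.0, _PAIR_BASELINE_SD, size=n_pairs)
    noise_t = rng.normal(0.0, noise_sd, size=(n_genes, n_pairs))
    noise_n = rng.normal(0.0, noise_sd, size=(n_genes, n_pairs))

    tumor = gene_base[:, None] + pair_base[None, :] + delta[:, None] + noise_t
    normal = gene_base[:, None] + pair_base[None, :] + noise_n

    tumor_ids = [f"T{i:03d}" for i in range(n_pairs)]
    normal_ids = [f"N{i:03d}" for i in range(n_pairs)]
    values = pd.DataFrame(
        np.hstack([tumor, normal]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=tumor_ids + normal_ids,
    )
    matrix = ExpressionMatrix(values, pairing=list(zip(tumor_ids, normal_ids)))
    truth = SyntheticTruth(
        de_genes=frozenset(de_list),
        cerna_pairs=frozenset(),
        effect_size=effect,
        seed=seed,
        up_genes=up,
        down_genes=down,
    )
    return matrix, truth


def generate_interaction_tables(
    n_lnc: int,
    n_mrna: int,
    n_mirna: int,
    baseline_mirnas_per_rna: int,
    n_planted_pairs: int,
    planted_overlap: int,
    seed: int,
) -> tuple[InteractionTable, InteractionTable, SyntheticTruth]:
    """Simulate lncRNA-miRNA and mRNA-miRNA interaction tables.

    Every RNA interacts with ``baseline_mirnas_per_rna`` miRNAs drawn
    uniformly without replacement, so non-planted pairs share miRNAs
    only by chance. Planted pairs are assigned round-robin over the
    lncRNAs (pair j links lncRNA ``j % n_lnc`` with mRNA j); each
    planted lncRNA carries one fixed "sponge core" of
    ``planted_overlap`` of its own miRNAs that all of its planted
    partners inherit, so every planted pair shares at least
    ``planted_overlap`` miRNAs even when one lncRNA has several
    partners.
    """
    if min(n_lnc, n_mrna, n_mirna) <= 0:
        raise InvalidArgumentError("RNA and miRNA universe sizes must be positive")
    if not 0 <= planted_overlap <= baseline_mirnas_per_rna <= n_mirna:
        raise InvalidArgumentError(
            "need 0 <= planted_overlap <= baseline_mirnas_per_rna <= n_mirna; "
            f"got {planted_overlap}, {baseline_mirnas_per_rna}, {n_mirna}"
        )
    if n_planted_pairs < 0 or n_planted_pairs > n_mrna:
        raise InvalidArgumentError(
            f"n_planted_pairs must be in [0, n_mrna]; got {n_planted_pairs}"
        )

    rng = np.random.default_rng(seed)
    lnc_ids = [f"lnc_{i:03d}" for i in range(n_lnc)]
    mrna_ids = [f"mrna_{i:04d}" for i in range(n_mrna)]
    mirna_ids = np.array([f"mir_{i:04d}" for i in range(n_mirna)])

    sets: dict[str, np.ndarray] = {}
    for rna in lnc_ids + mrna_ids:
        sets[rna] = rng.choice(mirna_ids, size=baseline_mirnas_per_rna, replace=False)

    pairs: list[tuple[str, str]] = []
    cores: dict[str, np.ndarray] = {}
    for j in range(n_planted_pairs):
        lnc = lnc_ids[j % n_lnc]
        mrna = mrna_ids[j]
        if lnc not in cores:
            # the sponge core is a fixed subset of the lncRNA's own miRNAs
            cores[lnc] = sets[lnc][:planted_overlap]
        core = cores[lnc]
        rest_pool = mirna_ids[~np.isin(mirna_ids, core)]
        fill = rng.choice(
            rest_pool, size=baseline_mirnas_per_rna - planted_overlap, replace=False
        )
        sets[mrna] = np.concatenate([core, fill])
        pairs.append((lnc, mrna))

    def table_for(ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            [(rna, mir) for rna in ids for mir in sorted(sets[rna])],
            columns=["rna_id", "mirna_id"],
        )

    lnc_table = InteractionTable(table_for(lnc_ids), rna_class=LNCRNA)
    mrna_table = InteractionTable(table_for(mrna_ids), rna_class=MRNA)
    truth = SyntheticTruth(
        de_genes=frozenset(),
        cerna_pairs=frozenset(pairs),
        effect_size=0.0,
        seed=seed,
    )
    return lnc_table, mrna_table, truth


@dataclass
class SyntheticStudy:
    """A coordinated end-to-end synthetic study.

    Expression and interaction data share one gene universe; the
    planted ceRNA genes are forced into the DE set so planted edges
    survive the DEG filter. ``hub_lncrna`` is the unique planted lncRNA
    with the most planted partners; ``seed_genes`` are three of its
    planted mRNA partners, playing the role of known disease genes.
    """

    expression: ExpressionMatrix
    lnc_table: InteractionTable
    mrna_table: InteractionTable
    truth: SyntheticTruth
    hub_lncrna: str
    seed_genes: list[str]
    lnc_ids: list[str] = field(default_factory=list)
    mrna_ids: list[str] = field(default_factory=list)


def simulate_study(
    seed: int,
    n_lnc: int = 5,
    n_mrna: int = 150,
    n_mirna: int = 150,
    baseline_mirnas_per_rna: int = 8,
    n_planted_pairs: int = 11,
    planted_overlap: int = 8,
    n_pairs: int = 44,
    de_fraction: float = 0.25,
    effect: float = 2.0,
    noise_sd: float = 0.5,
) -> SyntheticStudy:
    """Generate one coherent synthetic study for the whole pipeline.

    Defaults model a mid-sized paired-cohort microarray study: 44
    tumor/normal pairs, DE effect 2.0 log-units against noise 0.5, and
    a sponge architecture of 11 fully overlapping planted pairs spread
    round-robin over 5 lncRNAs — leaving lncRNA 0 with three partners,
    the unique planted hub.
    """
    lnc_table, mrna_table, int_truth = generate_interaction_tables(
        n_lnc,
        n_mrna,
        n_mirna,
        baseline_mirnas_per_rna,
        n_planted_pairs,
        planted_overlap,
        seed,
    )
    lnc_ids = lnc_table.rna_ids
    mrna_ids = mrna_table.rna_ids
    universe = lnc_ids + mrna_ids

    planted_genes = {g for pair in int_truth.cerna_pairs for g in pair}
    n_genes = len(universe)
    k = int(round(n_genes * de_fraction))
    rng = np.random.default_rng(seed + 1)
    extras = [g for g in rng.permutation(universe) if g not in planted_genes]
    de_set = set(planted_genes) | set(extras[: max(0, k - len(planted_genes))])

    expression, expr_truth = generate_paired_expression(
        n_genes,
        n_pairs,
        de_fraction,
        effect,
        noise_sd,
        seed + 2,
        gene_ids=universe,
        de_gene_ids=de_set,
    )

    partners: dict[str, list[str]] = {}
    for lnc, mrna in sorted(int_truth.cerna_pairs):
        partners.setdefault(lnc, []).append(mrna)
    hub = max(partners, key=lambda l: (len(partners[l]), l)) if partners else ""
    seed_genes = sorted(partners.get(hub, []))[:3]

    truth = SyntheticTruth(
        de_genes=expr_truth.de_genes,
        cerna_pairs=int_truth.cerna_pairs,
        effect_size=effect,
        seed=seed,
        up_genes=expr_truth.up_genes,
        down_genes=expr_truth.down_genes,
    )
    return SyntheticStudy(
        expression=expression,
        lnc_table=lnc_table,
        mrna_table=mrna_table,
        truth=truth,
        hub_lncrna=hub,
        seed_genes=seed_genes,
        lnc_ids=lnc_ids,
        mrna_ids=mrna_ids,
    )
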