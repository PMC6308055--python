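"""Probe filtering, probe-to-gene aggregation and paired differential expression.

The expression stage assumes log-scale intensities from a paired
tumor/normal design: each biological pair contributes one tumor and one
normal column. Per-gene screening uses the paired t-test on the
within-pair differences; no multiple-testing correction is applied at
this stage (the screen is a hard threshold on the raw p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
    NotFoundError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "filter_probe_hits",
    "aggregate_probes",
    "paired_t_test",
    "screen_degs",
    "validate_candidate",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-intensity matrix with explicit tumor/normal pairing.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    pairing
        List of ``(tumor_sample_id, normal_sample_id)`` column pairs.
    """

    values: pd.DataFrame
    pairing: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = set(self.values.columns)
        used: set[str] = set()
        for tumor, normal in self.pairing:
            if tumor not in cols or normal not in cols:
                raise InvalidArgumentError(
                    f"pairing references unknown sample(s): {tumor!r}/{normal!r}"
                )
            if tumor == normal or tumor in used or normal in used:
                raise InvalidArgumentError(
                    f"pairing ids must name distinct columns: {tumor!r}/{normal!r}"
                )
            used.update((tumor, normal))
        if self.values.isna().any().any():
            raise InvalidArgumentError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def paired_differences(self) -> pd.DataFrame:
        """Per-gene tumor minus normal differences, one column per pair."""
        tumor_cols = [t for t, _ in self.pairing]
        normal_cols = [n for _, n in self.pairing]
        d = self.values[tumor_cols].to_numpy() - self.values[normal_cols].to_numpy()
        return pd.DataFrame(
            d, index=self.values.index, columns=[f"pair{i}" for i in range(len(self.pairing))]
        )


def filter_probe_hits(hits: pd.DataFrame, min_probes: int = 4) -> set[str]:
    """Select transcripts that pass the probe re-annotation criteria.

    A transcript is accepted iff, after discarding (i) probes hitting
    two or more transcripts anywhere in the table and (ii) probes with
    any mismatch, at least ``min_probes`` probes remain for it. The
    default of 4 reads "detected by more than three probes" literally.

    Parameters
    ----------
    hits
        DataFrame with columns ``probe_id``, ``transcript_id``,
        ``mismatches``; (probe_id, transcript_id) rows are unique.
    min_probes
        Minimum retained probe count for acceptance (>= 1).
    """
    if min_probes < 1:
        raise InvalidArgumentError(f"min_probes must be >= 1, got {min_probes}")
    required = {"probe_id", "transcript_id", "mismatches"}
    missing = required - set(hits.columns)
    if missing:
        raise InvalidArgumentError(f"probe hit table missing columns: {sorted(missing)}")
    if hits.empty:
        return set()
    if (hits["mismatches"] < 0).any():
        raise InvalidArgumentError("mismatches must be non-negative")

    # Multi-mapping is judged on the full table, before the mismatch filter:
    # a probe hitting two transcripts is uninformative regardless of mismatches.
    targets_per_probe = hits.groupby("probe_id")["transcript_id"].nunique()
    unique_probes = set(targets_per_probe[targets_per_probe == 1].index)

    retained = hits[hits["probe_id"].isin(unique_probes) & (hits["mismatches"] == 0)]
    counts = retained.groupby("transcript_id")["probe_id"].nunique()
    return set(counts[counts >= min_probes].index)


def aggregate_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: dict[str, str],
    pairing: list[tuple[str, str]] | None = None,
) -> ExpressionMatrix:
    """Collapse a probes x samples matrix to genes x samples by the mean.

    Each gene's row is the arithmetic per-sample mean over its probes'
    rows. Mapped probes absent from the matrix are dropped; a gene left
    with no probes is excluded with a warning.
    """
    present = {p: g for p, g in probe_to_gene.items() if p in probe_matrix.index}
    dropped = set(probe_to_gene) - set(present)
    if dropped:
        logger.warning("%d mapped probes absent from the matrix; dropped", len(dropped))

    lost_genes = set(probe_to_gene.values()) - set(present.values())
    for g in sorted(lost_genes):
        logger.warning("gene %s has no probes in the matrix; excluded", g)

    if not present:
        return ExpressionMatrix(
            pd.DataFrame(columns=probe_matrix.columns, dtype=float), pairing or []
        )

    sub = probe_matrix.loc[list(present)]
    genes = pd.Series(present, name="gene").loc[sub.index]
    out = sub.groupby(genes.to_numpy()).mean()
    out.index.name = "gene_id"
    out = out.sort_index()
    return ExpressionMatrix(out, pairing or [])


def paired_t_test(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """Paired t-test of tumor vs normal; returns ``(t, two-sided p)``.

    t = mean(d) / (sd(d)/sqrt(n)) with d = tumor - normal and the
    sample (n-1) standard deviation; p from Student's t with n-1 df.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise InvalidArgumentError("tumor and normal vectors must have equal length")
    n = tumor.size
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs n >= 2 pairs, got {n}")
    d = tumor - normal
    sd = d.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def screen_degs(matrix: ExpressionMatrix, alpha: float = 0.001) -> pd.DataFrame:
    """Screen every gene with the paired t-test at threshold ``alpha``.

    Returns a DataFrame indexed by gene id with columns ``t``, ``p``,
    ``mean_diff``, ``significant`` and ``degenerate``. Significance is
    strict (p < alpha) with no multiple-testing correction. Genes whose
    paired differences have zero variance are flagged degenerate and
    reported non-significant rather than failing the screen.
    """
    if not 0.0 < alpha <= 1.0:
        raise InvalidArgumentError(f"alpha must be in (0, 1], got {alpha}")
    if not matrix.pairing:
        raise InvalidArgumentError("expression matrix has no tumor/normal pairing")
    n = matrix.n_pairs
    if n < 2:
        raise InsufficientDataError("screening needs at least 2 sample pairs")

    d = matrix.paired_differences().to_numpy()
    mean_diff = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    t[degenerate] = np.nan
    p[degenerate] = np.nan

    significant = np.where(degenerate, False, p < alpha)
    if degenerate.any():
        logger.warning("%d genes had zero-variance differences; skipped", int(degenerate.sum()))
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_diff": mean_diff,
            "significant": significant,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )


def validate_candidate(matrix: ExpressionMatrix, gene_id: str) -> tuple[int, float]:
    """Paired-test a single candidate gene in an independent cohort.

    Returns ``(direction, p)`` where direction is the sign of the mean
    paired difference (+1 up in tumor, -1 down).
    """
    if gene_id not in matrix.values.index:
        raise NotFoundError(f"gene {gene_id!r} not in expression matrix")
    tumor = matrix.values.loc[gene_id, [t for t, _ in matrix.pairing]].to_numpy()
    normal = matrix.values.loc[gene_id, [n for _, n in matrix.pairing]].to_numpy()
    t, p = paired_t_test(tumor, normal)
    direction = int(np.sign(np.mean(tumor - normal)))
    return direction, p
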