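"""Over-representation analysis (ORA) against user-supplied gene sets.

For each gene set the overlap with the query list is scored by the
upper hypergeometric tail over an explicit background universe, and
p-values are adjusted across sets by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeometric_tail
from .errors import InvalidArgumentError

__all__ = ["GeneSetCollection", "read_gmt", "ora_test"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InvalidArgumentError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InvalidArgumentError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member"
            )
        name, desc, *members = fields
        if name in sets:
            raise InvalidArgumentError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = [m for m in members if m]
        if not members:
            raise InvalidArgumentError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = frozenset(members)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def ora_test(
    gene_list: set[str],
    collection: GeneSetCollection,
    background: set[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Every set is intersected with the background before testing; the
    per-set p-value is the upper tail with T = |background|,
    M = |gene_list|, k = |set in background|, x = |set overlap with the
    query|. Returns a DataFrame sorted by FDR then set name with
    columns set_name, description, overlap, set_size, p_value, fdr,
    significant (fdr < threshold).
    """
    if not background:
        raise InvalidArgumentError("background must be non-empty")
    stray = gene_list - background
    if stray:
        raise InvalidArgumentError(
            f"{len(stray)} query genes are not in the background (e.g. {sorted(stray)[:3]})"
        )
    T, M = len(background), len(gene_list)
    rows = []
    for name in sorted(collection.sets):
        in_bg = collection.sets[name] & background
        k = len(in_bg)
        x = len(in_bg & gene_list)
        p = hypergeometric_tail(T, M, k, x)
        rows.append(
            {
                "set_name": name,
                "description": collection.descriptions.get(name, ""),
                "overlap": x,
                "set_size": k,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["fdr", "set_name"]).reset_index(drop=True)
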