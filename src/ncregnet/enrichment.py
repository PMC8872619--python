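"""Hypergeometric overrepresentation analysis over GMT gene-set collections.

Per tested set the result carries the query hit count ("Count DE"), the
set size within the background ("GO Size"), the percentage affected,
the hypergeometric upper-tail p-value and its BH-adjusted q-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from ._util import normalize_gene, round_half_away
from .de import bh_adjust
from .errors import ValidationError


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT rows); names unique, sets non-empty."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValidationError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Delegates to scipy's log-space survival function for numerical
    stability; bounds are validated first.
    """
    for name, val in (("k", k), ("K", K), ("n", n), ("N", N)):
        if val < 0:
            raise ValidationError(f"{name} must be >= 0")
    if K > N or n > N:
        raise ValidationError("K and n must not exceed N")
    if k > min(K, n):
        raise ValidationError("k must not exceed min(K, n)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pct_affected(count_de: int, go_size: int) -> float:
    """100 * count_de / go_size, one decimal, ties away from zero."""
    if go_size <= 0:
        raise ValidationError("go_size must be positive")
    if not 0 <= count_de <= go_size:
        raise ValidationError("count_de must lie in [0, go_size]")
    return round_half_away(100.0 * count_de / go_size)


def ora(
    query_genes,
    collection: GeneSetCollection,
    background,
) -> pd.DataFrame:
    """Overrepresentation of ``query_genes`` in each set of ``collection``.

    Gene identifiers are compared case-insensitively. Sets are intersected
    with the background before testing, so go_size is the in-background set
    size; the query must be a subset of the background. BH adjustment runs
    across all tested sets; rows come back sorted by q, then p, then name.
    """
    bg = {normalize_gene(g) for g in background}
    if not bg:
        raise ValidationError("background gene universe is empty")
    query = {normalize_gene(g) for g in query_genes}
    stray = query - bg
    if stray:
        raise ValidationError(
            f"query gene(s) outside the background: {sorted(stray)[:5]}")

    N, n = len(bg), len(query)
    rows = []
    for gene_set in collection:
        members = {normalize_gene(g) for g in gene_set.genes} & bg
        go_size = len(members)
        count_de = len(members & query)
        p = 1.0 if go_size == 0 else hypergeom_tail(count_de, go_size, n, N)
        rows.append({
            "set_name": gene_set.name,
            "count_de": count_de,
            "go_size": go_size,
            "pct_affected": pct_affected(count_de, go_size) if go_size else 0.0,
            "pvalue": p,
        })
    result = pd.DataFrame(
        rows, columns=["set_name", "count_de", "go_size", "pct_affected", "pvalue"])
    result["qvalue"] = bh_adjust(result["pvalue"].to_numpy()) if len(result) else []
    result = result.sort_values(
        ["qvalue", "pvalue", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return result
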