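"""Degree-centrality ranking, top-k hub selection, Jaccard similarity and
co-regulation partition statistics.

Centrality here is the out-degree over distinct DE targets: the networks
are bipartite, so degree is the only centrality in play. Hub labels follow
the >100 / <20 distinct-target split used for lncRNA reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_away, truncate_percent
from .errors import ConsistencyError, ParameterError, ValidationError
from .network import RegulatoryNetwork

HUB_DEGREE_MIN = 100   # "hub" label: degree strictly above
MINOR_DEGREE_MAX = 20  # "minor" label: degree strictly below

TIE_RULES = ("lexicographic", "keep-all-ties")


@dataclass
class RankingResult:
    """Regulators ranked by distinct-target degree (non-increasing)."""

    table: pd.DataFrame  # regulator_id, regulator_class, degree, rank, label
    tie_rule: str = "lexicographic"

    def for_class(self, regulator_class: str) -> pd.DataFrame:
        sub = self.table[self.table["regulator_class"] == regulator_class]
        return sub.reset_index(drop=True)


def _degree_label(degree: int) -> str:
    if degree > HUB_DEGREE_MIN:
        return "hub"
    if degree < MINOR_DEGREE_MAX:
        return "minor"
    return "intermediate"


def regulator_degrees(net: RegulatoryNetwork) -> RankingResult:
    """Rank every registered regulator by its count of distinct DE targets.

    Regulators with no retained edges are reported with degree 0. Ties are
    ordered lexicographically for a deterministic table; ranks are contiguous
    from 1.
    """
    counts = (
        net.edges.groupby("regulator_id")["target_gene"].nunique()
        if len(net.edges) else pd.Series(dtype=int)
    )
    rows = []
    seen = set()
    roster = pd.concat(
        [net.regulators,
         net.edges[["regulator_id", "regulator_class"]].drop_duplicates()],
        ignore_index=True,
    ).drop_duplicates()
    for _, row in roster.iterrows():
        rid = row["regulator_id"]
        if rid in seen:
            continue
        seen.add(rid)
        deg = int(counts.get(rid, 0))
        rows.append({
            "regulator_id": rid,
            "regulator_class": row["regulator_class"],
            "degree": deg,
            "label": _degree_label(deg),
        })
    table = pd.DataFrame(rows, columns=["regulator_id", "regulator_class", "degree", "label"])
    table = table.sort_values(
        ["degree", "regulator_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(3, "rank", np.arange(1, len(table) + 1))
    return RankingResult(table=table)


def top_k(
    ranking: RankingResult,
    k: int = 10,
    regulator_class: str | None = None,
    tie_rule: str = "lexicographic",
) -> list[str]:
    """The k highest-degree regulators (optionally of one class).

    ``lexicographic`` breaks boundary ties alphabetically and returns
    exactly k ids; ``keep-all-ties`` extends the list with every regulator
    tied with the k-th degree. If k exceeds the population a warning is
    emitted and the full list returned.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if tie_rule not in TIE_RULES:
        raise ParameterError(f"tie_rule must be one of {TIE_RULES}")
    table = ranking.table
    if regulator_class is not None:
        table = table[table["regulator_class"] == regulator_class]
    table = table.sort_values(
        ["degree", "regulator_id"], ascending=[False, True], kind="mergesort"
    )
    ids = table["regulator_id"].tolist()
    degrees = table["degree"].tolist()
    if k >= len(ids):
        if k > len(ids):
            warnings.warn(
                f"top_k: k={k} exceeds population {len(ids)}; returning all",
                stacklevel=2,
            )
        return ids
    if tie_rule == "lexicographic":
        return ids[:k]
    cutoff = degrees[k - 1]
    return [rid for rid, d in zip(ids, degrees) if d >= cutoff]


@dataclass
class PartitionStats:
    """Sizes and percentages of the top-k co-regulation partition.

    M = union of top miRNA targets, L = union of top lncRNA targets,
    network = M u L, shared = M n L; percentages are one-decimal
    (half-away-from-zero) shares of either the network or all DE genes.
    """

    n_de_genes: int
    m_targets: int
    l_targets: int
    shared: int
    network_targets: int = field(init=False)

    def __post_init__(self):
        self.network_targets = self.m_targets + self.l_targets - self.shared
        if self.shared > min(self.m_targets, self.l_targets):
            raise ConsistencyError("shared exceeds one of the target-set sizes")
        if self.n_de_genes < self.network_targets:
            raise ConsistencyError(
                f"n_de_genes ({self.n_de_genes}) smaller than network target count "
                f"({self.network_targets})")

    def _pct(self, num: int, den: int) -> float:
        return 0.0 if den == 0 else 100.0 * num / den

    @property
    def pct_network_of_de(self) -> float:
        return round_half_away(self._pct(self.network_targets, self.n_de_genes))

    @property
    def pct_m_of_network(self) -> float:
        return round_half_away(self._pct(self.m_targets, self.network_targets))

    @property
    def pct_m_of_de(self) -> float:
        return round_half_away(self._pct(self.m_targets, self.n_de_genes))

    @property
    def pct_l_of_network(self) -> float:
        return round_half_away(self._pct(self.l_targets, self.network_targets))

    @property
    def pct_l_of_de(self) -> float:
        return round_half_away(self._pct(self.l_targets, self.n_de_genes))

    @property
    def pct_shared_of_network(self) -> float:
        return round_half_away(self._pct(self.shared, self.network_targets))

    @property
    def pct_shared_of_de(self) -> float:
        return round_half_away(self._pct(self.shared, self.n_de_genes))

    _PCT_FIELDS = (
        "pct_network_of_de", "pct_m_of_network", "pct_m_of_de",
        "pct_l_of_network", "pct_l_of_de", "pct_shared_of_network",
        "pct_shared_of_de",
    )

    def as_dict(self, display: str = "decimal") -> dict:
        """Counts plus all seven percentages.

        ``display='integer'`` truncates each percentage to a whole percent
        (the style that prints 26 for 217/828).
        """
        if display not in ("decimal", "integer"):
            raise ParameterError("display must be 'decimal' or 'integer'")
        out = {
            "n_de_genes": self.n_de_genes,
            "m_targets": self.m_targets,
            "l_targets": self.l_targets,
            "shared": self.shared,
            "network_targets": self.network_targets,
        }
        for name in self._PCT_FIELDS:
            exact = getattr(self, name)
            if display == "integer":
                # truncate the exact share, not the rounded one
                num, den = {
                    "pct_network_of_de": (self.network_targets, self.n_de_genes),
                    "pct_m_of_network": (self.m_targets, self.network_targets),
                    "pct_m_of_de": (self.m_targets, self.n_de_genes),
                    "pct_l_of_network": (self.l_targets, self.network_targets),
                    "pct_l_of_de": (self.l_targets, self.n_de_genes),
                    "pct_shared_of_network": (self.shared, self.network_targets),
                    "pct_shared_of_de": (self.shared, self.n_de_genes),
                }[name]
                out[name] = truncate_percent(self._pct(num, den))
            else:
                out[name] = exact
        return out


def partition_stats_from_counts(
    m_targets: int, l_targets: int, shared: int, n_de_genes: int
) -> PartitionStats:
    """Partition statistics straight from the four printed counts."""
    for name, val in (("m_targets", m_targets), ("l_targets", l_targets),
                      ("shared", shared), ("n_de_genes", n_de_genes)):
        if val < 0:
            raise ParameterError(f"{name} must be >= 0")
    return PartitionStats(
        n_de_genes=n_de_genes, m_targets=m_targets, l_targets=l_targets, shared=shared
    )


def partition_stats(
    net: RegulatoryNetwork,
    top_mirnas: list[str],
    top_lncrnas: list[str],
    n_de_genes: int,
) -> PartitionStats:
    """Partition statistics over the distinct targets of the listed
    top regulators in ``net``."""
    m = net.targets_of(top_mirnas)
    l = net.targets_of(top_lncrnas)
    return partition_stats_from_counts(
        m_targets=len(m), l_targets=len(l), shared=len(m & l), n_de_genes=n_de_genes
    )


def regulator_similarity(net: RegulatoryNetwork) -> pd.DataFrame:
    """Pairwise Jaccard similarity of regulator target sets.

    Diagonal is 1; a regulator with zero targets gets similarity 0 against
    every other regulator (and is flagged with a warning).
    """
    ranking = regulator_degrees(net)
    ids = ranking.table["regulator_id"].tolist()
    if len(ids) < 2:
        raise ValidationError("similarity requires at least two regulators")
    target_sets = {
        rid: set(net.edges.loc[net.edges["regulator_id"] == rid, "target_gene"])
        for rid in ids
    }
    empty = [rid for rid, ts in target_sets.items() if not ts]
    if empty:
        warnings.warn(
            f"regulator_similarity: zero-target regulator(s) {empty}; "
            "similarities reported as 0", stacklevel=2)
    ids = sorted(ids)
    mat = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                mat[i, j] = 1.0
                continue
            sa, sb = target_sets[a], target_sets[b]
            union = sa | sb
            mat[i, j] = len(sa & sb) / len(union) if union else 0.0
    return pd.DataFrame(mat, index=ids, columns=ids)
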