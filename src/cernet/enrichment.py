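"""Over-representation analysis (ORA) of DE mRNA sets against gene-set files.

The statistic is the hypergeometric upper tail: with a universe of N
genes of which K belong to a term, and a DE set of n genes of which k
fall in the term, p = P(X >= k) for X ~ Hypergeom(N, K, n). The universe
is the set of genes present in both the expression data and the
annotation, per standard ORA practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError

CATEGORIES = ("BP", "CC", "MF", "pathway")

ORA_COLUMNS = ["term", "category", "k", "K", "n", "N", "p", "q"]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GO terms / pathways)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.term_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate term ids in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(de_set, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """One enrichment record per term intersecting the universe.

    Sorted by p ascending, ties broken by term id; q is the BH adjustment
    over the tested terms.
    """
    de_set = set(de_set)
    universe = set(universe)
    if not de_set <= universe:
        raise ValidationError("DE set contains genes outside the universe")
    N, n = len(universe), len(de_set)

    rows = []
    for gs in collection:
        members = gs.genes & universe
        if not members:
            continue
        K = len(members)
        k = len(members & de_set)
        rows.append((gs.term_id, gs.category, k, K, n, N, hypergeometric_tail(k, K, n, N)))

    out = pd.DataFrame(rows, columns=ORA_COLUMNS[:-1])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def top_terms(records: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """First n records of an ORA table (already p-sorted)."""
    return records.head(n).reset_index(drop=True)
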