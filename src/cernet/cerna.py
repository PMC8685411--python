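"""ceRNA triplet assembly and tripartite network construction.

A ceRNA triplet is (sponge, miRNA, mRNA) where the sponge is a lncRNA or
circRNA sharing a miRNA with the mRNA: the triplet is emitted iff both
sponge and mRNA pass DE calling and the expression filters, the pair is
positively coexpressed above threshold, and the target map contains both
miRNA->sponge and miRNA->mRNA edges. miRNA DE status is not required by
default — miRNAs absent from DE results carry direction "unknown" — but a
strict mode restricts to DE miRNAs moving opposite to their sponge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .diffexpr import DIRECTION_DOWN, DIRECTION_UP
from .errors import ValidationError
from .matrix import GROUP_A, GROUP_H, ExpressionMatrix

DIRECTION_UNKNOWN = "unknown"
SPONGE_CLASSES = ("lncRNA", "circRNA")

TRIPLET_COLUMNS = [
    "sponge", "sponge_class", "mirna", "mrna",
    "r", "p", "sponge_direction", "mrna_direction", "mirna_direction",
]


@dataclass
class FilterConfig:
    """Expression-level screening applied before triplet assembly.

    A feature is kept when the mean normalized expression of at least one
    group exceeds ``min_group_mean`` AND the fraction of samples in which
    it is expressed (value > ``expressed_threshold``) is at least
    ``min_expressed_fraction`` of all samples. ``fc_up``/``fc_down`` are
    the fold-change bounds equivalent to |log2FC| >= 1.
    """

    min_group_mean: float = 0.5
    min_expressed_fraction: float = 2.0 / 3.0
    expressed_threshold: float = 0.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    p_threshold: float = 0.05
    strict_mirna_de: bool = False

    def __post_init__(self):
        if not 0 < self.min_expressed_fraction <= 1:
            raise ValidationError("min_expressed_fraction must lie in (0, 1]")


@dataclass
class TargetMap:
    """miRNA->target interaction edges with target class annotation."""

    edges: pd.DataFrame  # columns: mirna, target, target_class

    def __post_init__(self):
        required = ["mirna", "target", "target_class"]
        if list(self.edges.columns) != required:
            self.edges = self.edges[required]
        bad = set(self.edges["target_class"]) - {"mRNA", "lncRNA", "circRNA"}
        if bad:
            raise ValidationError(f"invalid target classes: {sorted(bad)}")
        if self.edges.duplicated().any():
            raise ValidationError("duplicate target-map edges")

    def __len__(self) -> int:
        return len(self.edges)

    def mirnas_targeting(self, target: str) -> set[str]:
        return set(self.edges.loc[self.edges["target"] == target, "mirna"])


def expression_filter(matrix: ExpressionMatrix, config: FilterConfig | None = None) -> set[str]:
    """Feature ids passing the group-mean and expressed-fraction screens."""
    config = config or FilterConfig()
    if matrix.values.empty:
        return set()
    means = matrix.group_means()
    mean_ok = (means[GROUP_A] > config.min_group_mean) | (means[GROUP_H] > config.min_group_mean)
    expressed = (matrix.values > config.expressed_threshold).sum(axis=1)
    frac_ok = expressed / matrix.n_samples >= config.min_expressed_fraction
    return set(matrix.features[mean_ok & frac_ok])


def find_triplets(
    de_tables: dict[str, pd.DataFrame],
    pairs: pd.DataFrame,
    targets: TargetMap,
    filters: FilterConfig | None = None,
    matrices: dict[str, ExpressionMatrix] | None = None,
) -> pd.DataFrame:
    """Assemble ceRNA triplets from coexpression pairs and a target map.

    ``de_tables`` maps RNA class to its DE table; ``pairs`` is the output
    of :func:`cernet.coexpr.coexpression_pairs` (possibly concatenated
    over sponge classes); ``matrices`` supplies the expression filter
    inputs (when omitted, the expression filter is skipped and DE status
    alone gates membership). Rows are ordered (miRNA, sponge, mRNA)
    lexicographically.
    """
    filters = filters or FilterConfig()

    kept: dict[str, set[str]] = {}
    for cls, table in de_tables.items():
        ids = set(table.loc[table["passes"], "feature"])
        if matrices is not None and cls in matrices:
            ids &= expression_filter(matrices[cls], filters)
        kept[cls] = ids

    direction = {
        cls: table.set_index("feature")["direction"].to_dict()
        for cls, table in de_tables.items()
    }
    mirna_dir = direction.get("miRNA", {})

    # index target edges by target id once
    by_target: dict[str, set[str]] = {}
    for mirna, target in zip(targets.edges["mirna"], targets.edges["target"]):
        by_target.setdefault(target, set()).add(mirna)

    rows = []
    for row in pairs.itertuples(index=False):
        if row.r <= 0:
            continue
        sponge, cls, mrna = row.ncrna, row.ncrna_class, row.mrna
        if cls not in SPONGE_CLASSES:
            continue
        if sponge not in kept.get(cls, set()) or mrna not in kept.get("mRNA", set()):
            continue
        shared = by_target.get(sponge, set()) & by_target.get(mrna, set())
        s_dir = direction[cls].get(sponge, DIRECTION_UNKNOWN)
        for mirna in sorted(shared):
            m_dir = mirna_dir.get(mirna, DIRECTION_UNKNOWN)
            if m_dir not in (DIRECTION_UP, DIRECTION_DOWN):
                m_dir = DIRECTION_UNKNOWN
            if filters.strict_mirna_de:
                opposite = {DIRECTION_UP: DIRECTION_DOWN, DIRECTION_DOWN: DIRECTION_UP}
                if m_dir != opposite.get(s_dir):
                    continue
            rows.append(
                (sponge, cls, mirna, mrna, row.r, row.p,
                 s_dir, direction["mRNA"].get(mrna, DIRECTION_UNKNOWN), m_dir)
            )

    out = pd.DataFrame(rows, columns=TRIPLET_COLUMNS)
    return out.sort_values(["mirna", "sponge", "mrna"], kind="mergesort").reset_index(drop=True)


@dataclass
class CeRNANetwork:
    """Tripartite graph induced by a triplet table.

    Nodes carry ``kind`` (mRNA/lncRNA/circRNA/miRNA) and ``direction``
    attributes; edges carry ``interaction`` in {mirna-sponge, mirna-mrna,
    coexpression}.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    n_triplets: int = 0

    @property
    def summary(self) -> dict:
        kinds = nx.get_node_attributes(self.graph, "kind")
        counts = {k: 0 for k in ("lncRNA", "circRNA", "miRNA", "mRNA")}
        for kind in kinds.values():
            counts[kind] += 1
        return {
            "n_triplets": self.n_triplets,
            "n_sponges": counts["lncRNA"] + counts["circRNA"],
            "n_lncRNAs": counts["lncRNA"],
            "n_circRNAs": counts["circRNA"],
            "n_miRNAs": counts["miRNA"],
            "n_mRNAs": counts["mRNA"],
            "n_edges": self.graph.number_of_edges(),
        }


def build_network(triplets: pd.DataFrame) -> CeRNANetwork:
    """Union graph of all triplet edges with deduplicated nodes."""
    g = nx.Graph()
    for t in triplets.itertuples(index=False):
        g.add_node(t.sponge, kind=t.sponge_class, direction=t.sponge_direction)
        g.add_node(t.mirna, kind="miRNA", direction=t.mirna_direction)
        g.add_node(t.mrna, kind="mRNA", direction=t.mrna_direction)
        g.add_edge(t.mirna, t.sponge, interaction="mirna-sponge")
        g.add_edge(t.mirna, t.mrna, interaction="mirna-mrna")
        g.add_edge(t.sponge, t.mrna, interaction="coexpression")
    return CeRNANetwork(graph=g, n_triplets=int(len(triplets)))


def whitelist_filter(triplets: pd.DataFrame, mrna_whitelist) -> pd.DataFrame:
    """Restrict a triplet table to a set of key mRNAs."""
    keep = set(mrna_whitelist)
    return triplets[triplets["mrna"].isin(keep)].reset_index(drop=True)
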