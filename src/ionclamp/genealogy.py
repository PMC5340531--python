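"""Ancestor-descendant relations between channel models.

Channel models cite and adapt earlier models; the directed graph of these
relations partitions a corpus into *families* (connected components of the
undirected skeleton).  Cross-tabulating families, annotated subtypes and
kinetic clusters shows how provenance relates to behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["GenealogyGraph", "families", "crosstab"]


def _norm(label: str) -> str:
    return str(label).strip().lower()


@dataclass
class GenealogyGraph:
    """Directed ancestor -> descendant graph with free-text node metadata."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) references an unknown node")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node, meta in self.nodes.items():
            g.add_node(node, **meta)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, edges: pd.DataFrame) -> "GenealogyGraph":
        """Build from CSV-style tables: nodes need an ``id`` column, edges
        ``ancestor``/``descendant`` columns; remaining node columns become
        metadata."""
        node_map = {
            str(row["id"]): {k: row[k] for k in nodes.columns if k != "id"}
            for _, row in nodes.iterrows()
        }
        edge_list = [(str(r["ancestor"]), str(r["descendant"])) for _, r in edges.iterrows()]
        return cls(nodes=node_map, edges=edge_list)


def families(graph: GenealogyGraph) -> dict[str, int]:
    """Family id per channel: connected components of the undirected skeleton.

    Ids are assigned by decreasing family size, ties broken by the
    lexicographically smallest member.
    """
    g = graph.to_networkx().to_undirected()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    return {node: fam for fam, comp in enumerate(comps) for node in comp}


def crosstab(labels_a: dict[str, object], labels_b: dict[str, object]) -> pd.DataFrame:
    """Contingency table of two partitions over the same channel ids.

    Free-text labels are matched exactly after lowercasing and trimming.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("partitions do not cover the same set of channel ids")
    ids = sorted(labels_a)

    def norm(v):
        return _norm(v) if isinstance(v, str) else v

    a = pd.Series([norm(labels_a[i]) for i in ids], name="a")
    b = pd.Series([norm(labels_b[i]) for i in ids], name="b")
    return pd.crosstab(a, b)
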