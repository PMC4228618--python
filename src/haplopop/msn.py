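"""Minimum spanning networks over unique multilocus genotypes.

A minimum spanning network (MSN) is the union of all minimum spanning trees
of the weighted complete graph on unique genotypes: edges are processed in
ascending weight, and within each weight class an edge is kept iff its
endpoints lay in different components *as they stood at the start of that
class*; components merge only once the whole class is processed. Loops in
the network appear exactly where alternative equal-cost connections exist —
the signature of homoplasy and recombination.

Inferred intermediate haplotypes are not synthesized; an edge simply carries
its genotype distance as the weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .genotypic import GenotypeCensus

__all__ = ["GenotypeNetwork", "build_msn", "export_network"]


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass(frozen=True)
class GenotypeNetwork:
    """Union-of-all-MSTs network over unique genotypes."""

    graph: nx.Graph              # nodes = genotype IDs; edge attrs weight, in_all_msts

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mst_weight(self) -> float:
        t = nx.minimum_spanning_tree(self.graph, weight="weight")
        return float(sum(d["weight"] for _, _, d in t.edges(data=True)))

    def edge_list(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "weight": d["weight"],
                 "in_all_msts": d["in_all_msts"]}
                for u, v, d in self.graph.edges(data=True)]
        rows.sort(key=lambda r: (r["weight"], str(r["source"]), str(r["target"])))
        return pd.DataFrame(rows, columns=["source", "target", "weight", "in_all_msts"])


def build_msn(dist: np.ndarray, node_ids=None,
              node_attrs: dict | None = None) -> GenotypeNetwork:
    """Build the union-of-all-MSTs network from a genotype distance matrix.

    Parameters
    ----------
    dist : (k, k) symmetric array
        Distances between the k unique genotypes.
    node_ids : sequence, optional
        Node labels (default ``MLG1..MLGk``), sorted lexicographically in the
        output for deterministic files.
    node_attrs : dict, optional
        Per-node attribute dicts (e.g. member individuals, strata colors).
    """
    d = np.asarray(dist, dtype=float)
    k = d.shape[0]
    if node_ids is None:
        node_ids = [f"MLG{i + 1}" for i in range(k)]
    node_ids = [str(x) for x in node_ids]
    G = nx.Graph()
    for nid in sorted(node_ids):
        G.add_node(nid, **(node_attrs.get(nid, {}) if node_attrs else {}))
    if k < 2:
        return GenotypeNetwork(G)

    iu, ju = np.triu_indices(k, 1)
    order = np.lexsort((ju, iu, d[iu, ju]))
    edges = [(d[iu[e], ju[e]], int(iu[e]), int(ju[e])) for e in order]

    dsu = _DSU(k)
    kept: list[tuple[int, int, float]] = []
    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        cls = []
        while pos < len(edges) and edges[pos][0] == w:
            cls.append(edges[pos])
            pos += 1
        # keep an edge iff it spans two components as of the class start
        snapshot = {i: dsu.find(i) for i in range(k)}
        kept_class = [(a, b) for _, a, b in cls if snapshot[a] != snapshot[b]]
        for a, b in kept_class:
            kept.append((a, b, w))
            dsu.union(a, b)
        # flag edges present in every MST: within the class, contract the
        # class-start components and keep bridges of the kept-edge multigraph
        comp_graph = nx.MultiGraph()
        comp_graph.add_nodes_from(set(snapshot.values()))
        for a, b in kept_class:
            comp_graph.add_edge(snapshot[a], snapshot[b], ends=(a, b))
        forced = set()
        simple = nx.Graph()
        simple.add_nodes_from(comp_graph.nodes)
        parallel = set()
        for u_, v_ in comp_graph.edges():
            if simple.has_edge(u_, v_):
                parallel.add(frozenset((u_, v_)))
            else:
                simple.add_edge(u_, v_)
        bridges = set(frozenset(e) for e in nx.bridges(simple)) if simple.number_of_edges() else set()
        for u_, v_, data in comp_graph.edges(data=True):
            key = frozenset((u_, v_))
            if key in bridges and key not in parallel:
                forced.add(data["ends"])
        for a, b, w_ in kept[-len(kept_class):] if kept_class else []:
            G.add_edge(node_ids[a], node_ids[b], weight=w_,
                       in_all_msts=(a, b) in forced)
    return GenotypeNetwork(G)


def network_from_census(c: GenotypeCensus, dist: np.ndarray,
                        rep_index: np.ndarray | None = None,
                        strata_frame: pd.DataFrame | None = None
                        ) -> GenotypeNetwork:
    """MSN over a census, attaching member individuals and strata as attrs.

    ``dist`` is the distance matrix between the census genotypes in
    iteration order of ``c.counts``.
    """
    keys = list(c.counts)
    node_ids = [f"MLG{i + 1}" for i in range(len(keys))]
    attrs = {}
    for nid, key in zip(node_ids, keys):
        members = list(c.members.get(key, ()))
        a: dict = {"size": c.counts[key], "members": ";".join(members)}
        if strata_frame is not None and members:
            first = strata_frame.loc[members[0]]
            for col in strata_frame.columns:
                a[col] = str(first[col])
        attrs[nid] = a
    return build_msn(dist, node_ids=node_ids, node_attrs=attrs)


_FORMATS = ("graphml", "dot", "tsv")


def export_network(net: GenotypeNetwork, path: str | Path,
                   format: str = "graphml") -> None:
    """Write the network as GraphML, DOT or a TSV edge list."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "dot":
        lines = ["graph msn {"]
        for nid, data in sorted(net.graph.nodes(data=True)):
            attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(data.items()))
            lines.append(f'  "{nid}" [{attrs}];' if attrs else f'  "{nid}";')
        df = net.edge_list()
        for _, r in df.iterrows():
            lines.append(f'  "{r.source}" -- "{r.target}" [weight={r.weight:g}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "tsv":
        net.edge_list().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}; supported: {_FORMATS}")
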