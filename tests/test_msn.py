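import numpy as np
import networkx as nx
import pytest

from haplopop import build_msn, export_network
from haplopop.msn import network_from_census
from haplopop.genotypic import census
from haplopop.amova import distance_matrix
from oracles import union_of_all_msts


def test_triangle_of_ties_keeps_all_three_edges():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    net = build_msn(d)
    assert net.n_edges == 3                        # loop from the full tie class
    assert all(not e["in_all_msts"]
               for _, _, e in net.graph.edges(data=True))


def test_strict_chain_is_a_unique_mst():
    d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    net = build_msn(d)
    assert net.n_edges == 2                        # path, no loop
    assert all(e["in_all_msts"] for _, _, e in net.graph.edges(data=True))


def test_single_node_network():
    net = build_msn(np.zeros((1, 1)), node_ids=["only"])
    assert net.n_nodes == 1 and net.n_edges == 0


@pytest.mark.parametrize("n,high,seed", [
    (5, 3, 0), (6, 3, 1), (6, 4, 2), (7, 4, 3), (8, 9, 4), (8, 9, 5),
])
def test_edge_set_equals_union_of_all_msts(n, high, seed):
    rng = np.random.default_rng(seed)
    d = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    w = rng.integers(1, high + 1, size=iu.size).astype(float)
    d[iu, ju] = w
    d[ju, iu] = w
    ids = [f"MLG{i + 1}" for i in range(n)]
    net = build_msn(d, node_ids=ids)
    got = {frozenset((ids.index(u), ids.index(v))) for u, v in net.graph.edges}
    assert got == union_of_all_msts(d)


def test_network_invariants(survey):
    matrix, strata = survey
    complete = matrix.subset_individuals(
        [i for i, row in zip(matrix.individuals, matrix.missing_mask)
         if not row.any()])
    c = census(complete)
    reps = [m[0] for m in c.members.values()]
    net = network_from_census(c, distance_matrix(complete.subset_individuals(reps)),
                              strata_frame=strata.frame)
    g = net.graph
    assert nx.is_connected(g)
    assert net.n_edges >= net.n_nodes - 1
    # every spanning tree inside the network has the global MST weight
    t = nx.minimum_spanning_tree(g, weight="weight")
    assert sum(d["weight"] for _, _, d in t.edges(data=True)) == net.mst_weight
    # removing any non-bridge edge keeps the network connected
    bridges = set(map(frozenset, nx.bridges(g)))
    non_bridge = [e for e in g.edges if frozenset(e) not in bridges]
    for u, v in non_bridge[:10]:
        h = g.copy()
        h.remove_edge(u, v)
        assert nx.is_connected(h)


def test_forced_edges_are_in_every_mst():
    rng = np.random.default_rng(7)
    n = 6
    d = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    w = rng.integers(1, 4, size=iu.size).astype(float)
    d[iu, ju] = w
    d[ju, iu] = w
    ids = [f"MLG{i + 1}" for i in range(n)]
    net = build_msn(d, node_ids=ids)
    union = union_of_all_msts(d)
    # recompute "in all MSTs" by explicit enumeration
    G = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            G.add_edge(i, j, weight=d[i, j])
    msts = []
    min_w = None
    for tree in nx.SpanningTreeIterator(G, weight="weight", minimum=True):
        tw = sum(dd["weight"] for _, _, dd in tree.edges(data=True))
        if min_w is None:
            min_w = tw
        if tw > min_w + 1e-9:
            break
        msts.append({frozenset(e) for e in tree.edges()})
    in_all = set.intersection(*msts)
    for u, v, data in net.graph.edges(data=True):
        e = frozenset((ids.index(u), ids.index(v)))
        assert data["in_all_msts"] == (e in in_all)


def test_export_formats(tmp_path):
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    net = build_msn(d, node_attrs={"MLG1": {"tree": "3"}})
    gml = tmp_path / "net.graphml"
    export_network(net, gml, "graphml")
    back = nx.read_graphml(gml)
    assert back.number_of_nodes() == 3 and back.number_of_edges() == 3
    dot = tmp_path / "net.dot"
    export_network(net, dot, "dot")
    text = dot.read_text()
    assert text.startswith("graph msn {") and '"MLG1" -- "MLG2"' in text
    tsv = tmp_path / "net.tsv"
    export_network(net, tsv, "tsv")
    assert len(tsv.read_text().strip().splitlines()) == 4   # header + 3 edges
    with pytest.raises(ValueError, match="graphml"):
        export_network(net, tmp_path / "x.bin", "gexf")


def test_survey_scale_node_count(tmp_path, survey):
    matrix, _ = survey
    c = census(matrix)
    reps = [m[0] for m in c.members.values()]
    net = network_from_census(c, distance_matrix(matrix.subset_individuals(reps)))
    export_network(net, tmp_path / "big.graphml")
    assert nx.read_graphml(tmp_path / "big.graphml").number_of_nodes() == c.n_genotypes
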