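"""Median-joining haplotype networks (Bandelt-Forster-Rohl style).

The network is grown from the minimum spanning network (MSN) over the distinct
observed haplotype sequences: the MSN keeps every edge that belongs to at
least one minimum spanning tree, relaxed by an integer ``epsilon`` (an edge is
kept when its Hamming weight is at most the minimax path weight between its
endpoints plus epsilon).  Median vectors — per-site majority consensus of
connected node triplets — are then added as inferred intermediate haplotypes
until no new medians arise, and inferred nodes of degree < 3 are pruned as
obsolete.  Determinism contract: nodes are kept in lexicographic sequence
order, triplets are enumerated in that order, and candidate medians are
inserted in sorted order, so reruns are bit-identical.

Connected components after dropping edges heavier than a maximum edge
distance (default two SNPs) give a haplotype grouping comparable to
hierarchical clustering; ``concordance`` scores that correspondence as the
fraction of haplotypes whose component's plurality cluster label matches
their own cluster label.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .hapcluster import ClusterAssignment
from .hapio import ValidationError

logger = logging.getLogger("hapsignal")

Seq = tuple[int, ...]


def _as_sequences(haplotypes) -> list[Seq]:
    arr = np.asarray(haplotypes)
    if arr.ndim != 2:
        raise ValidationError("haplotypes must form a 2-D (n_hap, n_sites) array")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValidationError("haplotype sequences must be binary (0/1 sites)")
    return [tuple(int(x) for x in row) for row in arr]


def _hamming(a: Seq, b: Seq) -> int:
    return sum(x != y for x, y in zip(a, b))


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _msn_edges(seqs: list[Seq], epsilon: int) -> list[tuple[int, int, int]]:
    """Edges (i, j, weight) of the epsilon-relaxed minimum spanning network."""
    n = len(seqs)
    dist = np.zeros((n, n), dtype=np.int64)
    arr = np.asarray(seqs, dtype=np.int8)
    for i in range(n):
        dist[i] = np.abs(arr - arr[i]).sum(axis=1)
    # One MST via Kruskal (deterministic edge order), then minimax path
    # weights: the largest edge on the unique MST path between two nodes
    # equals the graph minimax, and an edge is in some MST iff its weight
    # equals that minimax.
    edges = sorted(
        ((int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n))
    )
    dsu = _DSU(n)
    mst = nx.Graph()
    mst.add_nodes_from(range(n))
    for w, i, j in edges:
        if dsu.union(i, j):
            mst.add_edge(i, j, weight=w)
    minimax = np.zeros((n, n), dtype=np.int64)
    for src in range(n):
        # DFS over the tree accumulating the max edge weight along the path
        stack = [(src, -1, 0)]
        while stack:
            node, parent, best = stack.pop()
            minimax[src, node] = best
            for nb in mst.neighbors(node):
                if nb != parent:
                    stack.append(
                        (nb, node, max(best, mst.edges[node, nb]["weight"]))
                    )
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= minimax[i, j] + epsilon:
                out.append((i, j, int(dist[i, j])))
    return out


def minimum_spanning_network(haplotypes, epsilon: int = 0) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over haplotype sequences.

    Duplicate sequences collapse into one node with summed multiplicity.
    Nodes are the sequences themselves (tuples); edges carry Hamming weights.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be a non-negative integer")
    seqs_all = _as_sequences(haplotypes)
    if len(set(seqs_all)) < 2:
        raise ValidationError("need at least two distinct sequences")
    mult = Counter(seqs_all)
    seqs = sorted(mult)
    g = nx.Graph()
    for s in seqs:
        g.add_node(s, multiplicity=mult[s])
    for i, j, w in _msn_edges(seqs, epsilon):
        g.add_edge(seqs[i], seqs[j], weight=w)
    return g


@dataclass
class MJNetwork:
    """Median-joining network over observed plus inferred haplotypes."""

    graph: nx.Graph                # nodes are int ids with seq/kind/... attrs
    hap_nodes: np.ndarray          # input haplotype index -> node id
    epsilon: int

    @property
    def observed_nodes(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def median_nodes(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def node_sequence(self, node: int) -> Seq:
        return self.graph.nodes[node]["seq"]


def _median_of(u: Seq, v: Seq, w: Seq) -> Seq:
    return tuple(1 if (a + b + c) >= 2 else 0 for a, b, c in zip(u, v, w))


def _network_cost(seqs: list[Seq]) -> int:
    """Total weight of a minimum spanning tree over the node set."""
    n = len(seqs)
    arr = np.asarray(seqs, dtype=np.int8)
    edges = sorted(
        (int(np.abs(arr[i] - arr[j]).sum()), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    dsu = _DSU(n)
    total = 0
    for w, i, j in edges:
        if dsu.union(i, j):
            total += w
    return total


def median_join(
    haplotypes,
    epsilon: int = 0,
    populations=None,
    max_iter: int = 30,
    max_medians: int = 2000,
) -> MJNetwork:
    """Median-joining network over binary haplotypes.

    ``haplotypes`` is an (n_hap, n_sites) binary array (duplicates allowed —
    they collapse into one observed node with summed multiplicity).
    ``populations``, when given, is one label per input haplotype and is
    aggregated into per-node population counts.
    """
    seqs_all = _as_sequences(haplotypes)
    if len(set(seqs_all)) < 2:
        raise ValidationError("need at least two distinct sequences")
    if populations is not None and len(populations) != len(seqs_all):
        raise ValidationError("populations must align with haplotypes")

    observed = sorted(set(seqs_all))
    nodes: list[Seq] = list(observed)
    observed_set = set(observed)

    prev_cost = _network_cost(nodes)
    for _ in range(max_iter):
        idx_edges = _msn_edges(nodes, epsilon)
        adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
        for i, j, _w in idx_edges:
            adj[i].append(j)
            adj[j].append(i)
        candidates: set[Seq] = set()
        node_set = set(nodes)
        # every triplet with >= 2 MSN edges appears as (neighbour, v, neighbour)
        for v in range(len(nodes)):
            nbrs = sorted(adj[v])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    m = _median_of(nodes[nbrs[a]], nodes[v], nodes[nbrs[b]])
                    if m not in node_set:
                        candidates.add(m)
        if not candidates:
            break
        # BFR acceptance: a median enters only if it does not increase the
        # cost of spanning the network (greedy, in sorted order for
        # determinism).  Candidates that fail now may re-qualify later.
        accepted = 0
        for m in sorted(candidates):
            if len(nodes) - len(observed) >= max_medians:
                logger.warning("median_join: median cap reached; stopping early")
                break
            trial = sorted(nodes + [m])
            cost = _network_cost(trial)
            if cost <= prev_cost:
                nodes = trial
                prev_cost = cost
                accepted += 1
        if accepted == 0:
            break

    # prune obsolete medians: inferred nodes of degree < 3 in the current MSN
    while True:
        idx_edges = _msn_edges(nodes, epsilon)
        degree = Counter()
        for i, j, _w in idx_edges:
            degree[i] += 1
            degree[j] += 1
        drop = {
            i
            for i, s in enumerate(nodes)
            if s not in observed_set and degree[i] < 3
        }
        if not drop:
            break
        nodes = [s for i, s in enumerate(nodes) if i not in drop]

    mult = Counter(seqs_all)
    pops_of: dict[Seq, Counter] = {s: Counter() for s in observed}
    if populations is not None:
        for s, p in zip(seqs_all, populations):
            pops_of[s][str(p)] += 1

    graph = nx.Graph()
    for i, s in enumerate(nodes):
        obs = s in observed_set
        graph.add_node(
            i,
            seq=s,
            kind="observed" if obs else "median",
            multiplicity=mult[s] if obs else 0,
            populations=dict(sorted(pops_of[s].items())) if obs else {},
        )
    for i, j, w in _msn_edges(nodes, epsilon):
        graph.add_edge(i, j, weight=w)

    node_of = {s: i for i, s in enumerate(nodes)}
    hap_nodes = np.array([node_of[s] for s in seqs_all], dtype=np.int64)
    return MJNetwork(graph=graph, hap_nodes=hap_nodes, epsilon=epsilon)


@dataclass
class ComponentClustering:
    """Haplotype grouping by network components under an edge-weight filter."""

    node_component: dict[int, int]
    hap_component: np.ndarray      # input haplotype index -> component id
    max_edge: int


def components_by_edge_filter(net: MJNetwork, max_edge: int = 2) -> ComponentClustering:
    """Connected components after dropping edges heavier than ``max_edge``.

    Singleton nodes form their own components.  Component ids are assigned in
    order of each component's smallest node id (deterministic).
    """
    if max_edge < 1:
        raise ValidationError("max_edge must be at least 1")
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["weight"] <= max_edge:
            g.add_edge(u, v)
    comps = sorted(nx.connected_components(g), key=min)
    node_component = {}
    for cid, comp in enumerate(comps):
        for node in comp:
            node_component[node] = cid
    hap_component = np.array(
        [node_component[n] for n in net.hap_nodes], dtype=np.int64
    )
    return ComponentClustering(
        node_component=node_component, hap_component=hap_component, max_edge=max_edge
    )


def concordance(
    components: ComponentClustering,
    clusters: ClusterAssignment,
    matching: str = "plurality",
) -> float:
    """Fraction of haplotypes whose component maps to their cluster label.

    With ``matching="plurality"`` each component adopts the cluster label held
    by the plurality of its haplotypes (ties broken towards the label whose
    overall cluster is larger, then lexicographically).  With
    ``matching="one_to_one"`` components and labels are matched by an optimal
    one-to-one assignment instead.
    """
    if len(components.hap_component) != clusters.n_haplotypes:
        raise ValidationError(
            "components and clusters must cover the same haplotypes"
        )
    labels = np.asarray(clusters.labels)
    comp = components.hap_component
    total_sizes = Counter(labels.tolist())

    if matching == "plurality":
        matched = 0
        for cid in np.unique(comp):
            members = comp == cid
            counts = Counter(labels[members].tolist())
            best = sorted(
                counts.items(), key=lambda kv: (-kv[1], -total_sizes[kv[0]], kv[0])
            )[0][0]
            matched += counts[best]
        return matched / len(labels)
    if matching == "one_to_one":
        from scipy.optimize import linear_sum_assignment

        comp_ids = list(np.unique(comp))
        label_ids = sorted(set(labels.tolist()))
        gain = np.zeros((len(comp_ids), len(label_ids)))
        for a, cid in enumerate(comp_ids):
            counts = Counter(labels[comp == cid].tolist())
            for b, lab in enumerate(label_ids):
                gain[a, b] = counts.get(lab, 0)
        rows, cols = linear_sum_assignment(-gain)
        return float(gain[rows, cols].sum() / len(labels))
    raise ValidationError(f"unknown matching mode {matching!r}")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_graphml(net: MJNetwork, path) -> None:
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(
            n,
            seq="".join(str(x) for x in d["seq"]),
            kind=d["kind"],
            multiplicity=int(d["multiplicity"]),
            populations=",".join(f"{k}:{v}" for k, v in d["populations"].items()),
        )
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, weight=int(d["weight"]))
    nx.write_graphml(g, str(path))


def write_dot(net: MJNetwork, path) -> None:
    # hand-rolled writer: the networkx DOT exporters need pydot/pygraphviz
    with open(path, "w") as fh:
        fh.write("graph mjn {\n")
        for n, d in sorted(net.graph.nodes(data=True)):
            seq = "".join(str(x) for x in d["seq"])
            shape = "circle" if d["kind"] == "observed" else "point"
            fh.write(
                f'  n{n} [label="{seq} (x{d["multiplicity"]})", shape={shape}];\n'
            )
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f'  n{u} -- n{v} [label="{d["weight"]}"];\n')
        fh.write("}\n")


__all__ = [
    "MJNetwork",
    "ComponentClustering",
    "minimum_spanning_network",
    "median_join",
    "components_by_edge_filter",
    "concordance",
    "write_graphml",
    "write_dot",
]
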