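"""Median-joining haplotype networks with maximum-parsimony cleanup.

The classic construction for intraspecific haplotype data: repeatedly build
an epsilon-relaxed minimum-spanning network over the current node set, add
quasi-median (consensus) vectors of linked triples that shorten the network,
and stop at a fixed point.  A final parsimony step removes median vectors not
lying on any shortest connection between observed haplotypes, so surviving
inferred nodes are true branch points (degree >= 3).

Epsilon relaxes which links are admissible: a pair is linked when its
distance is within epsilon of the bottleneck (minimax-path) distance between
the two nodes, so epsilon = 0 yields exactly the minimum-spanning network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datamodel import HaplotypeTable

__all__ = ["HaplotypeNetwork", "hamming_matrix", "median_joining", "mp_cleanup"]

MAX_MEDIANS = 200


@dataclass
class HaplotypeNetwork:
    """Observed haplotypes plus inferred medians, linked by mutation steps."""

    graph: nx.Graph  # nodes: sequence strings; edge attr 'weight' = steps
    observed: list[str]
    frequencies: dict[str, int]
    epsilon: int
    medians: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def spanning_length(self) -> float:
        """Weight of a minimum spanning tree over the final node set."""
        return float(
            sum(
                d["weight"]
                for _, _, d in nx.minimum_spanning_edges(self.graph, data=True)
            )
        )

    def export_edgelist(self) -> list[tuple[str, str, int]]:
        return [
            (u, v, int(d["weight"])) for u, v, d in self.graph.edges(data=True)
        ]


def hamming_matrix(seqs: list[str] | HaplotypeTable) -> np.ndarray:
    """Symmetric integer matrix of pairwise site differences."""
    if isinstance(seqs, HaplotypeTable):
        seqs = seqs.haplotypes
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i] = (arr != arr[i]).sum(axis=1)
    return d


def _bottleneck_distances(d: np.ndarray) -> np.ndarray:
    """Minimax path distance between all pairs (max edge on the MST path)."""
    n = d.shape[0]
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(d[i, j]))
    mst = nx.minimum_spanning_tree(g)
    bn = np.zeros((n, n))
    for i in range(n):
        # DFS over MST tracking the max edge seen
        stack = [(i, -1, 0.0)]
        while stack:
            u, parent, mx = stack.pop()
            bn[i, u] = mx
            for v in mst.neighbors(u):
                if v != parent:
                    stack.append((v, u, max(mx, mst[u][v]["weight"])))
    return bn


def _msn_edges(d: np.ndarray, epsilon: int) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum-spanning network."""
    bn = _bottleneck_distances(d)
    n = d.shape[0]
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= bn[i, j] + epsilon
    ]


def _quasi_medians(u: str, v: str, w: str, cap: int = 8) -> list[str]:
    """Per-site majority consensus of a triple; three-state sites branch into
    all resolutions (capped to avoid combinatorial blow-up)."""
    options: list[tuple[str, ...]] = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append((a, b, c))
    n_branch = 1
    for o in options:
        n_branch *= len(o)
        if n_branch > cap:
            return []
    return ["".join(t) for t in itertools.product(*options)]


def _mst_length(d: np.ndarray) -> float:
    g = nx.Graph()
    n = d.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(d[i, j]))
    return sum(dd["weight"] for _, _, dd in nx.minimum_spanning_edges(g, data=True))


def median_joining(
    table: HaplotypeTable, epsilon: int = 0, max_iter: int = 25
) -> HaplotypeNetwork:
    """Median-joining network of the observed haplotypes.

    Iterates: build the epsilon-relaxed minimum-spanning network, propose
    quasi-medians of linked triples, keep those that shorten the spanning
    length of the node set; stops when no median helps.
    """
    observed = list(table.haplotypes)
    freqs = dict(zip(observed, (int(c) for c in table.total_counts)))
    nodes = list(observed)
    if len(nodes) == 1:
        g = nx.Graph()
        g.add_node(nodes[0])
        return HaplotypeNetwork(g, observed, freqs, epsilon)

    for _ in range(max_iter):
        d = hamming_matrix(nodes)
        edges = _msn_edges(d, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        base_len = _mst_length(d)
        added = False
        candidates: dict[str, None] = {}
        for i in range(len(nodes)):
            for j, k in itertools.combinations(sorted(adj[i]), 2):
                for m in _quasi_medians(nodes[i], nodes[j], nodes[k]):
                    if m not in candidates and m not in set(nodes):
                        candidates[m] = None
        for m in candidates:
            if len(nodes) - len(observed) >= MAX_MEDIANS:
                break
            trial = nodes + [m]
            if _mst_length(hamming_matrix(trial)) < base_len - 1e-9:
                nodes.append(m)
                added = True
        if not added:
            break

    d = hamming_matrix(nodes)
    edges = _msn_edges(d, epsilon)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, j in edges:
        g.add_edge(nodes[i], nodes[j], weight=int(d[i, j]))
    net = HaplotypeNetwork(
        g, observed, freqs, epsilon, medians=[n for n in nodes if n not in set(observed)]
    )
    return mp_cleanup(net)


def mp_cleanup(net: HaplotypeNetwork) -> HaplotypeNetwork:
    """Remove median vectors not on any shortest connection between observed
    haplotypes; shortest-path lengths among observed nodes are preserved.

    Iterates because removing one median can strand another; the surviving
    medians are genuine branch points of the network.
    """
    nodes = list(net.graph.nodes)
    observed = set(net.observed)
    epsilon = net.epsilon
    while True:
        d = hamming_matrix(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i, j in _msn_edges(d, epsilon):
            g.add_edge(nodes[i], nodes[j], weight=int(d[i, j]))
        sp = dict(nx.all_pairs_dijkstra_path_length(g))
        needed: set[str] = set(observed)
        obs_list = [n for n in nodes if n in observed]
        for a, b in itertools.combinations(obs_list, 2):
            dab = sp[a].get(b, float("inf"))
            for m in nodes:
                if m in observed:
                    continue
                if sp[a].get(m, float("inf")) + sp[m].get(b, float("inf")) <= dab + 1e-9:
                    needed.add(m)
        # degree-<3 medians are never true branch points: splice them out
        drop = {
            m for m in nodes
            if m not in observed and (m not in needed or g.degree(m) < 3)
        }
        if not drop:
            return HaplotypeNetwork(
                g, net.observed, net.frequencies, epsilon,
                medians=[n for n in nodes if n not in observed],
            )
        nodes = [n for n in nodes if n not in drop]
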