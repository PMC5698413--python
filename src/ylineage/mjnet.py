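"""Median-joining networks for STR haplotypes.

Stage 1 is the minimum spanning network (MSN): the union of all minimum
spanning trees of the pairwise stepwise-distance graph, relaxed by an
``epsilon`` tolerance (an edge enters if its weight is within epsilon of
the minimax connection cost between its endpoints).  Stage 2 iteratively
proposes median (Steiner) haplotypes — per-locus medians of triplets that
are connected in the current MSN — keeps those that shorten the minimum
spanning tree, and prunes medians that stop being useful.  Identical
observed haplotypes collapse into one node whose frequency is the count.

The resulting graph quantifies the qualitative "star-likeness" of a
radiation: :func:`star_index` is the fraction of observed haplotypes one
mutational step away from the most frequent node.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx
import numpy as np

from .containers import STRHaplotypeTable

MAX_MJ_ITERATIONS = 50


def _condense(haplotypes):
    """Distinct haplotype vectors with frequencies and population tallies."""
    if isinstance(haplotypes, STRHaplotypeTable):
        vectors = [tuple(int(x) for x in h) for h in haplotypes.haplotype_tuples()]
        pops = list(haplotypes.populations)
        loci = haplotypes.loci
    else:
        arr = np.asarray(haplotypes, dtype=np.int64)
        vectors = [tuple(int(x) for x in row) for row in arr.reshape(len(arr), -1)]
        pops = [None] * len(vectors)
        loci = [f"locus{j + 1}" for j in range(len(vectors[0]))] if vectors else []
    freq: Counter = Counter(vectors)
    pop_comp: dict[tuple, Counter] = {}
    for v, p in zip(vectors, pops):
        if p is not None:
            pop_comp.setdefault(v, Counter())[p] += 1
    uniq = sorted(freq)  # canonical order: input-order independent
    return uniq, freq, pop_comp, loci


def _dist(a: tuple, b: tuple, weights: np.ndarray) -> float:
    return float(np.dot(np.abs(np.subtract(a, b)), weights))


def _pairwise(nodes: list[tuple], weights: np.ndarray) -> np.ndarray:
    arr = np.asarray(nodes, dtype=float)
    return np.abs(arr[:, None, :] - arr[None, :, :]).dot(weights)


def _mst_cost_and_minimax(dmat: np.ndarray):
    """Total MST cost plus the minimax (bottleneck) distance of every pair.

    An edge (u, v) belongs to some minimum spanning tree exactly when its
    direct distance equals the minimax path distance between u and v.
    """
    k = dmat.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            g.add_edge(i, j, weight=dmat[i, j])
    mst = nx.minimum_spanning_tree(g)
    cost = mst.size(weight="weight")
    minimax = np.zeros_like(dmat)
    for i in range(k):
        # max edge weight along MST paths from i
        lengths = {}
        stack = [(i, 0.0)]
        seen = {i}
        while stack:
            u, best = stack.pop()
            for v in mst.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    w = max(best, mst[u][v]["weight"])
                    lengths[v] = w
                    stack.append((v, w))
        for j, w in lengths.items():
            minimax[i, j] = w
    return cost, minimax


def _msn_graph(nodes: list[tuple], weights: np.ndarray, epsilon: float) -> nx.Graph:
    dmat = _pairwise(nodes, weights)
    _, minimax = _mst_cost_and_minimax(dmat)
    g = nx.Graph()
    for idx, v in enumerate(nodes):
        g.add_node(v)
    k = len(nodes)
    for i in range(k):
        for j in range(i + 1, k):
            if dmat[i, j] <= minimax[i, j] + epsilon + 1e-12:
                g.add_edge(nodes[i], nodes[j], weight=float(dmat[i, j]))
    return g


def _annotate(g: nx.Graph, freq: Counter, pop_comp: dict, loci: list[str]) -> nx.Graph:
    for v in g.nodes:
        g.nodes[v]["haplotype"] = ",".join(str(x) for x in v)
        g.nodes[v]["frequency"] = int(freq.get(v, 0))
        g.nodes[v]["type"] = "observed" if v in freq else "median"
        comp = pop_comp.get(v)
        if comp:
            g.nodes[v]["populations"] = ";".join(
                f"{p}:{c}" for p, c in sorted(comp.items()))
    for u, v in g.edges:
        steps = [f"{loci[j]}:{v[j] - u[j]:+d}" for j in range(len(u)) if u[j] != v[j]]
        g.edges[u, v]["loci"] = ";".join(steps)
    return g


def minimum_spanning_network(haplotypes, epsilon: float = 0.0,
                             locus_weights=None) -> nx.Graph:
    """Minimum spanning network over the distinct observed haplotypes."""
    uniq, freq, pop_comp, loci = _condense(haplotypes)
    if not uniq:
        raise ValueError("no haplotypes given")
    weights = _weights(locus_weights, len(uniq[0]))
    g = _msn_graph(uniq, weights, epsilon)
    return _annotate(g, freq, pop_comp, loci)


def _weights(locus_weights, n_loci: int) -> np.ndarray:
    if locus_weights is None:
        return np.ones(n_loci)
    w = np.asarray(locus_weights, dtype=float)
    if w.shape != (n_loci,):
        raise ValueError("locus_weights length must match the locus count")
    return w


def _median_vector(a: tuple, b: tuple, c: tuple) -> tuple:
    return tuple(int(np.median([a[j], b[j], c[j]])) for j in range(len(a)))


def median_joining(haplotypes, epsilon: float = 0.0, locus_weights=None,
                   max_iterations: int = MAX_MJ_ITERATIONS) -> nx.Graph:
    """Median-joining network: MSN plus cost-reducing median haplotypes.

    Candidate medians are per-locus medians of triplets (u, v, w) where
    both u-v and v-w are MSN edges; a candidate is kept when adding it
    alone shortens the minimum spanning tree.  Iterates to a fixed point
    (total MST cost is non-increasing), then prunes medians whose removal
    leaves the MST cost unchanged.
    """
    uniq, freq, pop_comp, loci = _condense(haplotypes)
    if not uniq:
        raise ValueError("no haplotypes given")
    weights = _weights(locus_weights, len(uniq[0]))
    nodes = list(uniq)

    for iteration in range(max_iterations + 1):
        if iteration == max_iterations:
            raise RuntimeError(
                f"median joining did not converge in {max_iterations} iterations "
                f"({len(nodes)} nodes, {len(nodes) - len(uniq)} medians)")
        msn = _msn_graph(nodes, weights, epsilon)
        base_cost, _ = _mst_cost_and_minimax(_pairwise(nodes, weights))
        node_set = set(nodes)
        candidates = set()
        for v in msn.nodes:
            for u, w in itertools.combinations(msn.neighbors(v), 2):
                m = _median_vector(u, v, w)
                if m not in node_set:
                    candidates.add(m)
        added = []
        for m in sorted(candidates):
            cost, _ = _mst_cost_and_minimax(_pairwise(nodes + [m], weights))
            if cost < base_cost - 1e-9:
                added.append(m)
        if not added:
            break
        nodes.extend(sorted(added))

    # prune medians that no longer shorten the tree
    changed = True
    while changed:
        changed = False
        base_cost, _ = _mst_cost_and_minimax(_pairwise(nodes, weights))
        for m in [v for v in nodes if v not in set(uniq)]:
            rest = [v for v in nodes if v != m]
            cost, _ = _mst_cost_and_minimax(_pairwise(rest, weights))
            if cost <= base_cost + 1e-9:
                nodes = rest
                changed = True
                break

    g = _msn_graph(nodes, weights, epsilon)
    return _annotate(g, freq, pop_comp, loci)


def star_index(network: nx.Graph) -> float:
    """Fraction of observed haplotypes one mutational step from the centre.

    The centre is the highest-frequency observed node (ties broken by
    lexicographically smallest haplotype).  A perfect star scores 1.0; a
    long chain scores near 0.
    """
    if not nx.is_connected(network):
        raise ValueError("network must be connected")
    observed = [v for v, d in network.nodes(data=True) if d.get("type") == "observed"]
    if len(observed) < 2:
        return 1.0
    centre = min(observed, key=lambda v: (-network.nodes[v]["frequency"], v))
    dist = nx.single_source_dijkstra_path_length(network, centre, weight="weight")
    others = [v for v in observed if v != centre]
    hits = sum(1 for v in others if abs(dist.get(v, np.inf) - 1.0) <= 1e-9)
    return hits / len(others)


def write_graphml(network: nx.Graph, path) -> None:
    """GraphML export with string node keys (haplotype vectors as labels)."""
    g = nx.relabel_nodes(network, {v: ",".join(map(str, v)) for v in network.nodes})
    nx.write_graphml(g, str(path))
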