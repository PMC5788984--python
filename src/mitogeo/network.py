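"""Haplotype networks.

Builds a minimum-spanning network (MSN): the union of all minimum spanning
trees of the complete inter-haplotype distance graph.  Equal-weight ties at
the joining step are all retained, which produces the reticulations seen in
real haplotype networks.  Every retained link of weight ``w > 1`` is expanded
into a chain of ``w - 1`` anonymous latent ("missing") nodes so that each
edge of the final graph spans exactly one mutation step.

An optional connection limit (integer number of steps, in the spirit of the
statistical-parsimony cutoff) drops retained links longer than the limit,
which may disconnect the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .data_io import DiffMatrix, HaplotypeTable

LATENT = "latent"


def _msn_edges(d: np.ndarray) -> list[tuple[int, int, int]]:
    """Edges of the union of all minimum spanning trees of a complete graph.

    An edge (u, v, w) belongs to some MST iff u and v lie in different
    connected components of the subgraph of all strictly lighter edges
    (the cycle-property characterization), restricted to weights that some
    MST actually uses.  For a complete graph every weight class is examined
    in increasing order; classes that join nothing new are skipped.
    """
    n = d.shape[0]
    if n <= 1:
        return []
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    iu, iv = np.triu_indices(n, k=1)
    weights = d[iu, iv]
    order = np.argsort(weights, kind="stable")
    edges: list[tuple[int, int, int]] = []
    i = 0
    m = order.size
    while i < m:
        w = weights[order[i]]
        j = i
        batch = []
        while j < m and weights[order[j]] == w:
            e = order[j]
            u, v = int(iu[e]), int(iv[e])
            if find(u) != find(v):
                batch.append((u, v, int(w)))
            j += 1
        for u, v, wt in batch:  # union after collecting the whole tie class
            edges.append((u, v, wt))
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        i = j
    return edges


def build_network(
    d: DiffMatrix,
    freqs: Sequence[int] | None = None,
    group_freqs: Sequence[dict] | None = None,
    limit: int | None = None,
) -> nx.Graph:
    """Build the haplotype network graph from a difference matrix.

    Parameters
    ----------
    d
        Symmetric mutation-step matrix between haplotypes.
    freqs
        Haplotype frequencies (default 1 each), stored as node attributes.
    group_freqs
        Optional per-haplotype mapping of group name to count.
    limit
        Optional step cutoff: retained links longer than ``limit`` are
        dropped before chain expansion (may disconnect the graph).

    Returns
    -------
    networkx.Graph
        Nodes are haplotype labels (attributes ``frequency``, ``latent=False``,
        optional ``group_frequencies``) plus anonymous latent nodes
        (``latent=True``, frequency 0).  Every edge spans one mutation step
        and carries the label pair of its parent link in ``parent_link``.
    """
    labels = d.labels
    g = nx.Graph()
    fr = list(freqs) if freqs is not None else [1] * len(labels)
    for i, lab in enumerate(labels):
        attrs = {"frequency": int(fr[i]), "latent": False}
        if group_freqs is not None:
            attrs["group_frequencies"] = dict(group_freqs[i])
        g.add_node(lab, **attrs)
    links = _msn_edges(d.matrix)
    if limit is not None:
        links = [(u, v, w) for u, v, w in links if w <= limit]
    k = 0
    for u, v, w in links:
        lu, lv = labels[u], labels[v]
        if w <= 0:
            continue
        chain = [lu]
        for _ in range(w - 1):
            k += 1
            node = f"__latent{k}"
            g.add_node(node, frequency=0, latent=True)
            chain.append(node)
        chain.append(lv)
        for a, b in zip(chain[:-1], chain[1:]):
            g.add_edge(a, b, parent_link=(lu, lv), parent_weight=int(w))
    return g


def network_from_haplotypes(
    ht: HaplotypeTable, d: DiffMatrix | None = None, limit: int | None = None
) -> nx.Graph:
    """Convenience wrapper: MSN of a haplotype table."""
    from .data_io import pairwise_diff_matrix

    if d is None:
        d = pairwise_diff_matrix(ht)
    return build_network(
        d,
        freqs=ht.frequencies,
        group_freqs=[hap.group_frequencies for hap in ht.haplotypes],
        limit=limit,
    )


def contract_latent(g: nx.Graph) -> nx.Graph:
    """Re-contract latent chains, recovering the weighted MSN."""
    out = nx.Graph()
    for n, attrs in g.nodes(data=True):
        if not attrs.get("latent"):
            out.add_node(n, **attrs)
    seen: dict[tuple, int] = {}
    for _, _, attrs in g.edges(data=True):
        link = attrs["parent_link"]
        seen[link] = attrs["parent_weight"]
    for (u, v), w in seen.items():
        out.add_edge(u, v, weight=w)
    return out


def min_steps_between(
    d: DiffMatrix, set_a: Iterable[str], set_b: Iterable[str]
) -> int:
    """Minimum mutation steps between two disjoint haplotype sets."""
    a = list(set_a)
    b = list(set_b)
    if not a or not b:
        raise ValueError("both haplotype sets must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"haplotype sets overlap: {sorted(set(a) & set(b))}")
    ia = [d.index_of(x) for x in a]
    ib = [d.index_of(x) for x in b]
    return int(d.matrix[np.ix_(ia, ib)].min())


@dataclass(frozen=True)
class StarScore:
    central: str
    score: float
    n_tips: int


def star_score(g: nx.Graph) -> StarScore:
    """Star-likeness of a connected haplotype network component.

    The central node is the haplotype (non-latent) node of maximal degree
    (ties broken by higher frequency, then label order); the score is the
    fraction of tip haplotypes (non-latent nodes of degree 1) lying exactly
    one mutation step from the centre.  A perfect star scores 1.0.
    """
    if not nx.is_connected(g):
        raise ValueError("star_score requires a connected component")
    haps = [n for n, a in g.nodes(data=True) if not a.get("latent")]
    if len(haps) == 1:
        return StarScore(haps[0], 1.0, 0)
    central = sorted(
        haps,
        key=lambda n: (-g.degree(n), -g.nodes[n].get("frequency", 0), str(n)),
    )[0]
    tips = [n for n in haps if n != central and g.degree(n) == 1]
    if not tips:
        return StarScore(central, 0.0, 0)
    dist = nx.single_source_shortest_path_length(g, central)
    at_one = sum(1 for t in tips if dist.get(t) == 1)
    return StarScore(central, at_one / len(tips), len(tips))


def write_graphml(g: nx.Graph, path) -> None:
    h = _stringify(g)
    nx.write_graphml(h, path)


def write_gml(g: nx.Graph, path) -> None:
    nx.write_gml(_stringify(g), path)


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tparent_source\tparent_target\tparent_weight\n")
        for u, v, a in g.edges(data=True):
            pu, pv = a.get("parent_link", (u, v))
            fh.write(f"{u}\t{v}\t{pu}\t{pv}\t{a.get('parent_weight', 1)}\n")


def _stringify(g: nx.Graph) -> nx.Graph:
    """GraphML/GML writers need scalar attributes; flatten dicts/tuples."""
    h = nx.Graph()
    for n, attrs in g.nodes(data=True):
        flat = {}
        for k, v in attrs.items():
            if isinstance(v, dict):
                for gk, gv in v.items():
                    flat[f"freq_{gk}"] = int(gv)
            else:
                flat[k] = v if isinstance(v, (int, float, str, bool)) else str(v)
        h.add_node(n, **flat)
    for u, v, attrs in g.edges(data=True):
        flat = {
            k: (v2 if isinstance(v2, (int, float, str, bool)) else str(v2))
            for k, v2 in attrs.items()
        }
        h.add_edge(u, v, **flat)
    return h
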