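"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own tree/distance code paths: trees
are enumerated by sequential leaf insertion, path-length matrices come from
BFS over explicit edge lists, and least-squares fits use plain lstsq.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(taxa: list[str]) -> list[list[tuple]]:
    """All unrooted binary topologies on the given taxa, as edge lists.

    Leaves are the taxon strings, internal nodes negative integers.
    3 taxa -> 1 topology, 4 -> 3, 5 -> 15, 6 -> 105.
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    counter = itertools.count(-1, -1)
    root = next(counter)
    trees = [[(root, t) for t in taxa[:3]]]
    for leaf in taxa[3:]:
        nxt = []
        for edges in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                w = next(counter)
                nxt.append(edges[:k] + edges[k + 1:] + [(u, w), (w, v), (w, leaf)])
        trees = nxt
    return trees


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def splits_of(edges, nontrivial_only: bool = True) -> set[frozenset]:
    """Bipartitions of an edge-list tree, canonicalised to exclude the
    smallest leaf label."""
    adj = _adjacency(edges)
    leaves = {n for n in adj if isinstance(n, str)}
    ref = min(leaves)
    out = set()
    for u, v in edges:
        stack, seen, side = [v], {u, v}, set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if ref in side:
            side = leaves - side
        if nontrivial_only and not (2 <= len(side) <= len(leaves) - 2):
            continue
        out.add(frozenset(side))
    return out


def path_lengths(edges, lengths, taxa) -> np.ndarray:
    """Pairwise leaf-to-leaf distances by BFS over the weighted edge list."""
    adj = {}
    for (u, v), w in zip(edges, lengths):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(taxa)
    D = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for j, dst in enumerate(taxa):
            D[i, j] = dist[dst]
    return D


def least_squares_topology(D: np.ndarray, taxa: list[str]) -> set[frozenset]:
    """Best-fitting topology by ordinary least squares over all topologies.

    Returns the non-trivial split set of the topology minimising the
    residual of branch lengths fitted to the distance matrix.
    """
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    d = np.array([D[i, j] for i, j in pairs])
    best = None
    for edges in enumerate_topologies(taxa):
        adj = _adjacency(edges)
        # path indicator matrix: rows = pairs, cols = edges
        A = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            # BFS recording the edge path from taxa[i] to taxa[j]
            parent = {taxa[i]: None}
            stack = [taxa[i]]
            while stack:
                node = stack.pop()
                for nbr in adj[node]:
                    if nbr not in parent:
                        parent[nbr] = node
                        stack.append(nbr)
            node = taxa[j]
            while parent[node] is not None:
                u = parent[node]
                for c, (a, b) in enumerate(edges):
                    if {a, b} == {u, node}:
                        A[r, c] = 1.0
                        break
                node = u
        x, residuals, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(((A @ x - d) ** 2).sum())
        if best is None or resid < best[0] - 1e-12:
            best = (resid, splits_of(edges))
    return best[1]


def edges_to_newick(edges) -> str:
    """Render an edge-list tree (unit branch lengths) as Newick."""
    adj = _adjacency(edges)
    leaves = sorted(n for n in adj if isinstance(n, str))
    start = leaves[0]
    anchor = next(iter(adj[start]))

    def render(node, parent):
        if isinstance(node, str):
            return node
        parts = [render(nbr, node) + ":1" for nbr in sorted(adj[node], key=repr)
                 if nbr != parent]
        return "(" + ",".join(parts) + ")"

    inner = render(anchor, start)[1:-1]
    return f"({start}:1,{inner});"
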