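"""Distances, neighbor joining, tree comparison and the outgroup experiment.

The experiment quantifies a compositional long-branch-attraction artefact:
two non-sister taxa are driven toward a shared, homoplastic base
composition by :func:`mitoskew.synthetic.simulate_skewed_alignment`, trees
are inferred by neighbor joining from an uncorrected p-distance matrix and
from a LogDet (paralinear) matrix, and the frequency with which the
homoplastic taxa unite as a clade is tabulated per outgroup strategy
(none / single homoplastic outgroup / many outgroups).  Findings are
directional contracts — p-distance attracts more than LogDet, and a single
composition-matched outgroup attracts more than no outgroup.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic import Alignment, AlignmentSimConfig, ConfigError, simulate_skewed_alignment

__all__ = [
    "DistanceMatrix",
    "Tree",
    "ExperimentResult",
    "OutgroupExperimentConfig",
    "p_distance_matrix",
    "logdet_distance_matrix",
    "neighbor_joining",
    "is_clade",
    "rf_distance",
    "run_outgroup_experiment",
    "default_experiment_config",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(alignment) -> tuple[list[str], np.ndarray]:
    """Sorted taxon labels + integer matrix (non-ACGT -> 4)."""
    seqs = alignment.sequences if isinstance(alignment, Alignment) else dict(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    labels = sorted(seqs)
    mat = np.full((len(labels), lengths.pop()), 4, dtype=np.int8)
    for i, lab in enumerate(labels):
        arr = np.frombuffer(seqs[lab].upper().encode(), dtype="S1").astype("U1")
        for base, code in _CODE.items():
            mat[i][arr == base] = code
    return labels, mat


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    #: unordered label pairs whose divergence table was singular
    saturated: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def p_distance_matrix(alignment) -> DistanceMatrix:
    """Proportion of differing sites per pair; sites with a non-ACGT symbol
    in either sequence are excluded pairwise."""
    labels, mat = _encode(alignment)
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        valid = (mat[i] < 4) & (mat[j] < 4)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
        out[i, j] = out[j, i] = float((mat[i][valid] != mat[j][valid]).sum()) / total
    return DistanceMatrix(labels, out)


def logdet_distance_matrix(alignment) -> DistanceMatrix:
    """LogDet (paralinear) distances, robust to compositional heterogeneity.

    For each pair, ``d = -(1/4) [ln det F - (1/2) sum_i ln(r_i c_i)]`` where
    F is the 4x4 joint relative-frequency table of the pair and r, c its
    marginals.  Pairs whose F is singular (or has an empty marginal) are
    flagged saturated and given an infinite distance instead of crashing.
    """
    labels, mat = _encode(alignment)
    n = len(labels)
    out = np.zeros((n, n))
    saturated: set[frozenset] = set()
    for i, j in itertools.combinations(range(n), 2):
        valid = (mat[i] < 4) & (mat[j] < 4)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
        F = np.zeros((4, 4))
        np.add.at(F, (mat[i][valid], mat[j][valid]), 1.0)
        F /= total
        r, c = F.sum(axis=1), F.sum(axis=0)
        det = np.linalg.det(F)
        if det <= 0 or np.any(r <= 0) or np.any(c <= 0):
            saturated.add(frozenset((labels[i], labels[j])))
            d = math.inf
        else:
            d = -0.25 * (math.log(det) - 0.5 * (np.log(r).sum() + np.log(c).sum()))
            d = max(d, 0.0)
        out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out, saturated=saturated)


# ---------------------------------------------------------------------------
# Trees

class Tree:
    """Unrooted tree: leaves are string labels, internal nodes integers.

    Branch lengths live on the adjacency map.  Equality-relevant structure
    is exposed through :meth:`bipartitions`.
    """

    def __init__(self) -> None:
        self.adjacency: dict[object, dict[object, float]] = {}
        self.negative_branch_clamped = False
        self._next_internal = 0

    # construction ---------------------------------------------------------
    def _new_internal(self) -> int:
        self._next_internal += 1
        return self._next_internal

    def add_edge(self, a, b, length: float = 0.0) -> None:
        self.adjacency.setdefault(a, {})[b] = length
        self.adjacency.setdefault(b, {})[a] = length

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        tree = cls()
        ids: dict = {}

        def node_id(node):
            if node not in ids:
                if node.is_leaf():
                    ids[node] = node.taxon.label
                else:
                    ids[node] = tree._new_internal()
            return ids[node]

        for node in dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            tree.add_edge(node_id(node.parent_node), node_id(node),
                          node.edge.length or 0.0)
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        # a rooted newick leaves a degree-2 root; merge its two edges
        for node in [n for n, nb in self.adjacency.items()
                     if isinstance(n, int) and len(nb) == 2]:
            (a, la), (b, lb) = self.adjacency[node].items()
            del self.adjacency[a][node]
            del self.adjacency[b][node]
            del self.adjacency[node]
            self.add_edge(a, b, la + lb)

    # queries --------------------------------------------------------------
    @property
    def leaves(self) -> set[str]:
        return {n for n in self.adjacency if isinstance(n, str)}

    def edges(self):
        seen = set()
        for a, nbrs in self.adjacency.items():
            for b, length in nbrs.items():
                key = frozenset((repr(a), repr(b)))
                if key in seen:
                    continue
                seen.add(key)
                yield a, b, length

    def _side(self, a, b) -> set[str]:
        """Leaves reachable from ``b`` without crossing edge (a, b)."""
        stack, seen, out = [b], {a, b}, set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.add(node)
            for nbr in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return out

    def splits(self, nontrivial_only: bool = True) -> set[frozenset]:
        """Bipartitions, canonicalised as the side excluding the smallest
        leaf label; non-trivial = both sides of size >= 2."""
        all_leaves = self.leaves
        ref = min(all_leaves)
        out = set()
        for a, b, _ in self.edges():
            side = self._side(a, b)
            if ref in side:
                side = all_leaves - side
            if nontrivial_only and not (2 <= len(side) <= len(all_leaves) - 2):
                continue
            out.add(frozenset(side))
        return out

    def restrict(self, keep) -> "Tree":
        """Induced subtree on ``keep`` (leaves pruned, degree-2 internals
        suppressed, branch lengths summed across suppressed nodes)."""
        keep = set(keep)
        if not keep <= self.leaves:
            raise ValueError("keep must be a subset of the tree's leaves")
        out = Tree()
        out._next_internal = self._next_internal
        out.adjacency = {n: dict(nb) for n, nb in self.adjacency.items()}
        changed = True
        while changed:
            changed = False
            for node in list(out.adjacency):
                nbrs = out.adjacency[node]
                if isinstance(node, str) and node not in keep:
                    for nbr in list(nbrs):
                        del out.adjacency[nbr][node]
                    del out.adjacency[node]
                    changed = True
                elif isinstance(node, int) and len(nbrs) == 1:
                    (nbr,) = nbrs
                    del out.adjacency[nbr][node]
                    del out.adjacency[node]
                    changed = True
                elif isinstance(node, int) and len(nbrs) == 2:
                    (a, la), (b, lb) = nbrs.items()
                    del out.adjacency[a][node]
                    del out.adjacency[b][node]
                    del out.adjacency[node]
                    out.add_edge(a, b, la + lb)
                    changed = True
        return out

    def to_newick(self) -> str:
        leaves = sorted(self.leaves)
        root = next(iter(self.adjacency[leaves[0]]))  # internal neighbour

        def render(node, parent) -> str:
            if isinstance(node, str):
                return node
            parts = [render(nbr, node) + f":{length:.6g}"
                     for nbr, length in sorted(self.adjacency[node].items(), key=lambda kv: repr(kv[0]))
                     if nbr != parent]
            return "(" + ",".join(parts) + ")"

        length = self.adjacency[root][leaves[0]]
        return f"({leaves[0]}:{length:.6g},{render(root, leaves[0])[1:-1]});"


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Standard neighbor joining on the Q-criterion.

    Deterministic: the matrix is label-sorted and Q-ties break on the
    lexicographically smallest representative label pair, so permuting the
    input taxon order cannot change the topology.  Negative branch lengths
    are clamped to zero and flagged on the returned tree.
    """
    if len(m.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("distance matrix contains non-finite entries (saturated pairs?)")

    order = np.argsort(np.asarray(m.labels, dtype=object))
    labels = [m.labels[i] for i in order]
    D = m.values[np.ix_(order, order)].astype(float).copy()

    tree = Tree()
    nodes: list[object] = list(labels)          # tree node per active cluster
    reps: list[str] = list(labels)              # min leaf label per cluster
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((reps[i], reps[j])))
                if best is None or (q, pair) < (best[0], best[1]):
                    best = (q, pair, i, j)
        _, _, i, j = best
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))))
        new = tree._new_internal()
        tree.add_edge(new, nodes[i], li)
        tree.add_edge(new, nodes[j], lj)
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([
            np.hstack([[0.0], d_new[keep]]),
            np.hstack([d_new[keep][:, None], D[np.ix_(keep, keep)]]),
        ])
        nodes = [new] + [nodes[k] for k in keep]
        reps = [min(reps[i], reps[j])] + [reps[k] for k in keep]

    # final three clusters joined at one internal node (closed form)
    center = tree._new_internal()
    (i, j, k) = (0, 1, 2)
    tree.add_edge(center, nodes[i], clamp(0.5 * (D[i, j] + D[i, k] - D[j, k])))
    tree.add_edge(center, nodes[j], clamp(0.5 * (D[i, j] + D[j, k] - D[i, k])))
    tree.add_edge(center, nodes[k], clamp(0.5 * (D[i, k] + D[j, k] - D[i, j])))
    tree.negative_branch_clamped = clamped
    return tree


def is_clade(tree: Tree, taxa, outgroup: str | None = None) -> bool:
    """True iff some edge splits exactly ``taxa`` from the rest.

    Unrooted bipartition test; when ``outgroup`` is given it must lie
    outside ``taxa`` (rooting on it then makes ``taxa`` a monophyletic
    clade whenever the bipartition exists).
    """
    taxa = frozenset(taxa)
    leaves = tree.leaves
    if not taxa or not taxa <= leaves:
        raise ValueError("taxa must be a non-empty subset of the tree's leaves")
    if taxa == leaves:
        raise ValueError("taxa equals the full leaf set; clade test is vacuous")
    if outgroup is not None:
        if outgroup in taxa:
            raise ValueError("outgroup must lie outside the queried taxa")
        if outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
    if len(taxa) == 1:
        return True
    query = taxa
    if min(leaves) in query:  # splits are canonicalised to exclude min leaf
        query = frozenset(leaves - query)
    return query in tree.splits(nontrivial_only=False)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    non-trivial bipartition sets."""
    if t1.leaves != t2.leaves:
        raise ValueError("trees must share one leaf set")
    return len(t1.splits() ^ t2.splits())


# ---------------------------------------------------------------------------
# Outgroup-strategy experiment


@dataclass
class OutgroupExperimentConfig:
    """The seeded long-branch-attraction experiment.

    ``ingroup_tree`` (rooted Newick) must place the two homoplastic taxa as
    non-sisters; they are assigned ``shifted_group``, everything else
    ``base_group``.  The single-outgroup strategy attaches one outgroup
    carrying the homoplastic composition (modelling an outgroup that shares
    the ingroup minority's skew state); the many-outgroup strategy attaches
    a ladder of outgroups with the background composition.
    """

    ingroup_tree: str
    homoplastic_taxa: tuple[str, str]
    groups: dict[str, str]
    group_freqs: dict[str, tuple[float, float, float, float]]
    base_group: str
    shifted_group: str
    seq_length: int
    replicates: int
    seed: int
    single_outgroup: str = "OUT"
    single_outgroup_branch: float = 1.5
    many_outgroups: tuple[str, ...] = ("OG1", "OG2", "OG3", "OG4", "OG5")
    many_outgroup_branch: float = 0.3
    strategies: tuple[str, ...] = ("none", "single", "many")
    methods: tuple[str, ...] = ("p", "logdet")


@dataclass
class CellStats:
    replicates: int
    artefact_count: int
    artefact_frequency: float
    mean_rf: float


@dataclass
class ExperimentResult:
    replicates: int
    seed: int
    cells: dict[tuple[str, str], CellStats]  # (method, strategy) -> stats

    def frequency(self, method: str, strategy: str) -> float:
        return self.cells[(method, strategy)].artefact_frequency

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "seed": self.seed,
            "cells": {
                f"{method}/{strategy}": {
                    "replicates": s.replicates,
                    "artefact_count": s.artefact_count,
                    "artefact_frequency": s.artefact_frequency,
                    "mean_rf": s.mean_rf,
                }
                for (method, strategy), s in sorted(self.cells.items())
            },
        }


_DIST_FNS = {"p": p_distance_matrix, "logdet": logdet_distance_matrix}


def _definite(m: DistanceMatrix) -> DistanceMatrix:
    """Replace saturated (infinite) entries by twice the largest finite
    distance so NJ can proceed; the saturated flags are preserved."""
    if not m.saturated:
        return m
    vals = m.values.copy()
    finite = vals[np.isfinite(vals)]
    cap = 2.0 * float(finite.max()) if finite.size else 1.0
    vals[~np.isfinite(vals)] = cap
    return DistanceMatrix(m.labels, vals, saturated=set(m.saturated))


def _strategy_tree(cfg: OutgroupExperimentConfig, strategy: str) -> tuple[str, dict[str, str]]:
    """Full Newick + taxon->group map for one outgroup strategy."""
    core = cfg.ingroup_tree.strip().rstrip(";")
    groups = dict(cfg.groups)
    if strategy == "none":
        return core + ";", groups
    if strategy == "single":
        groups[cfg.single_outgroup] = cfg.shifted_group
        return (f"({core}:0.2,{cfg.single_outgroup}:{cfg.single_outgroup_branch});",
                groups)
    if strategy == "many":
        b = cfg.many_outgroup_branch
        sub = f"{cfg.many_outgroups[0]}:{b}"
        for og in cfg.many_outgroups[1:]:
            sub = f"({sub},{og}:{b}):{b}"
        for og in cfg.many_outgroups:
            groups[og] = cfg.base_group
        return f"({core}:0.2,{sub});", groups
    raise ConfigError(f"unknown strategy {strategy!r}")


def run_outgroup_experiment(cfg: OutgroupExperimentConfig) -> ExperimentResult:
    """Run the seeded replicate experiment and tabulate, per distance method
    and outgroup strategy, how often the homoplastic pair unites as a clade
    and the mean RF distance to the true (generating) tree."""
    homoplastic = frozenset(cfg.homoplastic_taxa)
    counters = {(m, s): [0, 0.0] for m in cfg.methods for s in cfg.strategies}
    true_ingroup = Tree.from_newick(cfg.ingroup_tree)
    ingroup_leaves = true_ingroup.leaves
    trees: dict[str, tuple[str, dict[str, str]]] = {
        strategy: _strategy_tree(cfg, strategy) for strategy in cfg.strategies
    }

    for rep in range(cfg.replicates):
        for s_idx, strategy in enumerate(cfg.strategies):
            newick, groups = trees[strategy]
            rep_seed = int(np.random.SeedSequence(
                entropy=(cfg.seed, rep, s_idx)).generate_state(1)[0])
            aln = simulate_skewed_alignment(AlignmentSimConfig(
                tree=newick, groups=groups, group_freqs=cfg.group_freqs,
                root_group=cfg.base_group, length=cfg.seq_length, seed=rep_seed,
            ))
            for method in cfg.methods:
                inferred = neighbor_joining(_definite(_DIST_FNS[method](aln)))
                # outgroups only orient the topology: the clade and RF
                # questions are asked of the ingroup tree they leave behind
                inferred = inferred.restrict(ingroup_leaves)
                cell = counters[(method, strategy)]
                if is_clade(inferred, homoplastic):
                    cell[0] += 1
                cell[1] += rf_distance(inferred, true_ingroup)

    cells = {
        key: CellStats(
            replicates=cfg.replicates,
            artefact_count=count,
            artefact_frequency=count / cfg.replicates,
            mean_rf=rf_sum / cfg.replicates,
        )
        for key, (count, rf_sum) in counters.items()
    }
    return ExperimentResult(replicates=cfg.replicates, seed=cfg.seed, cells=cells)


def default_experiment_config(
    replicates: int = 200, seq_length: int = 2000, seed: int = 0,
    long_branch: float = 1.1, internal_branch: float = 0.15,
) -> OutgroupExperimentConfig:
    """The standard 12-ingroup-taxon setup: homoplastic taxa H1 and H2 sit at
    opposite ends of a caterpillar tree on long terminal branches and share a
    strongly shifted composition.  Set ``long_branch`` equal to
    ``internal_branch`` (and equal group compositions) for a no-signal null.
    """
    b, long = internal_branch, long_branch
    taxa = [f"T{i}" for i in range(1, 11)]
    sub = f"(H1:{long},T1:{b}):{b}"
    for t in taxa[1:9]:
        sub = f"({sub},{t}:{b}):{b}"
    ingroup = f"({sub},(H2:{long},T10:{b}):{b})"
    groups = {t: "base" for t in taxa}
    groups["H1"] = groups["H2"] = "shifted"
    return OutgroupExperimentConfig(
        ingroup_tree=ingroup + ";",
        homoplastic_taxa=("H1", "H2"),
        groups=groups,
        group_freqs={
            "base": (0.35, 0.15, 0.15, 0.35),
            "shifted": (0.15, 0.35, 0.35, 0.15),
        },
        base_group="base",
        shifted_group="shifted",
        seq_length=seq_length,
        replicates=replicates,
        seed=seed,
    )
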