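"""Additive trees from distance matrices: neighbor joining, exact
least-squares branch lengths, and local topology search.

The workflow mirrors classic distance-based population phylogenetics: start
from the Saitou-Nei neighbor-joining tree (an approximate least-squares
fit), then solve the branch lengths of that topology *exactly* by ordinary
least squares on the path-length equations (each leaf pair's distance is
the sum of branch lengths on its path; the branch-incidence system is
solved by normal equations).  Nearby topologies are explored by
nearest-neighbor interchange (NNI), each refit by OLS and ranked by
residual sum of squares.  Negative fitted branch lengths are permitted and
counted — internal negative segments signal violations of the pure-drift
additive-tree assumption (e.g. admixed populations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DistanceMatrix",
    "Tree",
    "neighbor_joining",
    "ols_branch_lengths",
    "nni_neighbors",
    "explore_topologies",
    "TopologySearchResult",
    "random_binary_tree",
    "tree_distance_matrix",
    "write_phylip",
    "read_phylip",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    pair_locus_counts: np.ndarray | None = None  # loci used per pair

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.abs(m - m.T).max() > 1e-12:
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(m)).max() > 0:
            raise ValueError("diagonal not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels),
                              self.matrix[np.ix_(idx, idx)])


class Tree:
    """Unrooted tree over string-labelled leaves (internal nodes are ints).

    Edge attribute ``length`` carries the branch length (may be negative
    after least-squares fitting).
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.leaves = sorted(n for n in graph if isinstance(n, str))
        if len(self.leaves) < 2:
            raise ValueError("tree needs >= 2 leaves")
        for leaf in self.leaves:
            if graph.degree(leaf) != 1:
                raise ValueError(f"leaf {leaf!r} has degree "
                                 f"{graph.degree(leaf)}")

    # -- structure ---------------------------------------------------------
    @property
    def edges(self) -> list[tuple]:
        return sorted(
            (tuple(sorted(e, key=str)) for e in self.graph.edges),
            key=str)

    def is_binary(self) -> bool:
        internal = [n for n in self.graph if not isinstance(n, str)]
        return all(self.graph.degree(n) == 3 for n in internal) and \
            len(self.graph.edges) == 2 * len(self.leaves) - 3

    def copy(self) -> "Tree":
        return Tree(self.graph.copy())

    def split_of_edge(self, u, v) -> frozenset:
        """Leaves on the *u* side after cutting edge (u, v), canonicalized
        to the side not containing the smallest leaf."""
        g = self.graph.copy()
        g.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(g, u)
                if isinstance(n, str)}
        if self.leaves[0] in side:
            side = set(self.leaves) - side
        return frozenset(side)

    def splits(self) -> frozenset:
        """Canonical set of non-trivial splits: the topology identifier.

        Computed in one rooted traversal: each edge's far-from-root side is
        the descendant leaf set of its child node.
        """
        root = self.leaves[0]
        order = list(nx.dfs_postorder_nodes(self.graph, root))
        parent = nx.dfs_predecessors(self.graph, root)
        below: dict = {}
        out = set()
        n = len(self.leaves)
        for node in order:
            leaves = {node} if isinstance(node, str) else set()
            for child, p in parent.items():
                if p == node:
                    leaves |= below[child]
            below[node] = leaves
            if node != root and 1 < len(leaves) < n - 1:
                out.add(frozenset(leaves))
        return frozenset(out)

    # -- metrics -----------------------------------------------------------
    def leaf_paths(self) -> dict[tuple[str, str], list[tuple]]:
        """Edge path for every leaf pair (edges as sorted tuples)."""
        paths = {}
        for i, a in enumerate(self.leaves):
            node_paths = nx.single_source_shortest_path(self.graph, a)
            for b in self.leaves[i + 1:]:
                nodes = node_paths[b]
                paths[(a, b)] = [tuple(sorted((u, v), key=str))
                                 for u, v in zip(nodes, nodes[1:])]
        return paths

    def branch_lengths(self) -> dict[tuple, float]:
        return {tuple(sorted((u, v), key=str)): d["length"]
                for u, v, d in self.graph.edges(data=True)}

    def negative_branch_counts(self) -> tuple[int, int]:
        """(internal, external) count of negative branch lengths."""
        internal = external = 0
        for u, v, d in self.graph.edges(data=True):
            if d["length"] < 0:
                if isinstance(u, str) or isinstance(v, str):
                    external += 1
                else:
                    internal += 1
        return internal, external

    def total_path_matrix(self) -> DistanceMatrix:
        lengths = self.branch_lengths()
        n = len(self.leaves)
        m = np.zeros((n, n))
        for (a, b), path in self.leaf_paths().items():
            i, j = self.leaves.index(a), self.leaves.index(b)
            m[i, j] = m[j, i] = sum(lengths[e] for e in path)
        return DistanceMatrix(tuple(self.leaves), m)

    # -- serialization -----------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        """Newick string rooted arbitrarily at the internal node adjacent to
        the first leaf (full precision, negative lengths as-is)."""
        first = self.leaves[0]
        anchor = next(iter(self.graph[first]))

        def render(node, parent) -> str:
            children = [n for n in self.graph[node] if n != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{render(c, node)}:"
                f"{self.graph[node][c]['length']:.{precision}g}"
                for c in children)
            return f"({inner})"

        return render(anchor, None) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _tie_break_argmin(q: np.ndarray) -> tuple[int, int]:
    """Lowest-index (i < j) cell attaining the minimum of *q*."""
    best = np.min(q)
    cells = np.argwhere(q <= best + 0.0)
    for i, j in cells:
        if i < j:
            return int(i), int(j)
    i, j = cells[0]
    return (int(j), int(i)) if i > j else (int(i), int(j))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic lowest-index
    tie-breaking.  Requires n >= 2; n = 3 is the exact star resolution."""
    n = len(dm)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    g = nx.Graph()
    if n == 2:
        g.add_edge(dm.labels[0], dm.labels[1], length=float(dm.matrix[0, 1]))
        return Tree(g)
    nodes: list = list(dm.labels)
    d = dm.matrix.astype(float).copy()
    next_internal = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = _tie_break_argmin(q)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        u = next_internal
        next_internal += 1
        g.add_edge(nodes[i], u, length=float(li))
        g.add_edge(nodes[j], u, length=float(lj))
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([np.column_stack([d[np.ix_(keep, keep)],
                                        dnew[keep]]),
                       np.append(dnew[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [u]
    # resolve the final star of three
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    center = next_internal
    g.add_edge(a, center, length=float((dab + dac - dbc) / 2))
    g.add_edge(b, center, length=float((dab + dbc - dac) / 2))
    g.add_edge(c, center, length=float((dac + dbc - dab) / 2))
    return Tree(g)


@dataclass
class OLSFit:
    tree: Tree
    residual_ss: float
    n_negative_internal: int
    n_negative_external: int


def ols_branch_lengths(tree: Tree, dm: DistanceMatrix) -> OLSFit:
    """Exact (unweighted) least-squares branch lengths for a fixed topology.

    Solves the linear path-length system ``A x = d`` (one row per leaf
    pair, one column per branch, entries 0/1 for path membership) by least
    squares; raises on a rank-deficient system.
    """
    if set(tree.leaves) != set(dm.labels):
        raise ValueError("tree leaves do not match matrix labels")
    paths = tree.leaf_paths()
    edges = tree.edges
    edge_index = {e: k for k, e in enumerate(edges)}
    pairs = sorted(paths)
    a = np.zeros((len(pairs), len(edges)))
    y = np.empty(len(pairs))
    for row, (p, q) in enumerate(pairs):
        for e in paths[(p, q)]:
            a[row, edge_index[e]] = 1.0
        y[row] = dm.value(p, q)
    x, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
    if rank < len(edges):
        raise ValueError("degenerate topology: branch-incidence system "
                         "is singular")
    fitted = tree.copy()
    for e, length in zip(edges, x):
        fitted.graph.edges[e]["length"] = float(length)
    resid = y - a @ x
    internal, external = fitted.negative_branch_counts()
    return OLSFit(fitted, float(resid @ resid), internal, external)


def nni_neighbors(tree: Tree) -> list[Tree]:
    """The two nearest-neighbor-interchange rearrangements of every
    internal edge."""
    out = []
    for u, v in list(tree.graph.edges):
        if isinstance(u, str) or isinstance(v, str):
            continue
        u_side = [n for n in tree.graph[u] if n != v]
        v_side = [n for n in tree.graph[v] if n != u]
        a = u_side[0]
        for c in v_side:
            g = tree.graph.copy()
            g.remove_edge(a, u)
            g.remove_edge(c, v)
            g.add_edge(a, v, length=0.0)
            g.add_edge(c, u, length=0.0)
            out.append(Tree(g))
    return out


@dataclass
class TopologySearchResult:
    n_evaluated: int
    n_no_negative_internal: int
    ranked: list[OLSFit] = field(repr=False)

    @property
    def best(self) -> OLSFit:
        return self.ranked[0]

    @property
    def best_without_negative_internal(self) -> OLSFit | None:
        for fit in self.ranked:
            if fit.n_negative_internal == 0:
                return fit
        return None


def explore_topologies(start: Tree, dm: DistanceMatrix,
                       radius: int = 1) -> TopologySearchResult:
    """Fit all topologies within *radius* NNI steps of *start* (inclusive),
    deduplicated by canonical split sets, ranked by residual SSQ."""
    seen: dict[frozenset, Tree] = {start.splits(): start}
    frontier = [start]
    for _ in range(radius):
        nxt = []
        for t in frontier:
            for neigh in nni_neighbors(t):
                key = neigh.splits()
                if key not in seen:
                    seen[key] = neigh
                    nxt.append(neigh)
        frontier = nxt
        if not frontier:
            break
    fits = [ols_branch_lengths(t, dm) for t in seen.values()]
    fits.sort(key=lambda f: f.residual_ss)
    return TopologySearchResult(
        n_evaluated=len(fits),
        n_no_negative_internal=sum(
            1 for f in fits if f.n_negative_internal == 0),
        ranked=fits,
    )


# -- utilities for simulation and testing ----------------------------------

def random_binary_tree(labels: list[str],
                       rng: np.random.Generator | int = 0,
                       length_low: float = 0.05,
                       length_high: float = 1.0) -> Tree:
    """Random unrooted binary tree with positive branch lengths (built by
    sequential random leaf attachment)."""
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def rand_len() -> float:
        return float(rng.uniform(length_low, length_high))

    g = nx.Graph()
    g.add_edge(labels[0], 0, length=rand_len())
    g.add_edge(labels[1], 0, length=rand_len())
    g.add_edge(labels[2], 0, length=rand_len())
    next_internal = 1
    for label in labels[3:]:
        u, v = list(g.edges)[rng.integers(len(g.edges))]
        length = g.edges[u, v]["length"]
        w = next_internal
        next_internal += 1
        g.remove_edge(u, v)
        split = float(rng.uniform(0.25, 0.75)) * length
        g.add_edge(u, w, length=split)
        g.add_edge(v, w, length=length - split)
        g.add_edge(label, w, length=rand_len())
    return Tree(g)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Additive (path-length) distance matrix of a tree."""
    return tree.total_path_matrix()


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix format."""
    lines = [f"    {len(dm)}"]
    for label, row in zip(dm.labels, dm.matrix):
        name = label[:10].ljust(10)
        lines.append(name + "  ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0].strip())
    labels, rows = [], []
    for line in text[1:n + 1]:
        labels.append(line[:10].strip())
        rows.append([float(v) for v in line[10:].split()])
    return DistanceMatrix(tuple(labels), np.array(rows))
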