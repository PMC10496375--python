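"""Unrooted phylogenetic trees: construction, Newick round-trip, neighbor
joining, Robinson-Foulds distance and nearest-neighbor-interchange moves.

Trees are stored as an undirected adjacency map with branch lengths in
expected substitutions per site. Leaves are nodes ``0..n-1`` in the order
of :attr:`Tree.taxa`; internal nodes follow. For ``n >= 3`` taxa the tree
is unrooted (every internal node has degree 3); two taxa degenerate to a
single internal node of degree 2 so that likelihood code can treat the
pair as one path.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field


@dataclass
class Tree:
    taxa: list[str]
    #: node -> {neighbor: branch length}
    adj: dict[int, dict[int, float]] = field(default_factory=dict)

    # -- basics -------------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def leaf_id(self, label: str) -> int:
        return self.taxa.index(label)

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in sorted(self.adj):
            for v, t in sorted(self.adj[u].items()):
                if u < v:
                    out.append((u, v, t))
        return out

    def internal_edges(self) -> list[tuple[int, int]]:
        n = self.n_leaves
        return [(u, v) for u, v, _ in self.edges() if u >= n and v >= n]

    def copy(self) -> "Tree":
        return Tree(list(self.taxa), {u: dict(nb) for u, nb in self.adj.items()})

    def set_length(self, u: int, v: int, t: float) -> None:
        self.adj[u][v] = t
        self.adj[v][u] = t

    def total_length(self) -> float:
        return sum(t for _, _, t in self.edges())

    def validate(self) -> None:
        n = self.n_leaves
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels")
        for u, nb in self.adj.items():
            deg = len(nb)
            if u < n and deg != 1:
                raise ValueError(f"leaf {u} has degree {deg}")
            if u >= n and n >= 3 and deg != 3:
                raise ValueError(f"internal node {u} has degree {deg}")

    # -- traversal ----------------------------------------------------------

    def default_root(self) -> int:
        """Deterministic pruning root: the internal neighbor of leaf 0."""
        if self.n_leaves == 1:
            return 0
        return next(iter(self.adj[0]))

    def postorder(self, root: int | None = None) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents; root last with
        parent -1."""
        root = self.default_root() if root is None else root
        out, stack = [], [(root, -1)]
        while stack:
            node, parent = stack.pop()
            out.append((node, parent))
            for nb in sorted(self.adj[node]):
                if nb != parent:
                    stack.append((nb, node))
        out.reverse()
        return out

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Patristic distances between all leaf pairs."""
        import heapq

        dists = {}
        for i in range(self.n_leaves):
            seen = {i: 0.0}
            heap = [(0.0, i)]
            while heap:
                d, u = heapq.heappop(heap)
                if d > seen.get(u, float("inf")):
                    continue
                for v, t in self.adj[u].items():
                    nd = d + t
                    if nd < seen.get(v, float("inf")):
                        seen[v] = nd
                        heapq.heappush(heap, (nd, v))
            for j in range(self.n_leaves):
                dists[(self.taxa[i], self.taxa[j])] = seen[j]
        return dists

    # -- bipartitions / RF ---------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side *not*
        containing the lexicographically smallest taxon."""
        anchor = min(self.taxa)
        splits = set()
        for u, v in self.internal_edges():
            side = self._leafset_below(v, u)
            labels = frozenset(self.taxa[i] for i in side)
            if anchor in labels:
                labels = frozenset(self.taxa) - labels
            if 1 < len(labels) < self.n_leaves - 1:
                splits.add(labels)
        return splits

    def _leafset_below(self, node: int, parent: int) -> set[int]:
        out, stack = set(), [(node, parent)]
        while stack:
            nd, pa = stack.pop()
            if nd < self.n_leaves:
                out.add(nd)
            for nb in self.adj[nd]:
                if nb != pa:
                    stack.append((nb, nd))
        return out


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if set(t1.taxa) != set(t2.taxa):
        raise ValueError("trees have different taxon sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


# -- Newick -----------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|,|;|:[-0-9.eE+]+|[^():,;]+")


def _parse_newick(text: str):
    """Minimal recursive-descent Newick reader (labels + branch lengths)."""
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick string")
    tokens = _TOKEN.findall(text.strip())
    pos = 0

    def parse_clade():
        nonlocal pos
        children = []
        if tokens[pos] == "(":
            pos += 1
            while True:
                children.append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise ValueError("malformed Newick string")
        label = None
        length = None
        while pos < len(tokens) and tokens[pos] not in {",", ")", ";"}:
            tok = tokens[pos]
            if tok.startswith(":"):
                length = float(tok[1:])
            else:
                label = tok.strip()
            pos += 1
        return (label, length, children)

    clade = parse_clade()
    if pos >= len(tokens) or tokens[pos] != ";":
        raise ValueError("Newick string must end with ';'")
    return clade


class _NodeCounter:
    def __init__(self, start: int):
        self.next = start

    def take(self) -> int:
        v = self.next
        self.next += 1
        return v


def tree_from_newick(text: str) -> Tree:
    clade = _parse_newick(text)

    labels: list[str] = []

    def collect(c):
        label, _, children = c
        if not children:
            labels.append(label)
        for ch in children:
            collect(ch)

    collect(clade)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate taxon labels in Newick string")

    tree = Tree(taxa=labels, adj={i: {} for i in range(len(labels))})
    counter = _NodeCounter(len(labels))

    def build(c) -> tuple[int, float | None]:
        label, length, children = c
        if not children:
            return labels.index(label), length
        node = counter.take()
        tree.adj.setdefault(node, {})
        for ch in children:
            cid, clen = build(ch)
            t = 0.0 if clen is None else clen
            tree.adj[node][cid] = t
            tree.adj.setdefault(cid, {})[node] = t
        return node, length

    root, _ = build(clade)
    # suppress a degree-2 root so the tree is genuinely unrooted
    if len(tree.adj[root]) == 2 and len(labels) >= 3:
        (a, ta), (b, tb) = tree.adj[root].items()
        del tree.adj[a][root]
        del tree.adj[b][root]
        del tree.adj[root]
        tree.adj[a][b] = ta + tb
        tree.adj[b][a] = ta + tb
    return tree


def tree_to_newick(tree: Tree) -> str:
    root = tree.default_root()
    buf = io.StringIO()

    def write(node: int, parent: int) -> str:
        if node < tree.n_leaves:
            return tree.taxa[node]
        kids = sorted(
            (nb for nb in tree.adj[node] if nb != parent),
            key=lambda nb: min(tree._leafset_below(nb, node)),
        )
        inner = ",".join(f"{write(k, node)}:{tree.adj[node][k]:.12g}" for k in kids)
        return f"({inner})"

    buf.write(write(root, -1))
    buf.write(";")
    return buf.getvalue()


Tree.from_newick = staticmethod(tree_from_newick)  # type: ignore[attr-defined]
Tree.to_newick = tree_to_newick  # type: ignore[attr-defined]


# -- construction helpers ----------------------------------------------------

def star_tree(taxa: list[str], length: float = 0.1) -> Tree:
    n = len(taxa)
    adj: dict[int, dict[int, float]] = {n: {}}
    for i in range(n):
        adj[i] = {n: length}
        adj[n][i] = length
    return Tree(list(taxa), adj)


def random_topology(taxa: list[str], rng, internal_length: float = 0.1,
                    terminal_length: float = 0.1) -> Tree:
    """Uniform-ish random unrooted binary topology by sequential addition."""
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        return Tree(list(taxa), {
            0: {2: terminal_length}, 1: {2: terminal_length},
            2: {0: terminal_length, 1: terminal_length},
        })
    tree = Tree(list(taxa), {})
    c = _NodeCounter(n)
    v = c.take()
    tree.adj = {v: {}}
    for i in range(3):
        tree.adj[i] = {v: terminal_length}
        tree.adj[v][i] = terminal_length
    for i in range(3, n):
        edges = tree.edges()
        u, w, t = edges[rng.integers(len(edges))]
        mid = c.take()
        del tree.adj[u][w]
        del tree.adj[w][u]
        tree.adj[mid] = {u: t / 2, w: t / 2, i: terminal_length}
        tree.adj[u][mid] = t / 2
        tree.adj[w][mid] = t / 2
        tree.adj[i] = {mid: terminal_length}
    for u, v_ in tree.internal_edges():
        tree.set_length(u, v_, internal_length)
    return tree


# -- neighbor joining --------------------------------------------------------

def nj_tree(dist, labels: list[str]) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    ``dist`` is a symmetric (n, n) matrix of pairwise distances in the
    order of ``labels``. Ties in the Q criterion are broken toward the
    pair whose smallest member label sorts first.
    """
    import numpy as np

    D = np.asarray(dist, dtype=float).copy()
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    tree = Tree(list(labels), {i: {} for i in range(n)})
    c = _NodeCounter(n)
    active = list(range(n))  # indices into D rows; node id of each cluster
    node_of = {i: i for i in range(n)}
    min_label = {i: labels[i] for i in range(n)}

    def join(i, j, li, lj):
        nid = c.take()
        tree.adj[nid] = {}
        a, b = node_of[i], node_of[j]
        tree.adj[nid][a] = max(li, 0.0)
        tree.adj.setdefault(a, {})[nid] = max(li, 0.0)
        tree.adj[nid][b] = max(lj, 0.0)
        tree.adj.setdefault(b, {})[nid] = max(lj, 0.0)
        return nid

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = [
            (min(min_label[active[i]], min_label[active[j]]),
             max(min_label[active[i]], min_label[active[j]]), i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] <= qmin + 1e-12
        ]
        _, _, i, j = min(cand)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        nid = join(ai, aj, li, lj)
        # distances of the new cluster
        new_d = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = new_d
        D[active, -1] = new_d
        D[-1, -1] = 0.0
        new_idx = D.shape[0] - 1
        node_of[new_idx] = nid
        min_label[new_idx] = min(min_label[ai], min_label[aj])
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    if len(active) == 3:
        i, j, k = active
        hub = c.take()
        tree.adj[hub] = {}
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            a = node_of[idx]
            tree.adj[hub][a] = max(ln, 0.0)
            tree.adj.setdefault(a, {})[hub] = max(ln, 0.0)
    elif len(active) == 2:
        i, j = active
        a, b = node_of[i], node_of[j]
        t = max(D[i, j], 0.0)
        tree.adj.setdefault(a, {})[b] = t
        tree.adj.setdefault(b, {})[a] = t
    return tree


# -- NNI ---------------------------------------------------------------------

def nni_neighbors(tree: Tree, edge: tuple[int, int]) -> list[Tree]:
    """The two topologies one NNI move away across an internal edge.

    Across edge (u, v) with u-side subtrees {a, b} and v-side {c, d}, the
    rearrangements swap b with c and b with d. Subtree order is by node id
    so the move set is deterministic.
    """
    u, v = edge
    if u < tree.n_leaves or v < tree.n_leaves:
        raise ValueError("NNI edge must be internal")
    a, b = sorted(nb for nb in tree.adj[u] if nb != v)
    c, d = sorted(nb for nb in tree.adj[v] if nb != u)
    out = []
    for x, y in ((b, c), (b, d)):
        t = tree.copy()
        tx, ty = t.adj[u].pop(x), t.adj[v].pop(y)
        del t.adj[x][u]
        del t.adj[y][v]
        t.adj[u][y] = ty
        t.adj[y][u] = ty
        t.adj[v][x] = tx
        t.adj[x][v] = tx
        out.append(t)
    return out
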