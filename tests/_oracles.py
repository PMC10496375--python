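"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: exhaustive enumeration, plain recursion, or
an unrelated library, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

# -- affine-bulge alignment by complete search --------------------------------

MATCH_COLS = {("A", "A"), ("C", "C"), ("G", "G"), ("T", "T")}
WOBBLE_COLS = {("G", "A"), ("A", "G"), ("T", "C"), ("C", "T")}


def _col(a, b, match, wobble, mismatch):
    if (a, b) in MATCH_COLS:
        return match
    if (a, b) in WOBBLE_COLS:
        return wobble
    return mismatch


def best_alignment_score(x: str, y: str, match=1.0, wobble=0.5, mismatch=-1.0,
                         bulge_open=-2.0, bulge_extend=-0.5) -> float:
    """Maximum score over all monotone alignments of x and y, by top-down
    complete search over moves with memoization on (i, j, last move).

    A run of L same-side gaps costs bulge_open + (L-1) * bulge_extend.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, last: str) -> float:
        if i == len(x) and j == len(y):
            return 0.0
        best = -np.inf
        if i < len(x) and j < len(y):
            best = max(best,
                       _col(x[i], y[j], match, wobble, mismatch)
                       + go(i + 1, j + 1, "M"))
        if i < len(x):
            cost = bulge_extend if last == "X" else bulge_open
            best = max(best, cost + go(i + 1, j, "X"))
        if j < len(y):
            cost = bulge_extend if last == "Y" else bulge_open
            best = max(best, cost + go(i, j + 1, "Y"))
        return best

    out = go(0, 0, "M")
    go.cache_clear()
    return out


def brute_alignment_score(x: str, y: str, **params) -> float:
    """Literal enumeration of every alignment as a move string (tiny
    inputs only); validates :func:`best_alignment_score` itself."""
    m, n = len(x), len(y)
    best = -np.inf
    match = params.get("match", 1.0)
    wobble = params.get("wobble", 0.5)
    mismatch = params.get("mismatch", -1.0)
    bo = params.get("bulge_open", -2.0)
    be = params.get("bulge_extend", -0.5)
    # k = number of paired columns; enumerate all interleavings of
    # k P's, (m-k) X's and (n-k) Y's
    for k in range(0, min(m, n) + 1):
        for seq in set(itertools.permutations("P" * k + "X" * (m - k)
                                              + "Y" * (n - k))):
            i = j = 0
            score = 0.0
            last = "M"
            for mv in seq:
                if mv == "P":
                    score += _col(x[i], y[j], match, wobble, mismatch)
                    i += 1
                    j += 1
                    last = "M"
                elif mv == "X":
                    score += be if last == "X" else bo
                    i += 1
                    last = "X"
                else:
                    score += be if last == "Y" else bo
                    j += 1
                    last = "Y"
            best = max(best, score)
    return best


# -- edit distance by plain recursion -----------------------------------------

def levenshtein_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(
            go(i + 1, j) + 1,
            go(i, j + 1) + 1,
            go(i + 1, j + 1) + (a[i] != b[j]),
        )

    out = go(0, 0)
    go.cache_clear()
    return out


# -- pruning likelihood by summation over internal states ---------------------

def enumeration_lnL(tree, aln: dict[str, str], model) -> float:
    """Sum the joint probability over all internal-node state
    assignments, site by site."""
    from virago.phylo.likelihood import NT_INDEX

    order = tree.postorder()
    root = order[-1][0]
    internals = [n for n in tree.adj if n >= tree.n_leaves]
    n_sites = len(next(iter(aln.values())))
    P = {(u, v): model.P(t) for u, v, t in tree.edges()}
    P.update({(v, u): model.P(t) for u, v, t in tree.edges()})
    total = 0.0
    for s in range(n_sites):
        site_p = 0.0
        leaf_states = {
            i: NT_INDEX.get(aln[tree.taxa[i]][s].upper(), 4)
            for i in range(tree.n_leaves)
        }
        leaf_choices = [
            [leaf_states[i]] if leaf_states[i] != 4 else [0, 1, 2, 3]
            for i in range(tree.n_leaves)
        ]
        for leaf_assign in itertools.product(*leaf_choices):
            for states in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, states))
                for i, a in enumerate(leaf_assign):
                    st[i] = a
                pr = model.freqs[st[root]]
                for u, v, _ in tree.edges():
                    pr *= P[(u, v)][st[u], st[v]]
                site_p += pr
        total += np.log(site_p)
    return total


def all_topologies(taxa: list[str]):
    """Every unrooted binary topology on the given taxa, by recursive
    leaf insertion."""
    from virago.phylo.tree import Tree

    n = len(taxa)
    base = Tree(list(taxa), {})
    hub = n
    base.adj = {hub: {}}
    for i in range(3):
        base.adj[i] = {hub: 0.1}
        base.adj[hub][i] = 0.1
    trees = [base]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for t in trees:
            for u, v, ln in t.edges():
                c = t.copy()
                mid = next_internal + (leaf - 3)  # unique enough per level
                mid = max(c.adj) + 1
                del c.adj[u][v]
                del c.adj[v][u]
                c.adj[mid] = {u: ln / 2, v: ln / 2, leaf: 0.1}
                c.adj[u][mid] = ln / 2
                c.adj[v][mid] = ln / 2
                c.adj[leaf] = {mid: 0.1}
                new_trees.append(c)
        trees = new_trees
    return trees


# -- RF distance via bipartition sets and dendropy ----------------------------

def rf_dendropy(newick1: str, newick2: str) -> int:
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick",
                           taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


# -- exact binomial CI by direct tail inversion -------------------------------

def clopper_pearson_search(k: int, n: int, conf=0.95, grid=200001):
    """Invert the binomial tails on a dense grid of p values."""
    from scipy.stats import binom

    alpha = 1 - conf
    ps = np.linspace(0.0, 1.0, grid)
    # lower limit: largest p with P(X >= k | p) <= alpha/2
    if k == 0:
        lo = 0.0
    else:
        tail = binom.sf(k - 1, n, ps)
        lo = ps[np.searchsorted(tail, alpha / 2, side="left")]
    if k == n:
        hi = 1.0
    else:
        tail = binom.cdf(k, n, ps)
        idx = np.searchsorted(-tail, -(alpha / 2), side="right")
        hi = ps[min(idx, grid - 1)]
    return float(lo), float(hi)


# -- naive motif scan ----------------------------------------------------------

def naive_motif_hits(seq: str, motif: str, max_offset: int):
    """Position-by-position scan for a motif near either end, both
    strands."""
    from virago.genome import revcomp

    seq = seq.upper()
    hits = set()
    m = len(motif)
    for probe, orient in ((motif.upper(), "fwd"), (revcomp(motif), "rc")):
        for start in range(len(seq) - m + 1):
            if seq[start : start + m] == probe:
                if start <= max_offset:
                    hits.add(("5p", orient, start))
                end_off = len(seq) - (start + m)
                if end_off <= max_offset:
                    hits.add(("3p", orient, end_off))
    return hits
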