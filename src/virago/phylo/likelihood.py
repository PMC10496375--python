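"""Maximum-likelihood machinery: substitution models, Felsenstein pruning,
branch-length optimization and NNI topology search.

Models are time-reversible nucleotide models (JC, K80, GTR) with rate
matrices normalized to one expected substitution per site per unit branch
length. Likelihoods are computed over compressed site patterns with
per-node rescaling, so alignments of arbitrary length cost only as much
as their number of distinct columns.

Branch lengths are optimized coordinate-wise. For a single branch the
per-pattern site likelihood is a small exponential sum

    s_p(t) = sum_k c_pk * exp(lambda_k * t)

whose coefficients come from the conditional likelihoods on the two sides
of the branch and the spectral decomposition of the rate matrix; Brent
search on t then needs no tree traversals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import _jc
from .tree import Tree, nj_tree, nni_neighbors

NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MISSING = 4  # N, gaps, ambiguity codes
MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0


# -- models ------------------------------------------------------------------

@dataclass
class Model:
    """A reversible rate matrix in spectral form (Q = V diag(lam) W)."""

    name: str
    freqs: np.ndarray
    rates: np.ndarray  # upper-triangle exchangeabilities AC, AG, AT, CG, CT, GT
    lam: np.ndarray
    V: np.ndarray
    W: np.ndarray

    def P(self, t: float) -> np.ndarray:
        return (self.V * np.exp(self.lam * t)) @ self.W

    def with_rates(self, rates, freqs=None) -> "Model":
        return make_model(self.name, rates=rates,
                          freqs=self.freqs if freqs is None else freqs)


def _build_Q(rates: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    S[iu] = rates
    S = S + S.T
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(freqs * np.diag(Q)).sum()
    return Q / scale


def make_model(name: str = "JC", kappa: float = 2.0,
               rates=None, freqs=None) -> Model:
    """Build a JC, K80(kappa) or GTR(rates, freqs) model.

    GTR exchangeabilities are ordered AC, AG, AT, CG, CT, GT; the last is
    conventionally fixed to 1 when optimizing.
    """
    name = name.upper()
    if name == "JC":
        rates = np.ones(6)
        freqs = np.full(4, 0.25)
    elif name in {"K80", "K2P"}:
        rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        freqs = np.full(4, 0.25)
        name = "K80"
    elif name == "GTR":
        if rates is None:
            rates = np.ones(6)
        rates = np.asarray(rates, dtype=float)
        freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    else:
        raise ValueError(f"unknown model {name!r}")
    if np.any(rates <= 0):
        raise ValueError("exchangeability rates must be positive")
    if abs(freqs.sum() - 1) > 1e-8 or np.any(freqs <= 0):
        raise ValueError("frequencies must be a positive simplex")
    Q = _build_Q(rates, freqs)
    # symmetrize for a stable eigendecomposition: B = D^1/2 Q D^-1/2
    rt = np.sqrt(freqs)
    B = (Q * rt[None, :]) / rt[:, None]
    lam, U = np.linalg.eigh((B + B.T) / 2)
    V = U / rt[:, None]
    W = U.T * rt[None, :]
    return Model(name=name, freqs=freqs, rates=rates, lam=lam, V=V, W=W)


# -- alignments --------------------------------------------------------------

@dataclass
class PatternData:
    """Site-pattern-compressed alignment."""

    taxa: list[str]
    codes: np.ndarray   # (n_taxa, n_patterns) int8, 4 = missing
    weights: np.ndarray  # (n_patterns,) pattern multiplicities
    n_sites: int

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]


def patterns_from_codes(taxa: list[str], mat: np.ndarray) -> PatternData:
    """Compress a (n_taxa, n_sites) code matrix into site patterns.

    For up to 27 taxa, columns are packed into base-5 integer keys so the
    unique step is a single integer sort.
    """
    n, n_sites = mat.shape
    if n <= 27:
        powers = 5 ** np.arange(n, dtype=np.int64)
        keys = powers @ mat.astype(np.int64)
        _, idx, counts = np.unique(keys, return_index=True, return_counts=True)
        pats = mat[:, idx]
    else:
        pats, counts = np.unique(mat, axis=1, return_counts=True)
    return PatternData(taxa=list(taxa), codes=np.ascontiguousarray(pats),
                       weights=counts.astype(float), n_sites=n_sites)


def encode_alignment(aln: dict[str, str]) -> PatternData:
    """Compress an aligned ``{taxon: sequence}`` mapping into site patterns."""
    taxa = list(aln)
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (n_sites,) = lengths
    mat = np.full((len(taxa), n_sites), MISSING, dtype=np.int8)
    for i, t in enumerate(taxa):
        arr = np.frombuffer(aln[t].upper().encode(), dtype=np.uint8)
        for ch, code in NT_INDEX.items():
            mat[i, arr == ord(ch)] = code
    return patterns_from_codes(taxa, mat)


_LEAF_ONEHOT = np.vstack([np.eye(4), np.ones(4)])


def _leaf_partial(codes_row: np.ndarray) -> np.ndarray:
    return _LEAF_ONEHOT[codes_row]


# -- pruning -----------------------------------------------------------------

def _check_taxa(tree: Tree, data: PatternData) -> np.ndarray:
    if set(tree.taxa) != set(data.taxa):
        raise ValueError(
            f"tree taxa {sorted(tree.taxa)} do not match alignment taxa "
            f"{sorted(data.taxa)}"
        )
    rows = np.array([data.taxa.index(t) for t in tree.taxa])
    return rows


def _postorder_partials(tree: Tree, data: PatternData, model: Model,
                        order=None):
    """Conditional likelihoods for every node, with per-node log rescaling.

    Returns (partials, scale_logs, order): ``partials[node]`` is (P, 4),
    ``scale_logs`` is the summed per-pattern log scale factors.
    """
    rows = _check_taxa(tree, data)
    if order is None:
        order = tree.postorder()
    P_pat = data.n_patterns
    partials: dict[int, np.ndarray] = {}
    scale = np.zeros(P_pat)
    for node, parent in order:
        if node < tree.n_leaves:
            partials[node] = _leaf_partial(data.codes[rows[node]])
            continue
        acc = np.ones((P_pat, 4))
        for child in tree.adj[node]:
            if child == parent:
                continue
            Pm = model.P(tree.adj[node][child])
            acc = acc * (partials[child] @ Pm.T)
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        scale += np.log(mx)
        partials[node] = acc / mx[:, None]
    return partials, scale, order


def pruning_lnL(tree: Tree, data, model: Model | str = "JC") -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree.

    ``data`` may be an aligned ``{taxon: seq}`` mapping or a
    :class:`PatternData`. Site patterns are compressed and partials are
    rescaled per node, keeping the computation stable for branch lengths
    up to 10 substitutions/site.
    """
    if isinstance(model, str):
        model = make_model(model)
    if isinstance(data, dict):
        data = encode_alignment(data)
    if tree.n_leaves == 1:
        return float(np.sum(data.weights * np.log(0.25)))
    if model.name == "JC":
        _check_taxa(tree, data)
        return _jc.jc_lnl(tree, data)
    partials, scale, order = _postorder_partials(tree, data, model)
    root = order[-1][0]
    site = partials[root] @ model.freqs
    return float(np.sum(data.weights * (np.log(site) + scale)))


# -- branch-length optimization ----------------------------------------------

def _edge_coefficients(G: np.ndarray, D: np.ndarray, model: Model):
    """Spectral coefficients c_pk with s_p(t) = sum_k c_pk exp(lam_k t)."""
    return (G @ model.V) * (D @ model.W.T)


def _optimize_edge(coef: np.ndarray, weights: np.ndarray, lam: np.ndarray,
                   t0: float) -> tuple[float, float]:
    def neg(t):
        s = coef @ np.exp(lam * t)
        if np.any(s <= 0):
            return np.inf
        return -float(weights @ np.log(s))

    res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                          method="bounded", options={"xatol": 1e-7})
    t_new, f_new = float(res.x), float(res.fun)
    if neg(t0) < f_new:  # never accept a worse point than the current one
        return t0, -neg(t0)
    return t_new, -f_new


def optimize_branch_lengths(tree: Tree, data, model: Model | str = "JC",
                            tol: float = 1e-6, max_sweeps: int = 50):
    """Coordinate-wise ML branch lengths on a fixed topology.

    Edges are swept in post-order; each branch is optimized by bounded
    Brent search on its exponential-sum site likelihood. Sweeps repeat
    until the total log-likelihood improves by less than ``tol``. Returns
    ``(tree, lnL, converged)`` with the tree modified in place.
    """
    if isinstance(model, str):
        model = make_model(model)
    if isinstance(data, dict):
        data = encode_alignment(data)
    if model.name == "JC":
        _check_taxa(tree, data)
        return _jc.jc_optimize_branch_lengths(tree, data, tol=tol,
                                              max_sweeps=max_sweeps)
    best = pruning_lnL(tree, data, model)
    converged = False
    for _ in range(max_sweeps):
        _sweep_edges(tree, data, model)
        cur = pruning_lnL(tree, data, model)
        if cur - best < tol:
            converged = cur >= best - 1e-9
            best = max(best, cur)
            break
        best = cur
    return tree, best, converged


def _sweep_edges(tree: Tree, data: PatternData, model: Model) -> None:
    order = tree.postorder()
    partials, scale, _ = _postorder_partials(tree, data, model, order)
    root = order[-1][0]
    n_pat = data.n_patterns
    # preorder "rest-of-tree" partials F[node]: conditional of everything
    # outside the subtree under `node`, as seen at `node` (freqs folded in
    # at the root)
    F: dict[int, np.ndarray] = {root: np.broadcast_to(model.freqs, (n_pat, 4)).copy()}
    child_contrib: dict[tuple[int, int], np.ndarray] = {}
    for node, parent in reversed(order):  # preorder
        kids = [k for k in tree.adj[node] if k != parent]
        for k in kids:
            child_contrib[(node, k)] = partials[k] @ model.P(tree.adj[node][k]).T
        for k in kids:
            G = F[node].copy()
            for other in kids:
                if other != k:
                    G *= child_contrib[(node, other)]
            # optimize the edge (node, k) while G and partials[k] are fresh
            coef = _edge_coefficients(G, partials[k], model)
            t_new, _ = _optimize_edge(coef, data.weights, model.lam,
                                      tree.adj[node][k])
            tree.set_length(node, k, t_new)
            child_contrib[(node, k)] = partials[k] @ model.P(t_new).T
            F[k] = G @ model.P(t_new)


# -- distances and tree search -----------------------------------------------

def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites over ungapped, unambiguous columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    a = np.frombuffer(seq_a.upper().encode(), np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), np.uint8)
    valid = np.isin(a, [65, 67, 71, 84]) & np.isin(b, [65, 67, 71, 84])
    if valid.sum() == 0:
        return 0.0
    return float((a[valid] != b[valid]).mean())


def jc_distance(seq_a: str, seq_b: str, pair: tuple[str, str] | None = None
                ) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3); saturated pairs are
    rejected."""
    p = p_distance(seq_a, seq_b)
    if p >= 0.75:
        name = f" {pair[0]}-{pair[1]}" if pair else ""
        raise ValueError(
            f"pair{name} is saturated (p-distance {p:.3f} >= 0.75); "
            "JC correction undefined"
        )
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def _pattern_p_distance(data: PatternData, i: int, j: int) -> float:
    a, b = data.codes[i], data.codes[j]
    valid = (a < 4) & (b < 4)
    den = float(data.weights[valid].sum())
    if den == 0:
        return 0.0
    num = float(data.weights[valid & (a != b)].sum())
    return num / den


def jc_distance_matrix(aln):
    """JC distance matrix from an alignment dict or PatternData."""
    data = aln if isinstance(aln, PatternData) else encode_alignment(aln)
    labels = list(data.taxa)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pattern_p_distance(data, i, j)
            if p >= 0.75:
                raise ValueError(
                    f"pair {labels[i]}-{labels[j]} is saturated "
                    f"(p-distance {p:.3f} >= 0.75); JC correction undefined"
                )
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D, labels


def nj_start_tree(data_or_aln) -> Tree:
    D, labels = jc_distance_matrix(data_or_aln)
    tree = nj_tree(D, labels)
    for u, v, t in tree.edges():
        tree.set_length(u, v, min(max(t, MIN_BRANCH), MAX_BRANCH))
    return tree


def nni_search(tree: Tree, data, model: Model | str = "JC",
               tol: float = 1e-6, max_rounds: int = 20):
    """NNI hill climbing from a starting tree.

    Each round scores both rearrangements of every internal edge (one
    branch-length sweep each) and applies the single best improving move;
    the search stops when no move improves the log-likelihood by more
    than ``tol``. Deterministic given the input tree.
    Returns (tree, lnL).
    """
    if isinstance(model, str):
        model = make_model(model)
    if isinstance(data, dict):
        data = encode_alignment(data)
    tree, best, _ = optimize_branch_lengths(tree, data, model)
    jc = model.name == "JC"
    for _ in range(max_rounds):
        best_cand, best_lnL = None, best
        for edge in tree.internal_edges():
            for cand in nni_neighbors(tree, edge):
                if jc:
                    lnL = _jc.jc_sweep_once(cand, data)
                else:
                    _sweep_edges(cand, data, model)
                    lnL = pruning_lnL(cand, data, model)
                if lnL > best_lnL + tol:
                    best_cand, best_lnL = cand, lnL
        if best_cand is None:
            break
        tree = best_cand
        tree, best, _ = optimize_branch_lengths(tree, data, model)
    return tree, best


def ml_tree(aln, model: Model | str = "JC", start: Tree | None = None):
    """NJ starting tree, branch-length optimization and NNI search.

    ``aln`` may be an aligned ``{taxon: seq}`` mapping or a
    :class:`PatternData`.
    """
    data = aln if isinstance(aln, PatternData) else encode_alignment(aln)
    if isinstance(model, str):
        model = make_model(model)
    tree = nj_start_tree(data) if start is None else start.copy()
    return nni_search(tree, data, model)


# -- model parameter fitting (K80 / GTR) --------------------------------------

def optimize_model_parameters(tree: Tree, data, model: Model,
                              rounds: int = 2):
    """Alternate branch-length sweeps with exchangeability updates.

    K80 optimizes kappa by Brent; GTR optimizes the five free
    exchangeabilities (GT fixed at 1) by Nelder-Mead on the log scale.
    JC has no free parameters. Returns (tree, model, lnL).
    """
    if isinstance(data, dict):
        data = encode_alignment(data)
    if model.name == "JC":
        tree, lnL, _ = optimize_branch_lengths(tree, data, model)
        return tree, model, lnL
    from scipy.optimize import minimize

    lnL = None
    for _ in range(rounds):
        tree, lnL, _ = optimize_branch_lengths(tree, data, model)
        if model.name == "K80":
            def neg_k(logk):
                m = make_model("K80", kappa=float(np.exp(logk)))
                return -pruning_lnL(tree, data, m)

            res = minimize_scalar(neg_k, bounds=(np.log(0.05), np.log(50)),
                                  method="bounded", options={"xatol": 1e-5})
            model = make_model("K80", kappa=float(np.exp(res.x)))
        else:  # GTR
            def neg_g(logr):
                rates = np.append(np.exp(logr), 1.0)
                m = model.with_rates(rates)
                return -pruning_lnL(tree, data, m)

            x0 = np.log(model.rates[:5] / model.rates[5])
            res = minimize(neg_g, x0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxiter": 400})
            model = model.with_rates(np.append(np.exp(res.x), 1.0))
        lnL = pruning_lnL(tree, data, model)
    tree, lnL, _ = optimize_branch_lengths(tree, data, model)
    return tree, model, lnL


# -- simulation ---------------------------------------------------------------

def _simulate_states(tree: Tree, model: Model, n_sites: int,
                     rng: np.random.Generator,
                     root_seq: str | None = None) -> np.ndarray:
    order = tree.postorder()
    root = order[-1][0]
    states: dict[int, np.ndarray] = {}
    if root_seq is None:
        states[root] = rng.choice(4, size=n_sites, p=model.freqs)
    else:
        if len(root_seq) != n_sites:
            raise ValueError("root sequence length does not match n_sites")
        states[root] = np.array([NT_INDEX.get(c, 0) for c in root_seq.upper()],
                                dtype=np.int64)
    for node, parent in reversed(order):  # preorder
        if parent == -1:
            continue
        Pm = model.P(tree.adj[parent][node])
        cum = np.cumsum(Pm, axis=1)
        u = rng.random(n_sites)
        parent_states = states[parent]
        states[node] = (u[:, None] > cum[parent_states]).sum(axis=1)
    return np.array([states[i] for i in range(tree.n_leaves)], dtype=np.int8)


def simulate_alignment(tree: Tree, model: Model | str, n_sites: int,
                       rng: np.random.Generator,
                       root_seq: str | None = None) -> dict[str, str]:
    """Evolve sequences along a tree (root states from the stationary
    distribution unless ``root_seq`` is given)."""
    if isinstance(model, str):
        model = make_model(model)
    mat = _simulate_states(tree, model, n_sites, rng, root_seq)
    chars = np.array(list("ACGT"))
    return {tree.taxa[i]: "".join(chars[mat[i]])
            for i in range(tree.n_leaves)}


def simulate_patterns(tree: Tree, model: Model | str, n_sites: int,
                      rng: np.random.Generator) -> PatternData:
    """Evolve an alignment and return it pattern-compressed (the fast
    path used by parametric-bootstrap replicates)."""
    if isinstance(model, str):
        model = make_model(model)
    mat = _simulate_states(tree, model, n_sites, rng)
    return patterns_from_codes(list(tree.taxa), mat)
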