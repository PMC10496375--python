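"""Fast Jukes-Cantor pruning and branch-length kernels.

Under JC the transition matrix is P(t) = b(t) + e(t) I with
e = exp(-4t/3) and b = (1 - e)/4, so a pruning "message" is
``b * colsum + e * partial`` and the single-branch site likelihood is an
affine function of e:

    s_p(e) = u_p + v_p e,   u_p = S_G S_D / 4,  v_p = (G . D) - u_p

where G and D are the conditional likelihoods on the two sides of the
branch. The per-branch ML problem is therefore one-dimensional and
concave in e, solved here by safeguarded Newton. These kernels are what
the general engine dispatches to for JC fits; they are numba-compiled
when numba is importable and run as plain numpy otherwise, with
identical results.

Array layout: nodes are renumbered by post-order position (children
before parents, root last); ``parent_pos[i]`` is the parent's position
(-1 for the root), ``tlen[i]`` the branch above node i, and
``leaf_codes[i]`` the pattern codes of leaf i (4 = missing; row unused
for internal nodes).
"""

from __future__ import annotations

import numpy as np

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _jc_lnl_kernel(parent_pos, tlen, leaf_codes, is_leaf, weights):
    m = parent_pos.shape[0]
    Pn = leaf_codes.shape[1]
    acc = np.ones((m, Pn, 4))
    scale = np.zeros(Pn)
    lnl = 0.0
    for i in range(m):
        par = parent_pos[i]
        if is_leaf[i]:
            L = np.empty((Pn, 4))
            for q in range(Pn):
                c = leaf_codes[i, q]
                for x in range(4):
                    L[q, x] = 1.0 if (c == 4 or c == x) else 0.0
        else:
            L = acc[i]
            for q in range(Pn):
                mx = 0.0
                for x in range(4):
                    if L[q, x] > mx:
                        mx = L[q, x]
                if mx > 0.0 and mx != 1.0:
                    for x in range(4):
                        L[q, x] /= mx
                    scale[q] += np.log(mx)
        if par == -1:
            for q in range(Pn):
                site = 0.25 * (L[q, 0] + L[q, 1] + L[q, 2] + L[q, 3])
                lnl += weights[q] * (np.log(site) + scale[q])
            return lnl
        e = np.exp(-4.0 * tlen[i] / 3.0)
        b = 0.25 * (1.0 - e)
        for q in range(Pn):
            S = L[q, 0] + L[q, 1] + L[q, 2] + L[q, 3]
            for x in range(4):
                acc[par, q, x] *= b * S + e * L[q, x]
    return lnl


@njit(cache=False)
def _grad_z(u, v, weights, z):
    g = 0.0
    for q in range(u.shape[0]):
        g += weights[q] * v[q] / (u[q] + v[q] * z)
    return g


@njit(cache=False)
def _opt_edge_z(u, v, weights, z_lo, z_hi):
    """Maximize sum_q w_q log(u_q + v_q z) over z in [z_lo, z_hi]."""
    if _grad_z(u, v, weights, z_hi) >= 0.0:
        return z_hi
    if _grad_z(u, v, weights, z_lo) <= 0.0:
        return z_lo
    lo, hi = z_lo, z_hi
    z = 0.5 * (lo + hi)
    for _ in range(60):
        g = 0.0
        h = 0.0
        for q in range(u.shape[0]):
            s = u[q] + v[q] * z
            r = v[q] / s
            g += weights[q] * r
            h -= weights[q] * r * r
        if g > 0.0:
            lo = z
        else:
            hi = z
        if abs(g) < 1e-12:
            break
        z_new = z - g / h if h < 0.0 else 0.5 * (lo + hi)
        if not (lo < z_new < hi):
            z_new = 0.5 * (lo + hi)
        if abs(z_new - z) < 1e-14:
            z = z_new
            break
        z = z_new
    return z


@njit(cache=False)
def _jc_sweep_kernel(parent_pos, tlen, leaf_codes, is_leaf, weights,
                     min_t, max_t):
    """One post-order sweep of per-branch Newton updates (in place)."""
    m = parent_pos.shape[0]
    Pn = leaf_codes.shape[1]
    D = np.ones((m, Pn, 4))
    msg = np.empty((m, Pn, 4))
    # down pass: D (own partial) and msg (partial propagated through the
    # branch above)
    for i in range(m):
        if is_leaf[i]:
            for q in range(Pn):
                c = leaf_codes[i, q]
                for x in range(4):
                    D[i, q, x] = 1.0 if (c == 4 or c == x) else 0.0
        par = parent_pos[i]
        if par == -1:
            continue
        e = np.exp(-4.0 * tlen[i] / 3.0)
        b = 0.25 * (1.0 - e)
        for q in range(Pn):
            S = D[i, q, 0] + D[i, q, 1] + D[i, q, 2] + D[i, q, 3]
            for x in range(4):
                v = b * S + e * D[i, q, x]
                msg[i, q, x] = v
                D[par, q, x] *= v
    # up pass: F (rest-of-tree partial, stationary freqs folded in at the
    # root); G at node i is F[parent] * prod(sibling msgs) = T[par]/msg[i]
    F = np.empty((m, Pn, 4))
    G = np.empty((m, Pn, 4))
    root = m - 1
    for q in range(Pn):
        for x in range(4):
            F[root, q, x] = 0.25
    for i in range(m - 2, -1, -1):
        par = parent_pos[i]
        for q in range(Pn):
            for x in range(4):
                T = F[par, q, x] * D[par, q, x] if not is_leaf[par] else F[par, q, x]
                G[i, q, x] = T / msg[i, q, x]
        e = np.exp(-4.0 * tlen[i] / 3.0)
        b = 0.25 * (1.0 - e)
        for q in range(Pn):
            S = G[i, q, 0] + G[i, q, 1] + G[i, q, 2] + G[i, q, 3]
            for x in range(4):
                F[i, q, x] = b * S + e * G[i, q, x]
    # post-order branch updates; after each update the D caches on the
    # root path are refreshed (divide out the old message, multiply the
    # new one) so later edges see fresh subtree partials. F stays from
    # sweep start; the outer loop iterates sweeps to convergence.
    z_lo = np.exp(-4.0 * max_t / 3.0)
    z_hi = np.exp(-4.0 * min_t / 3.0)
    u = np.empty(Pn)
    v = np.empty(Pn)
    for i in range(m - 1):
        par = parent_pos[i]
        for q in range(Pn):
            T0 = F[par, q, 0] * D[par, q, 0] / msg[i, q, 0]
            T1 = F[par, q, 1] * D[par, q, 1] / msg[i, q, 1]
            T2 = F[par, q, 2] * D[par, q, 2] / msg[i, q, 2]
            T3 = F[par, q, 3] * D[par, q, 3] / msg[i, q, 3]
            SG = T0 + T1 + T2 + T3
            SD = D[i, q, 0] + D[i, q, 1] + D[i, q, 2] + D[i, q, 3]
            gd = (T0 * D[i, q, 0] + T1 * D[i, q, 1]
                  + T2 * D[i, q, 2] + T3 * D[i, q, 3])
            u[q] = 0.25 * SG * SD
            v[q] = gd - u[q]
        z = _opt_edge_z(u, v, weights, z_lo, z_hi)
        tlen[i] = -0.75 * np.log(z)
        # refresh msg[i] and propagate D up the root path
        e = np.exp(-4.0 * tlen[i] / 3.0)
        b = 0.25 * (1.0 - e)
        node = i
        while True:
            p2 = parent_pos[node]
            if p2 == -1:
                break
            en = np.exp(-4.0 * tlen[node] / 3.0)
            bn = 0.25 * (1.0 - en)
            for q in range(Pn):
                S = (D[node, q, 0] + D[node, q, 1]
                     + D[node, q, 2] + D[node, q, 3])
                for x in range(4):
                    new = bn * S + en * D[node, q, x]
                    D[p2, q, x] *= new / msg[node, q, x]
                    msg[node, q, x] = new
            node = p2


def build_arrays(tree, data):
    """Flatten a tree + pattern data into kernel arrays.

    Returns (parent_pos, tlen, leaf_codes, is_leaf, order) where order is
    the list of (node, parent) pairs so branch lengths can be written
    back.
    """
    order = tree.postorder()
    pos = {node: i for i, (node, _) in enumerate(order)}
    m = len(order)
    parent_pos = np.empty(m, dtype=np.int64)
    tlen = np.zeros(m)
    is_leaf = np.zeros(m, dtype=np.bool_)
    leaf_codes = np.zeros((m, data.n_patterns), dtype=np.int8)
    row_of = {t: i for i, t in enumerate(data.taxa)}
    for i, (node, parent) in enumerate(order):
        parent_pos[i] = -1 if parent == -1 else pos[parent]
        if parent != -1:
            tlen[i] = tree.adj[node][parent]
        if node < tree.n_leaves:
            is_leaf[i] = True
            leaf_codes[i] = data.codes[row_of[tree.taxa[node]]]
    return parent_pos, tlen, leaf_codes, is_leaf, order


def jc_lnl(tree, data) -> float:
    parent_pos, tlen, leaf_codes, is_leaf, _ = build_arrays(tree, data)
    return float(
        _jc_lnl_kernel(parent_pos, tlen, leaf_codes, is_leaf, data.weights)
    )


def jc_optimize_branch_lengths(tree, data, tol: float = 1e-6,
                               max_sweeps: int = 50):
    """Sweep Newton branch updates until the lnL gain drops below tol."""
    parent_pos, tlen, leaf_codes, is_leaf, order = build_arrays(tree, data)
    w = data.weights
    best = prev = _jc_lnl_kernel(parent_pos, tlen, leaf_codes, is_leaf, w)
    best_t = tlen.copy()
    converged = False
    for _ in range(max_sweeps):
        _jc_sweep_kernel(parent_pos, tlen, leaf_codes, is_leaf, w,
                         MIN_BRANCH, MAX_BRANCH)
        cur = _jc_lnl_kernel(parent_pos, tlen, leaf_codes, is_leaf, w)
        if cur > best:
            best = cur
            best_t = tlen.copy()
        if cur - prev < tol:
            converged = True
            break
        prev = cur
    for i, (node, parent) in enumerate(order):
        if parent != -1:
            tree.set_length(node, parent, float(best_t[i]))
    return tree, float(best), converged


def jc_sweep_once(tree, data) -> float:
    """A single branch sweep (cheap scoring pass for NNI candidates)."""
    parent_pos, tlen, leaf_codes, is_leaf, order = build_arrays(tree, data)
    _jc_sweep_kernel(parent_pos, tlen, leaf_codes, is_leaf, data.weights,
                     MIN_BRANCH, MAX_BRANCH)
    lnl = _jc_lnl_kernel(parent_pos, tlen, leaf_codes, is_leaf, data.weights)
    for i, (node, parent) in enumerate(order):
        if parent != -1:
            tree.set_length(node, parent, float(tlen[i]))
    return float(lnl)
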