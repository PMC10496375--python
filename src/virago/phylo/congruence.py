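"""Tree-topology congruence testing across genome partitions.

Reassortment between co-circulating strains of a segmented virus shows up
as incongruent per-segment (or per-ORF) tree topologies. The test here
compares two maximum-likelihood fits over k partitions on a common taxon
set:

* unlinked: every partition gets its own topology (and branch lengths);
* linked: one shared topology, branch lengths still free per partition.

The statistic is delta = 2 (lnL_unlinked - lnL_linked). Because a
topology is not a regular parameter, the chi-square reference with
df = (k - 1)(n - 3) (the number of internal branches freed per extra
topology) is only a heuristic; the recommended significance measure is a
parametric bootstrap: simulate alignments under the fitted linked model,
recompute delta on each replicate, and report the fraction of replicates
with delta at least as large as observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .likelihood import (
    Model,
    encode_alignment,
    make_model,
    ml_tree,
    optimize_branch_lengths,
    pruning_lnL,
    simulate_patterns,
)
from .tree import Tree


@dataclass
class CongruenceResult:
    lnL_unlinked_parts: list[float]
    lnL_unlinked: float
    lnL_linked: float
    delta: float  # 2 * (lnL_unlinked - lnL_linked)
    df_heuristic: int
    p_chi2: float
    p_bootstrap: float | None
    n_bootstrap: int
    unlinked_trees: list[Tree]
    linked_tree: Tree
    linked_branch_lengths: list[Tree]  # linked topology, per-partition lengths


def concat_partitions(alignments: list[dict[str, str]]):
    """Column-wise concatenation of partitions on a common taxon set.

    Returns ``(alignment, boundaries)`` where boundaries are 0-based
    half-open column ranges of each partition in the concatenation.
    """
    if not alignments:
        raise ValueError("no partitions given")
    taxa = list(alignments[0])
    for aln in alignments[1:]:
        if set(aln) != set(taxa):
            raise ValueError("partitions have different taxon sets")
    out = {t: "".join(aln[t] for aln in alignments) for t in taxa}
    bounds, at = [], 0
    for aln in alignments:
        L = len(next(iter(aln.values())))
        bounds.append((at, at + L))
        at += L
    return out, bounds


def _fit_linked(datas, model: Model, candidates: list[Tree]):
    """Shared topology maximizing the summed lnL, branch lengths free per
    partition.

    Candidate topologies (the per-partition ML trees) and their NNI
    rearrangements are screened with a cheap one-sweep score; the winner
    is then branch-length-optimized to full tolerance per partition.
    """
    from ._jc import jc_sweep_once
    from .tree import nni_neighbors

    jc = model.name == "JC"

    def quick_score(topology: Tree) -> float:
        total = 0.0
        for data in datas:
            t = topology.copy()
            if jc:
                total += jc_sweep_once(t, data)
                total = total if np.isfinite(total) else -np.inf
            else:
                t, lnL, _ = optimize_branch_lengths(t, data, model,
                                                    max_sweeps=2)
                total += lnL
        return total

    def full_fit(topology: Tree):
        fits, total = [], 0.0
        for data in datas:
            t = topology.copy()
            t, lnL, _ = optimize_branch_lengths(t, data, model)
            fits.append(t)
            total += lnL
        return total, fits

    seen = {frozenset(candidates[0].bipartitions())}
    uniq = [candidates[0]]
    for cand in candidates[1:]:
        key = frozenset(cand.bipartitions())
        if key not in seen:
            seen.add(key)
            uniq.append(cand)
    scores = [quick_score(c) for c in uniq]
    best_topo = uniq[int(np.argmax(scores))]
    best_quick = max(scores)

    # NNI on the summed one-sweep score
    improved = True
    while improved:
        improved = False
        for edge in best_topo.internal_edges():
            for cand in nni_neighbors(best_topo, edge):
                s = quick_score(cand)
                if s > best_quick + 1e-6:
                    best_topo, best_quick = cand, s
                    improved = True
                    break
            if improved:
                break
    best_lnL, best_fits = full_fit(best_topo)
    return best_topo, best_lnL, best_fits


def congruence_test(partitions: list[dict[str, str]], model: Model | str = "JC",
                    n_bootstrap: int = 0, seed: int | None = None,
                    _progress=None) -> CongruenceResult:
    """Linked-vs-unlinked topology likelihood-ratio test with optional
    parametric bootstrap.

    ``partitions`` are aligned ``{taxon: seq}`` mappings on one taxon set
    (>= 4 taxa, >= 2 partitions). With ``n_bootstrap > 0``, replicate
    alignments are simulated under the fitted linked model (per-partition
    branch lengths) and ``p_bootstrap`` is the fraction of replicate
    delta values >= the observed delta.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    taxa = set(partitions[0])
    for p in partitions[1:]:
        if set(p) != taxa:
            raise ValueError("partitions have different taxon sets")
    if len(taxa) < 4:
        raise ValueError("need at least four taxa")
    if isinstance(model, str):
        model = make_model(model)

    rng = np.random.default_rng(seed)
    datas = [encode_alignment(p) for p in partitions]
    result = _congruence_core(datas, model)

    p_boot = None
    if n_bootstrap > 0:
        n_sites = [d.n_sites for d in datas]
        exceed = 0
        for b in range(n_bootstrap):
            sims = [
                simulate_patterns(result.linked_branch_lengths[i], model,
                                  n_sites[i], rng)
                for i in range(len(partitions))
            ]
            rep = _congruence_core(sims, model)
            if rep.delta >= result.delta - 1e-9:
                exceed += 1
            if _progress is not None:
                _progress(b)
        p_boot = exceed / n_bootstrap
    result.p_bootstrap = p_boot
    result.n_bootstrap = n_bootstrap
    return result


def _congruence_core(datas, model: Model) -> CongruenceResult:
    n = len(datas[0].taxa)
    k = len(datas)

    unlinked = [ml_tree(d, model) for d in datas]
    # linked candidates: each partition's ML topology
    candidates = [t for t, _ in unlinked]
    linked_topo, lnL_linked, linked_fits = _fit_linked(datas, model, candidates)

    # nesting guarantee: a partition's unlinked fit can never be worse than
    # its fit on the linked topology
    parts_lnL, trees = [], []
    for i, (tree, lnL) in enumerate(unlinked):
        linked_lnL_i = pruning_lnL(linked_fits[i], datas[i], model)
        if linked_lnL_i > lnL:
            tree, lnL = linked_fits[i].copy(), linked_lnL_i
        parts_lnL.append(lnL)
        trees.append(tree)

    lnL_unlinked = float(sum(parts_lnL))
    delta = 2.0 * (lnL_unlinked - lnL_linked)
    df = (k - 1) * (n - 3)
    p_chi2 = float(chi2.sf(max(delta, 0.0), df))
    return CongruenceResult(
        lnL_unlinked_parts=parts_lnL,
        lnL_unlinked=lnL_unlinked,
        lnL_linked=lnL_linked,
        delta=delta,
        df_heuristic=df,
        p_chi2=p_chi2,
        p_bootstrap=None,
        n_bootstrap=0,
        unlinked_trees=trees,
        linked_tree=linked_topo,
        linked_branch_lengths=linked_fits,
    )
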