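"""Tree and network likelihoods under K80.

The per-gene tree likelihood P(S_i | T) is computed by Felsenstein pruning
with uniform root frequencies, vectorized over the pooled unique site
patterns of the whole gene set (one pruning pass scores every gene on a
topology).  The network likelihood

    L(N, gamma | S) = prod_i sum_{T in T(N)} P(S_i | T) P(T | N, gamma)

mixes the displayed-tree likelihoods with the displayed-tree probabilities,
accumulated as log-sum-exp for numerical safety.

Branch lengths of a displayed tree default to those induced by the network
(edge subdivision preserves path lengths, so the base tree of an augmented
network scores identically to the original tree); per-branch ML
re-estimation (Brent sweeps) is available as an option.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment, GeneAlignmentSet
from .network import (NetworkError, PhyloNetwork, PhyloTree,
                      _induction_choices, _display, as_network)
from .substitution import K80Model

__all__ = [
    "LikelihoodCache",
    "pattern_log_likelihoods",
    "tree_log_likelihood",
    "network_log_likelihood",
    "optimize_new_gamma",
    "gamma_grid_scores",
]

_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones((1, 4))])  # row 4 = missing


def pattern_log_likelihoods(tree: PhyloTree, patterns: np.ndarray,
                            model: K80Model,
                            taxa: Sequence[str] | None = None) -> np.ndarray:
    """Log-likelihood of each site pattern (columns of ``patterns``) on a tree.

    ``patterns`` is (n_taxa, U) with rows ordered like ``taxa`` (default: the
    tree's sorted taxa); entries 0..3 are A,C,G,T and 4 is missing.
    """
    taxa = tuple(taxa) if taxa is not None else tree.taxa
    n_taxa, u = patterns.shape
    if n_taxa != len(taxa):
        raise ValueError("pattern matrix does not match taxon count")
    idx = {t: i for i, t in enumerate(taxa)}
    post = tree.postorder()
    node_id = dict(idx)
    nxt = n_taxa
    for v in post:
        if v not in node_id:
            node_id[v] = nxt
            nxt += 1
    partials = np.empty((nxt, u, 4))
    for t in taxa:
        partials[idx[t]] = _LEAF_PARTIALS[patterns[idx[t]]]
    logscale = np.zeros(u)
    for v in post:
        cs = tree.children.get(v, ())
        if not cs:
            continue
        acc = None
        for c in cs:
            p = model.transition_matrix(tree.lengths[(v, c)])
            term = partials[node_id[c]] @ p.T
            acc = term if acc is None else acc * term
        # rescale only when some pattern is in underflow danger; the floor on
        # the scaling factor keeps 1/mx finite for impossible patterns
        if acc.min() < 1e-150:
            mx = np.maximum(acc.max(axis=1), 1e-280)
            acc = acc / mx[:, None]
            logscale = logscale + np.log(mx)
        partials[node_id[v]] = acc
    site = partials[node_id[tree.root]] @ model.stationary
    return np.log(np.maximum(site, 1e-300)) + logscale


def _single_gene_patterns(alignment: Alignment) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    taxa = alignment.taxa
    mat = alignment.encoded(taxa)
    uniq, inverse = np.unique(mat, axis=1, return_inverse=True)
    counts = np.bincount(np.asarray(inverse).ravel(), minlength=uniq.shape[1]).astype(float)
    return uniq, counts, taxa


def _optimize_branch_lengths(tree: PhyloTree, patterns: np.ndarray,
                             counts: np.ndarray, model: K80Model,
                             taxa: Sequence[str],
                             max_sweeps: int = 5,
                             rtol: float = 1e-4) -> tuple[PhyloTree, float]:
    """Per-branch Brent sweeps maximizing the pattern-weighted log-likelihood."""
    work = tree.copy()
    edges = sorted(work.lengths)

    def lnl() -> float:
        return float(counts @ pattern_log_likelihoods(work, patterns, model, taxa))

    best = lnl()
    for _ in range(max_sweeps):
        prev = best
        for e in edges:
            old = work.lengths[e]

            def neg(x: float, e=e) -> float:
                work.lengths[e] = x
                return -float(counts @ pattern_log_likelihoods(work, patterns, model, taxa))

            res = minimize_scalar(neg, bounds=(1e-9, 10.0), method="bounded",
                                  options={"xatol": 1e-6})
            if -res.fun > best:
                work.lengths[e] = float(res.x)
                best = -res.fun
            else:
                work.lengths[e] = old
        if best - prev <= rtol * (abs(prev) + 1.0):
            # converged: relative improvement over a full sweep below tolerance
            break
    return work, best


def tree_log_likelihood(tree: PhyloTree, alignment: Alignment,
                        model: K80Model | None = None,
                        optimize_branches: bool = False) -> float:
    """ln P(S_i | T) for one gene alignment (nats)."""
    model = model or K80Model()
    if set(alignment.taxa) != set(tree.leaves()):
        raise NetworkError("alignment taxa do not match tree leaves")
    patterns, counts, taxa = _single_gene_patterns(alignment)
    if optimize_branches:
        _, best = _optimize_branch_lengths(tree, patterns, counts, model, taxa)
        return best
    return float(counts @ pattern_log_likelihoods(tree, patterns, model, taxa))


class LikelihoodCache:
    """Memoizes per-gene tree log-likelihoods keyed by the tree's canonical
    Newick (topology + branch lengths), the gene set, and the model."""

    def __init__(self):
        self._store: dict[tuple, np.ndarray] = {}
        self.hits = 0
        self.misses = 0

    def gene_log_likelihoods(self, tree: PhyloTree, genes: GeneAlignmentSet,
                             model: K80Model) -> np.ndarray:
        key = (tree.canonical_newick(), genes.token, model.key)
        hit = self._store.get(key)
        if hit is not None:
            self.hits += 1
            return hit
        self.misses += 1
        patterns, counts = genes.patterns()
        site = pattern_log_likelihoods(tree, patterns, model, genes.taxa)
        out = counts @ site
        self._store[key] = out
        return out


def _component_matrix(network: PhyloNetwork, genes: GeneAlignmentSet,
                      model: K80Model, cache: LikelihoodCache | None,
                      optimize_branches: bool = False):
    """Displayed-tree mixture components as arrays.

    Returns (logLik matrix of shape (n_components, k), log-weights).
    Components are displayed trees deduplicated by exact topology+lengths
    (or by unrooted topology when branch lengths are re-optimized).
    """
    cache = cache or LikelihoodCache()
    comps: dict = {}
    for kept, w in _induction_choices(network):
        t = _display(network, kept)
        key = frozenset(t.bipartitions()) if optimize_branches else t.canonical_newick()
        if key in comps:
            comps[key] = (comps[key][0], comps[key][1] + w)
        else:
            comps[key] = (t, w)
    rows, weights = [], []
    for t, w in sorted(comps.values(), key=lambda tw: tw[0].canonical_newick()):
        if w <= 0.0:
            continue
        if optimize_branches:
            rows.append(np.array([
                tree_log_likelihood(t, g, model, optimize_branches=True)
                for g in genes
            ]))
        else:
            rows.append(cache.gene_log_likelihoods(t, genes, model))
        weights.append(w)
    if not rows:
        raise NetworkError("no displayed tree has positive probability")
    return np.vstack(rows), np.log(np.array(weights))


def network_log_likelihood(network: PhyloNetwork | PhyloTree,
                           genes: GeneAlignmentSet,
                           model: K80Model | None = None,
                           cache: LikelihoodCache | None = None,
                           optimize_branches: bool = False,
                           check: bool = True) -> float:
    """ln L(N, gamma | S): sum over genes of the log mixture likelihood."""
    model = model or K80Model()
    if isinstance(network, PhyloTree):
        network = as_network(network)
    if check:
        from .network import _require_valid
        _require_valid(network)
    if set(genes.taxa) != set(network.leaves()):
        raise NetworkError("gene set taxa do not match network leaves")
    mat, logw = _component_matrix(network, genes, model, cache, optimize_branches)
    per_gene = logsumexp(mat + logw[:, None], axis=0)
    return float(per_gene.sum())


def _gamma_components(network: PhyloNetwork, new_edge) -> list:
    """Mixture components with the new reticulation edge's gamma left symbolic.

    Returns a list of (tree, log base weight, uses_new_edge) where the base
    weight is the product of the *other* reticulations' inheritance
    probabilities; the full weight is base * gamma or base * (1 - gamma).
    """
    head = new_edge[1]
    if network.in_degree(head) != 2:
        raise NetworkError(f"{new_edge} is not a reticulation edge")
    comps: dict = {}
    for kept, _ in _induction_choices(network):
        base = 1.0
        for v, p in kept.items():
            if v != head:
                base *= network.gamma[(p, v)]
        uses_new = kept[head] == new_edge[0]
        t = _display(network, kept)
        key = (t.canonical_newick(), uses_new)
        if key in comps:
            comps[key] = (comps[key][0], comps[key][1] + base, uses_new)
        else:
            comps[key] = (t, base, uses_new)
    return [comps[k] for k in sorted(comps)]


def gamma_grid_scores(network: PhyloNetwork, new_edge, genes: GeneAlignmentSet,
                      grid: Sequence[float], model: K80Model,
                      cache: LikelihoodCache | None = None) -> np.ndarray:
    """ln L(N, gamma | S) at each grid value of the new edge's gamma (other
    inheritance probabilities held fixed)."""
    if not len(grid):
        raise ValueError("empty inheritance-probability grid")
    if any(not (0.0 < g < 1.0) for g in grid):
        raise ValueError("grid values must lie strictly in (0,1)")
    cache = cache or LikelihoodCache()
    comps = _gamma_components(network, new_edge)
    mat = np.vstack([cache.gene_log_likelihoods(t, genes, model) for t, _, _ in comps])
    base = np.array([b for _, b, _ in comps])
    uses = np.array([u for _, _, u in comps])
    scores = np.empty(len(grid))
    with np.errstate(divide="ignore"):
        logbase = np.log(base)
    for i, g in enumerate(grid):
        lw = logbase + np.where(uses, np.log(g), np.log1p(-g))
        finite = lw > -np.inf
        scores[i] = float(logsumexp(mat[finite] + lw[finite, None], axis=0).sum())
    return scores


def optimize_new_gamma(network: PhyloNetwork, new_edge,
                       genes: GeneAlignmentSet,
                       grid: Sequence[float], model: K80Model | None = None,
                       cache: LikelihoodCache | None = None) -> tuple[float, float]:
    """Grid-maximize the new edge's inheritance probability.

    Returns (best gamma, log-likelihood); ties break toward the smaller gamma.
    """
    model = model or K80Model()
    grid = sorted(grid)
    scores = gamma_grid_scores(network, new_edge, genes, grid, model, cache)
    best = int(np.argmax(scores))  # argmax returns the first (smallest gamma) on ties
    return float(grid[best]), float(scores[best])
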