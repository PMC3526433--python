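"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's pruning/suppression code paths:
tree likelihoods are exhaustive sums over ancestral states, network
likelihoods enumerate induction choices on the *unsuppressed* kept graph
(degree-two nodes are harmless because transition matrices compose), and
bipartition counts are re-derived by brute force.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from retnet import K80Model, PhyloTree, make_species_tree
from retnet.network import PhyloNetwork


@pytest.fixture(scope="session")
def model() -> K80Model:
    return K80Model()


@pytest.fixture(scope="session")
def caterpillar10() -> PhyloTree:
    return make_species_tree(10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251204)


@pytest.fixture(scope="session")
def tree4() -> PhyloTree:
    """((A,B),(C,D)) with distinct branch lengths."""
    return PhyloTree(
        "r",
        {"r": ("u", "v"), "u": ("A", "B"), "v": ("C", "D")},
        {("r", "u"): 0.1, ("r", "v"): 0.2, ("u", "A"): 0.3, ("u", "B"): 0.15,
         ("v", "C"): 0.25, ("v", "D"): 0.05},
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_tree_log_likelihood(tree: PhyloTree, alignment, model: K80Model) -> float:
    """Exhaustive summation over all ancestral state assignments."""
    internal = [v for v in tree.nodes() if v in tree.children]
    leaves = tree.leaves()
    code = {b: i for i, b in enumerate("ACGT")}
    total = 0.0
    for site in range(alignment.n_sites):
        obs = {t: code.get(alignment.sequences[t][site], None) for t in leaves}
        site_p = 0.0
        for states in itertools.product(range(4), repeat=len(internal)):
            assign = dict(zip(internal, states))
            p = 0.25
            for (u, v), t in tree.lengths.items():
                su = assign[u]
                sv = assign[v] if v in assign else obs[v]
                if sv is None:
                    continue  # missing data: marginalized, row sums to 1
                p *= model.transition_matrix(t)[su, sv]
            site_p += p
        total += np.log(site_p)
    return float(total)


def brute_force_network_gene_likelihood(net: PhyloNetwork, alignment,
                                        model: K80Model) -> float:
    """P(S_i | N, gamma) by enumerating induction choices on the kept graph.

    The kept graph is scored directly (degree-two and dangling nodes are
    summed over; Chapman-Kolmogorov makes this equal the suppressed tree's
    likelihood), so this oracle never calls the package's displayed-tree code.
    The per-site summation over hidden states is vectorized over the full
    4^m assignment grid.
    """
    retics = net.reticulation_nodes()
    code = {b: i for i, b in enumerate("ACGT")}
    leaves = set(net.leaves())
    total = 0.0
    options = [list(net.parents[v]) for v in retics]
    for combo in itertools.product(*options) if retics else [()]:
        kept = dict(zip(retics, combo))
        w = 1.0
        for v, p in kept.items():
            w *= net.gamma[(p, v)]
        edges = [(u, v) for (u, v) in net.lengths
                 if net.in_degree(v) != 2 or kept[v] == u]
        nodes = sorted({u for u, _ in edges} | {v for _, v in edges})
        hidden = [v for v in nodes if v not in leaves]
        hidx = {v: i for i, v in enumerate(hidden)}
        m = len(hidden)
        grid = np.array(np.meshgrid(*([np.arange(4)] * m), indexing="ij"),
                        dtype=np.intp).reshape(m, -1) if m else np.zeros((0, 1), np.intp)
        site_probs = []
        for site in range(alignment.n_sites):
            obs = {t: code.get(alignment.sequences[t][site], None)
                   for t in leaves}
            factors = np.full(grid.shape[1], 0.25)
            for (u, v) in edges:
                pmat = model.transition_matrix(net.lengths[(u, v)])
                su = grid[hidx[u]]
                if v in hidx:
                    factors *= pmat[su, grid[hidx[v]]]
                elif obs.get(v) is not None:
                    factors *= pmat[su, obs[v]]
                # missing leaf: row of pmat sums to 1, no factor
            site_probs.append(float(factors.sum()))
        total += w * float(np.prod(site_probs))
    return total


def brute_force_bipartitions(tree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial unrooted bipartitions as {side, complement} pairs, derived
    by splitting the leaf set at every edge."""
    taxa = frozenset(tree.leaves())
    out = set()
    for v in tree.nodes():
        if v == tree.root or v not in tree.children:
            continue
        below = frozenset(tree.leaves_below(v))
        if 2 <= len(below) <= len(taxa) - 2:
            out.add(frozenset({below, taxa - below}))
    return out
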