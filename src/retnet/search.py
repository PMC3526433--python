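"""Forward-selection search over phylogenetic-network space with AIC/BIC.

Starting from a species tree, the search repeatedly augments the current
optimal network with one reticulation edge, choosing the attachment pair of
edges and the new inheritance probability that maximize the network
likelihood ((e*, gamma*) = argmax L(N', gamma | S)).  Candidate attachments
subdivide two edges at their midpoints and connect the midpoints; pairs that
would create a directed cycle and pairs of sibling edges (two edges emanating
from one node) are excluded.

Model selection uses the likelihood-improvement thresholds implied by AIC and
BIC when each reticulation adds one parameter: an i-th reticulation is
accepted under AIC when ln L(i) - ln L(i-1) > 1 and under BIC when
ln L(i) - ln L(i-1) > ln(n)/2, n being the total number of sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .alignment import GeneAlignmentSet
from .likelihood import LikelihoodCache, gamma_grid_scores, network_log_likelihood
from .network import (Edge, NetworkError, PhyloNetwork, PhyloTree,
                      add_reticulation, as_network)
from .substitution import K80Model, default_gamma_grid

__all__ = [
    "ModelScore",
    "TrajectoryStep",
    "SearchTrajectory",
    "AugmentationResult",
    "enumerate_additions",
    "best_augmentation",
    "forward_search",
    "select_model",
    "selection_threshold",
]


@dataclass(frozen=True)
class ModelScore:
    """Fit summary of one network: AIC = 2K - 2 lnL, BIC = K ln n - 2 lnL,
    with K the number of branches of the network and n the total site count."""
    h: int
    log_likelihood: float
    k_params: int
    n_sites: int

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.k_params * math.log(self.n_sites) - 2.0 * self.log_likelihood


@dataclass(frozen=True)
class AugmentationResult:
    network: PhyloNetwork
    donor_edge: Edge
    recipient_edge: Edge
    new_edge: Edge
    gamma: float
    log_likelihood: float


@dataclass(frozen=True)
class TrajectoryStep:
    network: PhyloNetwork
    score: ModelScore
    donor_edge: Edge | None = None
    recipient_edge: Edge | None = None
    gamma: float | None = None


@dataclass
class SearchTrajectory:
    """Optimal networks for h = 0..h_max with scores and per-step choices."""
    steps: list[TrajectoryStep] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.steps[0].score.n_sites

    @property
    def improvements(self) -> list[float]:
        lnl = [s.score.log_likelihood for s in self.steps]
        return [b - a for a, b in zip(lnl, lnl[1:])]

    def select(self, criterion: str, mode: str = "sequential") -> int:
        return select_model(self, criterion, mode=mode)

    def to_dict(self) -> dict:
        from .newick import write_enewick
        return {
            "n_sites": self.n_sites,
            "steps": [
                {
                    "h": s.score.h,
                    "log_likelihood": s.score.log_likelihood,
                    "k_params": s.score.k_params,
                    "aic": s.score.aic,
                    "bic": s.score.bic,
                    "donor_edge": list(s.donor_edge) if s.donor_edge else None,
                    "recipient_edge": list(s.recipient_edge) if s.recipient_edge else None,
                    "gamma": s.gamma,
                    "network": write_enewick(s.network),
                }
                for s in self.steps
            ],
            "improvements": self.improvements,
            "selected_h": {
                "aic": self.select("aic"),
                "bic": self.select("bic"),
            },
        }


def _edge_sort_key(network: PhyloNetwork, edge: Edge) -> tuple:
    u, v = edge
    return (tuple(sorted(network.leaves_below(v))), tuple(sorted(network.leaves_below(u))), u, v)


def enumerate_additions(network: PhyloNetwork) -> list[tuple[Edge, Edge]]:
    """All (donor edge, recipient edge) attachments that pass the acyclicity
    and sibling-edge exclusions, in deterministic order."""
    edges = sorted(network.lengths, key=lambda e: _edge_sort_key(network, e))
    out: list[tuple[Edge, Edge]] = []
    for e1 in edges:
        for e2 in edges:
            if e1 == e2 or e1[0] == e2[0]:
                continue  # identical or sibling edges
            if network.is_reachable(e2[1], e1[0]):
                continue  # donor midpoint below recipient edge: directed cycle
            out.append((e1, e2))
    return out


def best_augmentation(network: PhyloNetwork | PhyloTree,
                      genes: GeneAlignmentSet,
                      grid: Sequence[float] | None = None,
                      model: K80Model | None = None,
                      cache: LikelihoodCache | None = None) -> AugmentationResult:
    """Optimal single-reticulation augmentation (e*, gamma*) of a network."""
    if isinstance(network, PhyloTree):
        network = as_network(network)
    model = model or K80Model()
    grid = sorted(grid) if grid is not None else list(default_gamma_grid())
    cache = cache or LikelihoodCache()
    candidates = enumerate_additions(network)
    if not candidates:
        raise NetworkError("no valid reticulation attachment exists")
    best: AugmentationResult | None = None
    old_nodes = set(network.nodes())
    for donor, recipient in candidates:
        cand = add_reticulation(network, donor, recipient, gamma=0.5)
        # the new reticulation node is the recipient midpoint; the new edge's
        # tail is the donor midpoint (the other new parent)
        (head,) = [v for v in cand.reticulation_nodes() if v not in old_nodes]
        (x1,) = [p for p in cand.parents[head] if p not in old_nodes]
        new_edge = (x1, head)
        scores = gamma_grid_scores(cand, new_edge, genes, grid, model, cache)
        for g, s in zip(grid, scores):
            if best is None or s > best.log_likelihood + 1e-12:
                net = cand.copy()
                net.gamma[new_edge] = float(g)
                partner = [p for p in net.parents[head] if p != new_edge[0]][0]
                net.gamma[(partner, head)] = 1.0 - float(g)
                best = AugmentationResult(net, donor, recipient, new_edge,
                                          float(g), float(s))
    assert best is not None
    return best


def forward_search(start_tree: PhyloTree | PhyloNetwork,
                   genes: GeneAlignmentSet,
                   h_max: int,
                   grid: Sequence[float] | None = None,
                   model: K80Model | None = None,
                   cache: LikelihoodCache | None = None) -> SearchTrajectory:
    """Greedy forward selection of reticulation edges for h = 0..h_max."""
    if h_max < 0:
        raise ValueError("h_max must be >= 0")
    model = model or K80Model()
    cache = cache or LikelihoodCache()
    net = as_network(start_tree) if isinstance(start_tree, PhyloTree) else start_tree
    n = genes.n_sites
    lnl = network_log_likelihood(net, genes, model, cache)
    traj = SearchTrajectory()
    traj.steps.append(TrajectoryStep(
        net, ModelScore(0, lnl, len(net.lengths), n)))
    for h in range(1, h_max + 1):
        aug = best_augmentation(net, genes, grid, model, cache)
        net = aug.network
        traj.steps.append(TrajectoryStep(
            net, ModelScore(h, aug.log_likelihood, len(net.lengths), n),
            donor_edge=aug.donor_edge, recipient_edge=aug.recipient_edge,
            gamma=aug.gamma))
    return traj


def selection_threshold(criterion: str, n_sites: int) -> float:
    crit = criterion.lower()
    if crit == "aic":
        return 1.0
    if crit == "bic":
        return math.log(n_sites) / 2.0
    raise ValueError(f"unknown criterion {criterion!r} (expected 'aic' or 'bic')")


def select_model(trajectory: SearchTrajectory | Sequence[float],
                 criterion: str = "bic",
                 n_sites: int | None = None,
                 mode: str = "sequential") -> int:
    """Number of reticulations selected along a search trajectory.

    ``sequential`` (default) accepts reticulations while each consecutive
    improvement exceeds the criterion threshold (1 for AIC, ln(n)/2 for BIC)
    and stops at the first failure.  ``global`` returns the h minimizing the
    criterion along the whole trajectory with one parameter per reticulation.
    """
    if isinstance(trajectory, SearchTrajectory):
        improvements = trajectory.improvements
        n = trajectory.n_sites
    else:
        improvements = list(trajectory)
        if n_sites is None:
            raise ValueError("n_sites is required when passing raw improvements")
        n = n_sites
    thr = selection_threshold(criterion, n)
    if mode == "sequential":
        h = 0
        for delta in improvements:
            if delta > thr:
                h += 1
            else:
                break
        return h
    if mode == "global":
        # criterion value up to a constant: h * 2*thr - 2 * lnL(h)
        lnl = [0.0]
        for d in improvements:
            lnl.append(lnl[-1] + d)
        values = [2.0 * thr * h - 2.0 * l for h, l in enumerate(lnl)]
        return int(min(range(len(values)), key=lambda i: (values[i], i)))
    raise ValueError(f"unknown mode {mode!r} (expected 'sequential' or 'global')")
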