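"""Experiment drivers: placement accuracy, inheritance-probability recovery,
model selection, and the effect of reticulation diameter/height.

Placement accuracy follows the displayed-tree comparison: a single
reticulation inferred on data from a planted single-reticulation network is
judged by the Robinson-Foulds distance between the alternate tree displayed
by the inferred network (T') and the true transferred gene tree (T_i); 0
means the placement was recovered exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment import GeneAlignmentSet
from .likelihood import LikelihoodCache, optimize_new_gamma
from .network import (PhyloTree, as_network, rf_distance)
from .search import best_augmentation, forward_search
from .simulate import DatasetBundle, apply_hgt, reticulation_geometry
from .substitution import K80Model, default_gamma_grid

__all__ = [
    "PlacementResult",
    "placement_experiment",
    "gamma_estimation_experiment",
    "model_selection_experiment",
    "diameter_effect_study",
    "height_effect_study",
    "spr_variants",
]


@dataclass(frozen=True)
class PlacementResult:
    """Outcome of inferring one reticulation edge on one replicate."""
    seed: int
    diameter: float
    gamma_true: float
    genome_size: int
    rf: int
    gamma_hat: float
    degenerate: bool
    log_likelihood: float


def _alternate_displayed_tree(aug_result, base_tree: PhyloTree):
    """The displayed tree of an augmented network that uses the new
    reticulation edge, plus a degeneracy flag (True when its unrooted topology
    equals the base tree's)."""
    from .network import _display
    net = aug_result.network
    head = aug_result.new_edge[1]
    kept = {v: net.parents[v][0] for v in net.reticulation_nodes()}
    # existing reticulations keep their higher-gamma parent; the new one uses
    # the new edge
    for v in net.reticulation_nodes():
        if v != head:
            kept[v] = max(net.parents[v], key=lambda p: net.gamma[(p, v)])
    kept[head] = aug_result.new_edge[0]
    alt = _display(net, kept)
    degenerate = frozenset(alt.bipartitions()) == frozenset(base_tree.bipartitions())
    return alt, degenerate


def placement_experiment(bundle: DatasetBundle,
                         grid: Sequence[float] | None = None,
                         model: K80Model | None = None,
                         cache: LikelihoodCache | None = None) -> PlacementResult:
    """Infer a single reticulation edge from the true species tree and score
    its placement against the planted transfer."""
    if bundle.truth is None:
        raise ValueError("bundle has no planted reticulation")
    model = model or K80Model(bundle.config.titv)
    aug = best_augmentation(bundle.species_tree, bundle.genes, grid, model, cache)
    alt, degenerate = _alternate_displayed_tree(aug, bundle.species_tree)
    target = alt if not degenerate else bundle.species_tree
    rf = rf_distance(target, bundle.transferred_tree)
    return PlacementResult(
        seed=bundle.config.seed, diameter=bundle.truth.diameter,
        gamma_true=bundle.truth.gamma, genome_size=bundle.config.genome_size,
        rf=rf, gamma_hat=aug.gamma, degenerate=degenerate,
        log_likelihood=aug.log_likelihood)


def gamma_estimation_experiment(bundle: DatasetBundle,
                                grid: Sequence[float] | None = None,
                                model: K80Model | None = None,
                                cache: LikelihoodCache | None = None) -> float:
    """Estimate the inheritance probability with the edge placement fixed at
    the planted truth (gamma-only use of the argmax)."""
    if bundle.network is None:
        raise ValueError("bundle has no planted reticulation")
    model = model or K80Model(bundle.config.titv)
    grid = grid if grid is not None else default_gamma_grid()
    net = bundle.network
    (head,) = net.reticulation_nodes()
    (x1,) = [p for p in net.parents[head]
             if p not in set(bundle.species_tree.nodes())]
    gamma_hat, _ = optimize_new_gamma(net, (x1, head), bundle.genes, grid,
                                      model, cache)
    return gamma_hat


def model_selection_experiment(bundles: Sequence[DatasetBundle],
                               h_max: int = 4,
                               grid: Sequence[float] | None = None,
                               model: K80Model | None = None) -> pd.DataFrame:
    """Forward-search each data set to h_max and tabulate the selected number
    of reticulations under AIC and BIC plus the improvement sequence."""
    rows = []
    for b in bundles:
        mdl = model or K80Model(b.config.titv)
        traj = forward_search(b.species_tree, b.genes, h_max, grid, mdl,
                              LikelihoodCache())
        rows.append({
            "seed": b.config.seed,
            "genome_size": b.config.genome_size,
            "true_h": 0 if b.truth is None else 1,
            "selected_aic": traj.select("aic"),
            "selected_bic": traj.select("bic"),
            "improvements": traj.improvements,
            "n_sites": traj.n_sites,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diameter / height effect studies
# ---------------------------------------------------------------------------

def spr_variants(tree: PhyloTree, attachments: Sequence[tuple[str, str]]):
    """SPR variant trees for (donor taxon, recipient taxon) pendant-edge
    attachment pairs, with the diameter and height of each implied event."""
    out = []
    for donor, recipient in attachments:
        donor_edge = tree.edge_above(donor)
        recipient_edge = tree.edge_above(recipient)
        from .network import add_reticulation
        net = add_reticulation(as_network(tree), donor_edge, recipient_edge,
                               gamma=0.5)
        (head,) = net.reticulation_nodes()
        (x1,) = [p for p in net.parents[head] if p not in set(tree.nodes())]
        geom = reticulation_geometry(net, (x1, head))
        variant = apply_hgt(tree, donor_edge, recipient_edge)
        out.append((f"{donor}->{recipient}", geom, variant))
    return out


def _delta_lnl_table(tree: PhyloTree, variants, genes: GeneAlignmentSet,
                     model: K80Model, covariate: str) -> pd.DataFrame:
    cache = LikelihoodCache()
    base = cache.gene_log_likelihoods(tree, genes, model)
    rows = []
    for label, geom, variant in variants:
        alt = cache.gene_log_likelihoods(variant, genes, model)
        delta = alt - base
        rows.append({
            "variant": label,
            "diameter": geom.diameter,
            "height": geom.height,
            "mean_delta_lnl": float(delta.mean()),
            "sd_delta_lnl": float(delta.std(ddof=1)) if len(delta) > 1 else 0.0,
        })
    return pd.DataFrame(rows).sort_values(covariate).reset_index(drop=True)


def diameter_effect_study(tree: PhyloTree, variants,
                          genes: GeneAlignmentSet,
                          model: K80Model | None = None) -> pd.DataFrame:
    """Mean per-gene ln P(S_i|T') - ln P(S_i|T) for falsely postulated
    reticulations of increasing diameter (genes simulated on T)."""
    return _delta_lnl_table(tree, variants, genes, model or K80Model(), "diameter")


def height_effect_study(tree: PhyloTree, variants,
                        genes: GeneAlignmentSet,
                        model: K80Model | None = None) -> pd.DataFrame:
    """As the diameter study, with the event height as the covariate."""
    return _delta_lnl_table(tree, variants, genes, model or K80Model(), "height")
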