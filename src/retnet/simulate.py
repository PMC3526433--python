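"""Synthetic data: species trees, HGT gene trees, and K80 sequences.

The generator emulates the classic pipeline for studying horizontal gene
transfer detection: a species tree (fixed caterpillar, or a seeded
birth-death tree), a single planted reticulation built by midpoint attachment
(so the transferred gene tree is the corresponding SPR of the species tree),
a deterministic partition of the k genes between the two histories in
proportion gamma, and gene alignments of 100 sites simulated under K80 with
transition/transversion ratio 2, the root sequence drawn from the stationary
(uniform) base distribution.

Default study geometry: a 10-taxon caterpillar with pendant and internal
branches of 0.25 substitutions/site; the donor attachment is the midpoint of
taxon 3's pendant edge and recipients at taxa 4, 6 and 8 give reticulation
diameters of exactly 0.5, 1.0 and 1.5.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import Alignment, GeneAlignmentSet
from .network import (Edge, NetworkError, PhyloNetwork, PhyloTree,
                      add_reticulation, as_network, reticulation_geometry)
from .substitution import BASES, K80Model

__all__ = [
    "SimulationConfig",
    "HgtTruthRecord",
    "DatasetBundle",
    "make_species_tree",
    "apply_hgt",
    "partition_genes",
    "simulate_alignment",
    "simulate_gene_set",
    "make_hgt_bundle",
    "make_experiment_grid",
    "random_network",
    "recipient_for_diameter",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set."""
    n_taxa: int = 10
    tree_shape: str = "caterpillar"          # or "birth-death"
    pendant_length: float = 0.25
    internal_length: float = 0.25
    donor_taxon: str = "3"
    recipient_taxon: str | None = None       # None: no reticulation
    gamma: float = 0.3
    genome_size: int = 10                    # number of genes k
    sites_per_gene: int = 100
    titv: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_size < 1:
            raise ValueError("genome size must be >= 1")
        if self.sites_per_gene < 1:
            raise ValueError("sites per gene must be >= 1")
        if self.recipient_taxon is not None and not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0,1)")


@dataclass(frozen=True)
class HgtTruthRecord:
    """Ground truth for one planted transfer event."""
    event_id: str
    donor_edge: Edge
    recipient_edge: Edge
    gamma: float
    diameter: float
    height: float
    transferred_genes: tuple[int, ...]  # indices into the gene set


@dataclass
class DatasetBundle:
    """One simulated data set with its full ground truth."""
    config: SimulationConfig
    species_tree: PhyloTree
    network: PhyloNetwork | None
    transferred_tree: PhyloTree | None
    truth: HgtTruthRecord | None
    genes: GeneAlignmentSet


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def make_species_tree(n_taxa: int, shape: str = "caterpillar",
                      pendant_length: float = 0.25,
                      internal_length: float = 0.25,
                      seed: int | None = None,
                      birth_rate: float = 1.0,
                      death_rate: float = 0.0) -> PhyloTree:
    """Caterpillar (deterministic) or birth-death (seeded) species tree.

    Caterpillar taxa are labelled "1".."n" with taxa 1 and 2 forming the
    bottom cherry; internal node ``i<k>`` is the parent of taxon k.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if shape == "caterpillar":
        children: dict[str, tuple[str, ...]] = {"i2": ("1", "2")}
        lengths: dict[Edge, float] = {
            ("i2", "1"): pendant_length, ("i2", "2"): pendant_length}
        prev = "i2"
        for k in range(3, n_taxa + 1):
            node = f"i{k}"
            children[node] = (prev, str(k))
            lengths[(node, prev)] = internal_length
            lengths[(node, str(k))] = pendant_length
            prev = node
        return PhyloTree(prev, children, lengths)
    if shape == "birth-death":
        import dendropy
        from dendropy.model import birthdeath
        dtree = birthdeath.birth_death_tree(
            birth_rate=birth_rate, death_rate=death_rate,
            num_extant_tips=n_taxa, rng=random.Random(seed))
        dtree.suppress_unifurcations()
        children = {}
        lengths = {}
        counter = [0]
        names: dict = {}

        def name_of(nd) -> str:
            if nd in names:
                return names[nd]
            if nd.taxon is not None:
                names[nd] = nd.taxon.label.replace(" ", "_")
            else:
                counter[0] += 1
                names[nd] = f"i{counter[0]}"
            return names[nd]

        for nd in dtree.preorder_node_iter():
            kids = nd.child_nodes()
            if kids:
                children[name_of(nd)] = tuple(name_of(c) for c in kids)
                for c in kids:
                    lengths[(name_of(nd), name_of(c))] = float(c.edge.length or 0.0)
        return PhyloTree(name_of(dtree.seed_node), children, lengths)
    raise ValueError(f"unknown tree shape {shape!r}")


# ---------------------------------------------------------------------------
# HGT gene trees
# ---------------------------------------------------------------------------

def apply_hgt(tree: PhyloTree, donor_edge: Edge, recipient_edge: Edge) -> PhyloTree:
    """Gene tree of the genes transferred across an HGT edge.

    The recipient subtree is pruned and regrafted at the donor attachment
    point (an SPR move); by construction this equals the displayed tree of
    ``add_reticulation(tree, donor_edge, recipient_edge)`` that uses the new
    reticulation edge.
    """
    from .network import _display
    net = add_reticulation(as_network(tree), donor_edge, recipient_edge, gamma=0.5)
    (head,) = net.reticulation_nodes()
    (x1,) = [p for p in net.parents[head] if p not in set(tree.nodes())]
    return _display(net, {head: x1})


def partition_genes(k: int, gamma: float) -> tuple[int, int]:
    """Deterministic gene split: round(gamma*k) genes follow the transferred
    history, the rest the species tree.  Returns (base count, transferred)."""
    if k < 1:
        raise ValueError("genome size must be >= 1")
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0,1)")
    transferred = int(np.floor(gamma * k + 0.5))  # round half up
    return k - transferred, transferred


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: PhyloTree, sites: int,
                       model: K80Model | None = None,
                       seed: int | np.random.Generator = 0,
                       name: str = "") -> Alignment:
    """Evolve one alignment down a tree under K80.

    The root sequence is drawn uniformly over {A,C,G,T} (the K80 stationary
    distribution); each branch applies the closed-form transition matrix.
    """
    model = model or K80Model()
    if sites < 1:
        raise ValueError("need at least one site")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = [e for e in tree.edges() if e not in tree.lengths]
    if missing:
        raise NetworkError(f"edges without branch lengths: {missing}")
    states = {tree.root: rng.integers(0, 4, size=sites)}
    for v in tree.nodes():  # preorder
        for c in tree.children.get(v, ()):
            p = model.transition_matrix(tree.lengths[(v, c)])
            cum = np.cumsum(p, axis=1)[states[v]]       # (sites, 4)
            u = rng.random(sites)
            states[c] = (u[:, None] > cum).sum(axis=1)
    seqs = {leaf: "".join(BASES[s] for s in states[leaf]) for leaf in tree.leaves()}
    return Alignment(seqs, name=name)


def simulate_gene_set(base_tree: PhyloTree, k: int, sites: int,
                      model: K80Model | None = None,
                      seed: int = 0,
                      transferred_tree: PhyloTree | None = None,
                      gamma: float | None = None) -> tuple[GeneAlignmentSet, tuple[int, ...]]:
    """Simulate k genes; if a transferred tree and gamma are given, the *last*
    round(gamma*k) genes evolve on the transferred history.

    Returns the gene set and the indices of the transferred genes.
    """
    model = model or K80Model()
    if transferred_tree is not None:
        if gamma is None:
            raise ValueError("gamma required with a transferred tree")
        n_base, n_transferred = partition_genes(k, gamma)
    else:
        n_base, n_transferred = k, 0
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(k)
    genes = []
    for i in range(k):
        tree = base_tree if i < n_base else transferred_tree
        rng = np.random.default_rng(child_seeds[i])
        genes.append(simulate_alignment(tree, sites, model, rng, name=f"gene{i + 1}"))
    return GeneAlignmentSet(genes), tuple(range(n_base, k))


# ---------------------------------------------------------------------------
# experiment bundles
# ---------------------------------------------------------------------------

def recipient_for_diameter(diameter: float, donor_taxon: int = 3,
                           pendant_length: float = 0.25,
                           internal_length: float = 0.25) -> str:
    """Recipient taxon whose pendant-midpoint attachment realizes a diameter.

    On a caterpillar, attaching at the pendant midpoints of taxa d and r
    (r > d) gives diameter pendant + (r - d) * internal.
    """
    steps = (diameter - pendant_length) / internal_length
    r = donor_taxon + int(round(steps))
    if abs(pendant_length + (r - donor_taxon) * internal_length - diameter) > 1e-9 or r <= donor_taxon:
        raise ValueError(f"diameter {diameter} is not realizable on this caterpillar")
    return str(r)


def make_hgt_bundle(config: SimulationConfig) -> DatasetBundle:
    """Simulate one data set (with or without a planted reticulation)."""
    model = K80Model(config.titv)
    tree = make_species_tree(config.n_taxa, config.tree_shape,
                             config.pendant_length, config.internal_length,
                             seed=config.seed)
    if config.recipient_taxon is None:
        genes, _ = simulate_gene_set(tree, config.genome_size,
                                     config.sites_per_gene, model, config.seed)
        return DatasetBundle(config, tree, None, None, None, genes)

    donor_edge = tree.edge_above(config.donor_taxon)
    recipient_edge = tree.edge_above(config.recipient_taxon)
    net = add_reticulation(as_network(tree), donor_edge, recipient_edge,
                           gamma=config.gamma)
    (head,) = [v for v in net.reticulation_nodes()]
    (x1,) = [p for p in net.parents[head] if p not in set(tree.nodes())]
    new_edge = (x1, head)
    geom = reticulation_geometry(net, new_edge)
    t_alt = apply_hgt(tree, donor_edge, recipient_edge)
    genes, transferred = simulate_gene_set(
        tree, config.genome_size, config.sites_per_gene, model, config.seed,
        transferred_tree=t_alt, gamma=config.gamma)
    truth = HgtTruthRecord(
        event_id=f"hgt_{config.donor_taxon}_to_{config.recipient_taxon}",
        donor_edge=donor_edge, recipient_edge=recipient_edge,
        gamma=config.gamma, diameter=geom.diameter, height=geom.height,
        transferred_genes=transferred)
    return DatasetBundle(config, tree, net, t_alt, truth, genes)


def make_experiment_grid(diameters: Sequence[float] = (0.5, 1.0, 1.5),
                         gammas: Sequence[float] = (0.1, 0.3, 0.5),
                         genome_sizes: Sequence[int] = (10, 20, 40, 80),
                         replicates: int = 50,
                         base_seed: int = 0,
                         n_taxa: int = 10,
                         sites_per_gene: int = 100,
                         titv: float = 2.0) -> list[SimulationConfig]:
    """Full factorial of study conditions, one seeded config per replicate."""
    configs = []
    idx = 0
    for d in diameters:
        recipient = recipient_for_diameter(d)
        for g in gammas:
            for k in genome_sizes:
                for rep in range(replicates):
                    seed = int(np.random.SeedSequence(
                        entropy=base_seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31))
                    configs.append(SimulationConfig(
                        n_taxa=n_taxa, recipient_taxon=recipient, gamma=g,
                        genome_size=k, sites_per_gene=sites_per_gene,
                        titv=titv, seed=seed))
                    idx += 1
    return configs


# ---------------------------------------------------------------------------
# random networks (property testing, round-trip corpora)
# ---------------------------------------------------------------------------

def random_network(rng: np.random.Generator, n_taxa: int = 6,
                   n_reticulations: int = 1,
                   max_attempts: int = 200) -> PhyloNetwork:
    """Random binary network: random topology tree with random branch lengths,
    then random valid reticulation attachments with random gammas."""
    labels = [str(i + 1) for i in range(n_taxa)]
    nodes = list(labels)
    children: dict[str, tuple[str, ...]] = {}
    lengths: dict[Edge, float] = {}
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        parent = f"i{counter}"
        a, b = nodes[i], nodes[j]
        children[parent] = (a, b)
        lengths[(parent, a)] = float(rng.uniform(0.05, 0.5))
        lengths[(parent, b)] = float(rng.uniform(0.05, 0.5))
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [parent]
    net = PhyloNetwork(nodes[0], children, lengths)
    added = 0
    attempts = 0
    while added < n_reticulations and attempts < max_attempts:
        attempts += 1
        edges = sorted(net.lengths)
        e1 = edges[rng.integers(len(edges))]
        e2 = edges[rng.integers(len(edges))]
        g = float(rng.uniform(0.05, 0.95))
        try:
            net = add_reticulation(net, e1, e2, gamma=g,
                                   length=float(rng.uniform(0.0, 0.2)))
            added += 1
        except NetworkError:
            continue
    if added < n_reticulations:
        raise RuntimeError("could not place the requested reticulations")
    return net
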