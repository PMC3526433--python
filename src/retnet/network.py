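"""Rooted binary phylogenetic networks and trees.

A phylogenetic network is a rooted, directed, acyclic graph whose root has
out-degree 2, whose leaves are labelled by taxa, whose internal tree nodes
have in-degree 1 / out-degree 2, and whose reticulation nodes (horizontal
gene transfer or hybridization events) have in-degree 2 / out-degree 1.
Each reticulation edge carries an inheritance probability gamma, and the two
edges entering a reticulation node have gammas summing to one.  A tree is
the special case with no reticulation nodes.

Branch lengths are in expected substitutions per site.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

Edge = tuple[str, str]

__all__ = [
    "Edge",
    "NetworkError",
    "PhyloTree",
    "PhyloNetwork",
    "ReticulationGeometry",
    "validate",
    "contained_trees",
    "mixture_components",
    "tree_probability",
    "add_reticulation",
    "reticulation_geometry",
    "rf_distance",
    "as_network",
    "as_tree",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or illegal operations."""


def _fmt_len(x: float) -> str:
    return repr(float(x))


class PhyloTree:
    """Rooted binary tree with branch lengths and taxon-labelled leaves."""

    def __init__(self, root: str, children: Mapping[str, Sequence[str]],
                 lengths: Mapping[Edge, float]):
        self.root = root
        self.children: dict[str, tuple[str, ...]] = {
            v: tuple(cs) for v, cs in children.items() if cs
        }
        self.lengths: dict[Edge, float] = dict(lengths)
        self.parent: dict[str, str] = {}
        for v, cs in self.children.items():
            for c in cs:
                self.parent[c] = v

    # -- basic structure ---------------------------------------------------
    def nodes(self) -> list[str]:
        seen = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            seen.append(v)
            stack.extend(reversed(self.children.get(v, ())))
        return seen

    def leaves(self) -> list[str]:
        return [v for v in self.nodes() if v not in self.children]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaves()))

    def edges(self) -> list[Edge]:
        return [(v, c) for v in self.nodes() for c in self.children.get(v, ())]

    def postorder(self) -> list[str]:
        out: list[str] = []

        def rec(v: str) -> None:
            for c in self.children.get(v, ()):
                rec(c)
            out.append(v)

        rec(self.root)
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root, self.children, self.lengths)

    def edge_above(self, node: str) -> Edge:
        if node not in self.parent:
            raise KeyError(f"node {node!r} has no parent edge")
        return (self.parent[node], node)

    def leaves_below(self, node: str) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            cs = self.children.get(v, ())
            if cs:
                stack.extend(cs)
            else:
                out.append(v)
        return frozenset(out)

    def total_length(self) -> float:
        return float(sum(self.lengths.values()))

    def depths(self) -> dict[str, float]:
        d = {self.root: 0.0}
        for v in self.nodes():
            for c in self.children.get(v, ()):
                d[c] = d[v] + self.lengths[(v, c)]
        return d

    def path_length(self, a: str, b: str) -> float:
        """Undirected path length between two nodes of the tree."""
        depth = self.depths()
        anc_a = {a}
        v = a
        while v in self.parent:
            v = self.parent[v]
            anc_a.add(v)
        v = b
        while v not in anc_a:
            v = self.parent[v]
        lca = v
        return depth[a] + depth[b] - 2.0 * depth[lca]

    # -- canonical forms ---------------------------------------------------
    def canonical_newick(self, lengths: bool = True) -> str:
        """Rooted canonical Newick (children sorted by smallest leaf label)."""

        def rec2(v: str) -> tuple[str, str]:
            cs = self.children.get(v, ())
            if not cs:
                return v, v
            subs = []
            for c in cs:
                mn, s = rec2(c)
                if lengths:
                    s = f"{s}:{_fmt_len(self.lengths[(v, c)])}"
                subs.append((mn, s))
            subs.sort()
            return subs[0][0], "(" + ",".join(s for _, s in subs) + ")"

        return rec2(self.root)[1] + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each encoded as the half *not*
        containing the lexicographically smallest taxon."""
        taxa = frozenset(self.leaves())
        ref = min(taxa)
        out: set[frozenset[str]] = set()
        for v in self.nodes():
            if v == self.root or v not in self.children:
                continue
            below = self.leaves_below(v)
            side = taxa - below if ref in below else below
            if 2 <= len(side) <= len(taxa) - 2:
                out.add(frozenset(side))
        return out


class PhyloNetwork:
    """Rooted binary phylogenetic network with inheritance probabilities.

    ``children`` maps every non-leaf node to its ordered children; ``lengths``
    maps each directed edge to its branch length; ``gamma`` maps each
    reticulation edge (an edge whose head has in-degree 2) to its inheritance
    probability.
    """

    def __init__(self, root: str, children: Mapping[str, Sequence[str]],
                 lengths: Mapping[Edge, float],
                 gamma: Mapping[Edge, float] | None = None):
        self.root = root
        self.children: dict[str, tuple[str, ...]] = {
            v: tuple(cs) for v, cs in children.items() if cs
        }
        self.lengths: dict[Edge, float] = dict(lengths)
        self.gamma: dict[Edge, float] = dict(gamma or {})
        self.parents: dict[str, tuple[str, ...]] = {}
        for v, cs in self.children.items():
            for c in cs:
                self.parents[c] = self.parents.get(c, ()) + (v,)

    # -- structure ---------------------------------------------------------
    def nodes(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            out.append(v)
            stack.extend(reversed(self.children.get(v, ())))
        return out

    def edges(self) -> list[Edge]:
        return [(v, c) for v in self.nodes() for c in self.children.get(v, ())]

    def leaves(self) -> list[str]:
        return [v for v in self.nodes() if v not in self.children]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaves()))

    def in_degree(self, v: str) -> int:
        return len(self.parents.get(v, ()))

    def out_degree(self, v: str) -> int:
        return len(self.children.get(v, ()))

    def reticulation_nodes(self) -> list[str]:
        return sorted(v for v in self.nodes() if self.in_degree(v) == 2)

    def reticulation_edges(self) -> list[Edge]:
        return [(p, v) for v in self.reticulation_nodes()
                for p in self.parents[v]]

    @property
    def n_reticulations(self) -> int:
        return len(self.reticulation_nodes())

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(self.root, self.children, self.lengths, self.gamma)

    def edge_above(self, node: str) -> Edge:
        ps = self.parents.get(node, ())
        if len(ps) != 1:
            raise KeyError(f"node {node!r} does not have a unique parent edge")
        return (ps[0], node)

    def leaves_below(self, node: str) -> frozenset[str]:
        out: set[str] = set()
        stack = [node]
        seen: set[str] = set()
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            cs = self.children.get(v, ())
            if cs:
                stack.extend(cs)
            else:
                out.add(v)
        return frozenset(out)

    def is_reachable(self, src: str, dst: str) -> bool:
        """True iff ``dst`` is ``src`` or a (directed) descendant of it."""
        stack = [src]
        seen: set[str] = set()
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self.children.get(v, ()))
        return False


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(network: PhyloNetwork) -> list[str]:
    """Diagnose violations of the network invariants.

    Returns an empty list iff the object is a valid binary rooted
    phylogenetic network: correct node degrees, acyclic, all branch lengths
    non-negative, and inheritance probabilities summing to one at every
    reticulation node.
    """
    v9n: list[str] = []
    # collect all nodes mentioned anywhere (not only those reachable)
    nodes = set(network.children) | {
        c for cs in network.children.values() for c in cs
    } | {network.root}
    indeg = {v: 0 for v in nodes}
    for v, cs in network.children.items():
        for c in cs:
            indeg[c] += 1

    if indeg.get(network.root, 0) != 0:
        v9n.append(f"root {network.root!r} has in-degree {indeg[network.root]}, expected 0")
    if network.out_degree(network.root) != 2:
        v9n.append(
            f"root {network.root!r} has out-degree "
            f"{network.out_degree(network.root)}, expected 2"
        )
    for v in sorted(nodes):
        din, dout = indeg[v], len(network.children.get(v, ()))
        if v == network.root:
            continue
        if din == 0:
            v9n.append(f"node {v!r} is unreachable (in-degree 0, not the root)")
        elif din == 1 and dout not in (0, 2):
            v9n.append(f"tree node {v!r} has out-degree {dout}, expected 0 or 2")
        elif din == 2 and dout != 1:
            v9n.append(f"reticulation node {v!r} has out-degree {dout}, expected 1")
        elif din > 2:
            v9n.append(f"node {v!r} has in-degree {din} > 2")

    # acyclicity (Kahn)
    deg = dict(indeg)
    queue = [v for v in nodes if deg[v] == 0]
    visited = 0
    while queue:
        v = queue.pop()
        visited += 1
        for c in network.children.get(v, ()):
            deg[c] -= 1
            if deg[c] == 0:
                queue.append(c)
    if visited != len(nodes):
        v9n.append("cycle: graph contains a directed cycle")

    for e, length in network.lengths.items():
        if length < 0:
            v9n.append(f"edge {e} has negative length {length}")
    for v, cs in network.children.items():
        for c in cs:
            if (v, c) not in network.lengths:
                v9n.append(f"edge {(v, c)} has no branch length")

    for v in sorted(nodes):
        if indeg[v] == 2:
            gs = [network.gamma.get((p, v)) for p in network.parents.get(v, ())]
            if any(g is None for g in gs):
                v9n.append(f"reticulation node {v!r}: missing inheritance probability")
            elif any(not (0.0 <= g <= 1.0) for g in gs):
                v9n.append(f"reticulation node {v!r}: inheritance probability outside [0,1]")
            elif abs(sum(gs) - 1.0) > 1e-9:
                v9n.append(
                    f"reticulation node {v!r}: inheritance probabilities do not sum to 1 "
                    f"(sum={sum(gs):.6g})"
                )

    # leaf labels form the taxon set: duplicates impossible in this encoding,
    # but empty taxa are not allowed
    if not network.leaves():
        v9n.append("network has no leaves")
    return v9n


def _require_valid(network: PhyloNetwork) -> None:
    problems = validate(network)
    if problems:
        raise NetworkError("invalid network: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# displayed trees
# ---------------------------------------------------------------------------

def _induction_choices(network: PhyloNetwork) -> Iterator[tuple[dict[str, str], float]]:
    """Yield (kept-parent map, probability weight) for each way of keeping one
    incoming edge per reticulation node; weight = product of the kept gammas."""
    retics = network.reticulation_nodes()
    parent_options = [sorted(network.parents[v]) for v in retics]
    for combo in itertools.product(*parent_options):
        kept = dict(zip(retics, combo))
        w = 1.0
        for v, p in kept.items():
            w *= network.gamma[(p, v)]
        yield kept, w


def _display(network: PhyloNetwork, kept: Mapping[str, str]) -> PhyloTree:
    """Displayed tree for one induction choice: drop the unused reticulation
    edges, prune subtrees left without leaves, and suppress all degree-two
    nodes, summing merged branch lengths."""
    children = {v: list(cs) for v, cs in network.children.items()}
    lengths = dict(network.lengths)
    parent: dict[str, str] = {}
    for v in network.reticulation_nodes():
        for p in network.parents[v]:
            if p != kept[v]:
                children[p].remove(v)
                del lengths[(p, v)]
    for v, cs in children.items():
        for c in cs:
            parent[c] = v

    root = network.root
    real_leaves = set(network.leaves())

    def out_deg(v: str) -> int:
        return len(children.get(v, ()))

    # prune dangling internal nodes (no surviving leaf below), e.g. a
    # reticulation node whose only child chose its other parent
    dangling = [v for v in list(children) if not children[v] and v not in real_leaves]
    while dangling:
        u = dangling.pop()
        children.pop(u, None)
        p = parent.pop(u, None)
        if p is not None:
            children[p].remove(u)
            del lengths[(p, u)]
            if not children[p] and p not in real_leaves:
                dangling.append(p)

    # suppress in-1/out-1 nodes; re-root past out-degree-1 roots
    pending = [v for v in children if v != root and out_deg(v) == 1]
    while pending or out_deg(root) == 1:
        if pending:
            u = pending.pop()
            if u == root or out_deg(u) != 1 or u not in parent:
                continue
            p, (c,) = parent[u], children[u]
            lengths[(p, c)] = lengths.pop((p, u)) + lengths.pop((u, c))
            children[p][children[p].index(u)] = c
            parent[c] = p
            del children[u]
        else:
            (c,) = children[root]
            del lengths[(root, c)]
            del children[root]
            parent.pop(c, None)
            root = c
            if out_deg(root) == 1:
                pending.append(root)
    return PhyloTree(root, children, lengths)


def mixture_components(network: PhyloNetwork,
                       check: bool = True) -> list[tuple[PhyloTree, float]]:
    """Displayed trees with their probabilities, merged only when both the
    topology and the branch lengths coincide (the form needed for the
    likelihood mixture)."""
    if check:
        _require_valid(network)
    comps: dict[str, tuple[PhyloTree, float]] = {}
    for kept, w in _induction_choices(network):
        t = _display(network, kept)
        key = t.canonical_newick()
        if key in comps:
            comps[key] = (comps[key][0], comps[key][1] + w)
        else:
            comps[key] = (t, w)
    return [comps[k] for k in sorted(comps)]


def contained_trees(network: PhyloNetwork) -> list[tuple[PhyloTree, float]]:
    """All trees displayed by the network with P(T | N, gamma).

    Enumerates the 2^h induction choices, suppresses degree-two nodes (summing
    the lengths of merged edges), merges choices whose *unrooted topologies*
    coincide, and sums their induction-set weights.  The representative tree
    of a merged class is the one from the first induction choice in
    deterministic order.
    """
    _require_valid(network)
    groups: dict[frozenset, tuple[PhyloTree, float, str]] = {}
    for kept, w in _induction_choices(network):
        t = _display(network, kept)
        key = frozenset(t.bipartitions())
        if key in groups:
            rep, tot, rep_nwk = groups[key]
            groups[key] = (rep, tot + w, rep_nwk)
        else:
            groups[key] = (t, w, t.canonical_newick())
    return sorted(
        ((t, w) for t, w, _ in groups.values()),
        key=lambda tw: tw[0].canonical_newick(),
    )


def tree_probability(network: PhyloNetwork, tree: PhyloTree) -> float:
    """P(T | N, gamma): total induction-set weight of all ways the network
    displays the tree's (unrooted) topology; 0 if not displayed."""
    if set(tree.leaves()) != set(network.leaves()):
        raise NetworkError("tree and network are on different taxon sets")
    want = frozenset(tree.bipartitions())
    total = 0.0
    found = False
    for t, w in contained_trees(network):
        if frozenset(t.bipartitions()) == want:
            total += w
            found = True
    return total if found else 0.0


# ---------------------------------------------------------------------------
# reticulation attachment
# ---------------------------------------------------------------------------

def _fresh(network: PhyloNetwork, base: str) -> str:
    used = set(network.nodes())
    if base not in used:
        return base
    i = 2
    while f"{base}_{i}" in used:
        i += 1
    return f"{base}_{i}"


def add_reticulation(network: PhyloNetwork, donor_edge: Edge,
                     recipient_edge: Edge, gamma: float,
                     length: float = 0.0) -> PhyloNetwork:
    """Attach a new reticulation edge between the midpoints of two edges.

    Both edges are subdivided into two halves of equal length; a new
    reticulation edge of the given ``length`` (default 0: an instantaneous
    transfer) is drawn from the donor midpoint to the recipient midpoint, with
    inheritance probability ``gamma`` on the new edge and ``1 - gamma`` on the
    recipient's original (subdivided) parent edge.
    """
    if donor_edge == recipient_edge:
        raise NetworkError("identical edges: cannot attach a reticulation to one edge twice")
    edges = set(network.lengths)
    for e in (donor_edge, recipient_edge):
        if e not in edges:
            raise NetworkError(f"edge {e} not in network")
    (u1, v1), (u2, v2) = donor_edge, recipient_edge
    if u1 == u2:
        raise NetworkError("sibling edges: both edges emanate from the same node")
    if not (0.0 < gamma < 1.0):
        raise NetworkError(f"gamma must be in (0,1), got {gamma}")
    # cycle: new edge x1 -> x2 closes a cycle iff x1 is below x2, i.e. iff the
    # tail of the donor edge is reachable from the head of the recipient edge
    if network.is_reachable(v2, u1):
        raise NetworkError("would create cycle: donor attachment lies below the recipient edge")

    new = network.copy()
    h = new.n_reticulations + 1
    x1 = _fresh(new, f"d{h}")
    x2 = _fresh(new, f"h{h}")

    def subdivide(net: PhyloNetwork, edge: Edge, mid: str) -> None:
        u, v = edge
        half = net.lengths.pop(edge) / 2.0
        cs = list(net.children[u])
        cs[cs.index(v)] = mid
        net.children[u] = tuple(cs)
        net.children[mid] = (v,)
        net.lengths[(u, mid)] = half
        net.lengths[(mid, v)] = half
        if edge in net.gamma:
            # lower half keeps the inheritance probability (its head is still
            # the reticulation node)
            net.gamma[(mid, v)] = net.gamma.pop(edge)
        ps = list(net.parents[v])
        ps[ps.index(u)] = mid
        net.parents[v] = tuple(ps)
        net.parents[mid] = (u,)

    subdivide(new, donor_edge, x1)
    subdivide(new, recipient_edge, x2)
    new.children[x1] = new.children[x1] + (x2,)
    new.lengths[(x1, x2)] = float(length)
    new.parents[x2] = new.parents[x2] + (x1,)
    new.gamma[(x1, x2)] = float(gamma)
    new.gamma[(u2, x2)] = 1.0 - float(gamma)
    return new


# ---------------------------------------------------------------------------
# reticulation geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReticulationGeometry:
    """Diameter and height of a reticulation edge.

    diameter: path length (substitutions/site) between the donor and recipient
    attachment points along the underlying tree (the network without the
    reticulation edge itself).  height: sum of the path lengths from the two
    attachment points down to their farthest descendant leaves.
    """
    diameter: float
    height: float


def reticulation_geometry(network: PhyloNetwork, edge: Edge) -> ReticulationGeometry:
    import networkx as nx

    x1, x2 = edge
    if network.in_degree(x2) != 2 or edge not in network.gamma:
        raise NetworkError(f"{edge} is not a reticulation edge")
    lengths = {e: l for e, l in network.lengths.items() if e != edge}
    g = nx.Graph()
    for (u, v), l in lengths.items():
        # parallel paths: keep the shorter (shortest-path semantics)
        if g.has_edge(u, v):
            l = min(l, g[u][v]["weight"])
        g.add_edge(u, v, weight=l)
    diameter = nx.dijkstra_path_length(g, x1, x2, weight="weight")

    children = {v: [c for c in cs if (v, c) != edge]
                for v, cs in network.children.items()}

    def down(v: str, memo: dict[str, float]) -> float:
        if v in memo:
            return memo[v]
        cs = children.get(v, ())
        memo[v] = 0.0 if not cs else max(lengths[(v, c)] + down(c, memo) for c in cs)
        return memo[v]

    memo: dict[str, float] = {}
    return ReticulationGeometry(diameter=float(diameter),
                                height=float(down(x1, memo) + down(x2, memo)))


# ---------------------------------------------------------------------------
# Robinson-Foulds distance
# ---------------------------------------------------------------------------

def rf_distance(tree1: PhyloTree, tree2: PhyloTree) -> int:
    """Unnormalized Robinson-Foulds distance: the number of non-trivial
    unrooted bipartitions present in exactly one of the two trees."""
    if set(tree1.leaves()) != set(tree2.leaves()):
        raise NetworkError("trees are on different taxon sets")
    return len(tree1.bipartitions() ^ tree2.bipartitions())


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def as_network(tree: PhyloTree) -> PhyloNetwork:
    """View a tree as a reticulation-free network."""
    return PhyloNetwork(tree.root, tree.children, tree.lengths)


def as_tree(network: PhyloNetwork) -> PhyloTree:
    if network.n_reticulations:
        raise NetworkError("network has reticulation nodes; not a tree")
    return PhyloTree(network.root, network.children, network.lengths)
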