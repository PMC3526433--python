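"""Newick and extended-Newick (eNewick) reading and writing.

Trees are plain Newick with branch lengths.  Networks use the eNewick dialect
in which each reticulation node appears twice under a ``#H<k>`` tag: once with
its subtree (the "primary" occurrence) and once as a bare ``#H<k>`` reference.
Inheritance probabilities ride in the third colon field of the two
reticulation edges, as in PhyloNet/Dendroscope::

    ((1:0.1,(2:0.05)#H1:0.0::0.3):0.1,(#H1:0.05::0.7,3:0.1):0.1);

i.e. ``label:length:support:gamma`` with the (unused) support field left
empty.  The writer emits a canonical form (children ordered by smallest leaf
label) that round-trips bit-exactly through the parser.
"""
from __future__ import annotations

from pathlib import Path

from .network import Edge, NetworkError, PhyloNetwork, PhyloTree, validate

__all__ = [
    "NewickParseError",
    "parse_newick",
    "parse_tree_file",
    "write_newick",
    "write_enewick",
    "write_tree_file",
]


class NewickParseError(ValueError):
    def __init__(self, message: str, position: int, text: str = ""):
        prefix = text[:position]
        self.line = prefix.count("\n") + 1
        self.column = position - (prefix.rfind("\n") + 1) + 1
        super().__init__(f"{message} (line {self.line}, column {self.column})")
        self.position = position


_SPECIALS = set("(),;:#")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.i = 0
        self.counter = 0
        self.children: dict[str, list[str]] = {}
        self.lengths: dict[Edge, float] = {}
        self.gamma: dict[Edge, float] = {}
        self.hybrids: dict[str, str] = {}

    def error(self, msg: str):
        raise NewickParseError(msg, self.i, self.text)

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.i] if self.i < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.i < len(self.text) and self.text[self.i].isspace():
            self.i += 1

    def fresh(self) -> str:
        self.counter += 1
        return f"n{self.counter}"

    def read_label(self) -> str:
        self.skip_ws()
        start = self.i
        while self.i < len(self.text) and self.text[self.i] not in _SPECIALS \
                and not self.text[self.i].isspace():
            self.i += 1
        return self.text[start:self.i]

    def read_number(self, what: str) -> float:
        self.skip_ws()
        start = self.i
        while self.i < len(self.text) and (self.text[self.i] in "+-.eE"
                                           or self.text[self.i].isdigit()):
            self.i += 1
        if start == self.i:
            self.error(f"expected {what}")
        try:
            return float(self.text[start:self.i])
        except ValueError:
            self.error(f"malformed {what} {self.text[start:self.i]!r}")

    def parse(self) -> PhyloNetwork:
        root, _, _ = self.parse_node()
        if self.peek() != ";":
            self.error("expected ';'")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            self.error("trailing characters after ';'")
        return PhyloNetwork(root, self.children, self.lengths, self.gamma)

    def parse_node(self) -> tuple[str, float | None, float | None]:
        """Parse one node; returns (node id, branch length, gamma)."""
        kids: list[str] = []
        if self.peek() == "(":
            self.i += 1
            while True:
                child, length, g = self.parse_node()
                kids.append(child)
                edge_len = 0.0 if length is None else length
                # edges recorded by the caller below once this node has an id;
                # stash on a temp list
                self._pending.append((child, edge_len, g))
                ch = self.peek()
                if ch == ",":
                    self.i += 1
                    continue
                if ch == ")":
                    self.i += 1
                    break
                self.error("expected ',' or ')'")
        label = self.read_label()
        hybrid_id = None
        if self.peek() == "#":
            self.i += 1
            hybrid_id = self.read_label()
            if not hybrid_id:
                self.error("empty hybrid tag after '#'")
        length = support = g = None
        if self.peek() == ":":
            self.i += 1
            if self.peek() != ":":
                length = self.read_number("branch length")
            if self.peek() == ":":
                self.i += 1
                if self.peek() != ":":
                    support = self.read_number("support value")
                if self.peek() == ":":
                    self.i += 1
                    g = self.read_number("inheritance probability")
        del support  # parsed for dialect compatibility, not stored

        if hybrid_id is not None:
            if hybrid_id in self.hybrids:
                node = self.hybrids[hybrid_id]
                if kids:
                    if node in self.children and self.children[node]:
                        self.error(f"hybrid #{hybrid_id} has a subtree at both occurrences")
                    self.children[node] = kids
            else:
                node = label if label else f"#{hybrid_id}"
                self.hybrids[hybrid_id] = node
                if kids:
                    self.children[node] = kids
        else:
            if not kids and not label:
                self.error("leaf with empty label")
            node = label if label else self.fresh()
            if kids:
                self.children[node] = kids
        # attach the pending child edges parsed inside our parentheses
        if kids:
            for child, edge_len, cg in self._pop_pending(len(kids)):
                self.lengths[(node, child)] = edge_len
                if cg is not None:
                    self.gamma[(node, child)] = cg
        return node, length, g

    # child-edge bookkeeping: parse_node for a child returns before the parent
    # id exists, so (child, length, gamma) triples wait on a stack
    @property
    def _pending(self) -> list:
        if not hasattr(self, "_pend"):
            self._pend: list = []
        return self._pend

    def _pop_pending(self, n: int) -> list:
        out = self._pending[-n:]
        del self._pending[-n:]
        return out


def _postprocess_gamma(net: PhyloNetwork) -> None:
    """Fill in complementary inheritance probabilities where only one of a
    reticulation node's two incoming edges was annotated."""
    for v in net.reticulation_nodes():
        ps = net.parents[v]
        es = [(p, v) for p in ps]
        known = [e for e in es if e in net.gamma]
        if len(known) == 1:
            (e_known,) = known
            (e_other,) = [e for e in es if e != e_known]
            net.gamma[e_other] = 1.0 - net.gamma[e_known]


def parse_newick(text: str) -> PhyloNetwork | PhyloTree:
    """Parse a Newick tree or eNewick network string."""
    net = _Parser(text.strip()).parse()
    _postprocess_gamma(net)
    problems = validate(net)
    if problems:
        raise NetworkError("parsed network is invalid: " + "; ".join(problems))
    if not net.n_reticulations:
        return PhyloTree(net.root, net.children, net.lengths)
    return net


def parse_tree_file(path: str | Path) -> PhyloNetwork | PhyloTree:
    return parse_newick(Path(path).read_text())


def _fmt(x: float) -> str:
    return repr(float(x))


def write_newick(tree: PhyloTree) -> str:
    """Canonical Newick string for a tree."""
    return tree.canonical_newick()


def write_enewick(obj: PhyloNetwork | PhyloTree) -> str:
    """Canonical eNewick string; plain Newick when there are no reticulations.

    Hybrid numbering, primary-parent choice, and child ordering derive from
    node-name-free structural signatures, so the canonical form is a fixed
    point of write(parse(.)).
    """
    if isinstance(obj, PhyloTree):
        return obj.canonical_newick()
    net = obj

    def edge_ann(u: str, v: str) -> str:
        ann = f":{_fmt(net.lengths[(u, v)])}"
        if (u, v) in net.gamma:
            ann += f"::{_fmt(net.gamma[(u, v)])}"
        return ann

    sig: dict[str, str] = {}

    def sigf(v: str) -> str:
        if v not in sig:
            cs = net.children.get(v, ())
            if not cs:
                sig[v] = v
            else:
                sig[v] = "(" + ",".join(
                    sorted(sigf(c) + edge_ann(v, c) for c in cs)) + ")"
        return sig[v]

    sigf(net.root)

    def retic_key(v: str):
        return (sigf(v), sorted((sigf(p), edge_ann(p, v)) for p in net.parents[v]))

    retics = sorted(net.reticulation_nodes(), key=retic_key)
    tag = {v: f"H{i + 1}" for i, v in enumerate(retics)}
    primary = {v: min(net.parents[v], key=lambda p: (sigf(p), edge_ann(p, v)))
               for v in retics}

    def rec(v: str, via: str | None) -> str:
        if v in tag and via is not None and via != primary[v]:
            return f"#{tag[v]}"
        cs = net.children.get(v, ())
        if not cs:
            return v
        subs = sorted(rec(c, v) + edge_ann(v, c) for c in cs)
        body = "(" + ",".join(subs) + ")"
        if v in tag:
            body += f"#{tag[v]}"
        return body

    return rec(net.root, None) + ";"


def write_tree_file(obj: PhyloNetwork | PhyloTree, path: str | Path) -> None:
    Path(path).write_text(write_enewick(obj) + "\n")
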