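"""Tree data model and combinatorial operations for cell lineage trees.

A cell lineage tree is a phylogenetic tree whose leaves are labelled by
sampled cells.  Under the infinite-sites (IS) model each edge carries the
probability that a mutation occurs on it; the probabilities over all edges
sum to one.  "Fake" edges are terminal edges with mutation probability zero;
they attach a sampled cell that is genomically identical to one of its
ancestors and therefore never acquires a private mutation.

This module provides the :class:`LineageTree` container plus restriction,
quartet/triplet encodings, bipartitions, refinement checks, false-negative /
false-positive branch error, and exhaustive topology enumeration for the
exact solvers.
"""

from __future__ import annotations

import itertools
import sys
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "LineageTree",
    "Bipartition",
    "Quartet",
    "Triplet",
    "TreeErrorReport",
    "parse_newick",
    "enumerate_unrooted_binary",
    "enumerate_rooted_binary",
]

PROB_SUM_TOL = 1e-9
DEFAULT_ENUM_CAP = 8

# lineage fixtures contain chains of >1000 edges; recursive traversals need
# stack depth proportional to tree height
sys.setrecursionlimit(max(50000, sys.getrecursionlimit()))


# ---------------------------------------------------------------------------
# small combinatorial value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A split of a label set into two disjoint, covering blocks.

    Canonical orientation: the side containing the lexicographically
    smallest label is stored first, so equality and hashing are
    orientation-invariant.
    """

    side1: frozenset
    side2: frozenset

    @staticmethod
    def of(a: Iterable[str], b: Iterable[str]) -> "Bipartition":
        fa, fb = frozenset(a), frozenset(b)
        if not fa or not fb:
            raise ValueError("both sides of a bipartition must be non-empty")
        if fa & fb:
            raise ValueError("bipartition sides must be disjoint")
        if min(fa) > min(fb):
            fa, fb = fb, fa
        return Bipartition(fa, fb)

    @property
    def labels(self) -> frozenset:
        return self.side1 | self.side2

    @property
    def is_internal(self) -> bool:
        return len(self.side1) >= 2 and len(self.side2) >= 2

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return "{}|{}".format(",".join(sorted(self.side1)), ",".join(sorted(self.side2)))


@dataclass(frozen=True)
class Quartet:
    """An unrooted binary tree on four labels, e.g. ``A,B|C,D``.

    Canonical orientation: each pair sorted, the pair containing the
    smallest of the four labels first.
    """

    pair1: tuple
    pair2: tuple

    @staticmethod
    def of(pair_a: Iterable[str], pair_b: Iterable[str]) -> "Quartet":
        pa = tuple(sorted(pair_a))
        pb = tuple(sorted(pair_b))
        if len(pa) != 2 or len(pb) != 2 or len({*pa, *pb}) != 4:
            raise ValueError("a quartet needs four distinct labels split 2|2")
        if pa[0] > pb[0]:
            pa, pb = pb, pa
        return Quartet(pa, pb)

    @property
    def labels(self) -> frozenset:
        return frozenset(self.pair1) | frozenset(self.pair2)

    def __str__(self) -> str:
        return "{},{}|{},{}".format(*self.pair1, *self.pair2)


def quartet_topologies(labels: Iterable[str]) -> list:
    """The three possible quartets on a 4-label set, in a fixed order."""
    a, b, c, d = sorted(labels)
    return [Quartet.of((a, b), (c, d)), Quartet.of((a, c), (b, d)), Quartet.of((a, d), (b, c))]


@dataclass(frozen=True)
class Triplet:
    """A rooted binary tree on three labels: an outgroup and a cherry pair."""

    outgroup: str
    cherry: frozenset

    @staticmethod
    def of(outgroup: str, cherry: Iterable[str]) -> "Triplet":
        ch = frozenset(cherry)
        if len(ch) != 2 or outgroup in ch:
            raise ValueError("a triplet needs three distinct labels")
        return Triplet(outgroup, ch)

    @property
    def labels(self) -> frozenset:
        return self.cherry | {self.outgroup}

    def __str__(self) -> str:
        return "{}|{},{}".format(self.outgroup, *sorted(self.cherry))


def triplet_topologies(labels: Iterable[str]) -> list:
    """The three possible triplets on a 3-label set (outgroups in sorted order)."""
    lab = sorted(labels)
    return [Triplet.of(x, set(lab) - {x}) for x in lab]


@dataclass(frozen=True)
class TreeErrorReport:
    """Branch error between a reference tree and an estimate.

    A false negative branch is an internal bipartition of the reference
    missing from the estimate; a false positive branch is the reverse.
    For unresolved (non-binary) reference trees the false-negative count is
    the headline metric: it is zero exactly when the estimate refines the
    reference.
    """

    false_negative_branches: int
    false_positive_branches: int


# ---------------------------------------------------------------------------
# the tree container
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children", "prob", "fake")

    def __init__(self, label=None, prob=None, fake=False):
        self.label = label
        self.children: list = []
        self.prob = prob  # probability on the edge to the parent (None at root)
        self.fake = fake

    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "_Node":
        n = _Node(self.label, self.prob, self.fake)
        n.children = [c.copy() for c in self.children]
        return n


class LineageTree:
    """Rooted or unrooted labelled tree with per-edge mutation probabilities.

    The tree is stored parent-to-child from an anchor node.  For a rooted
    tree the anchor is the root; for an unrooted tree the anchor is an
    arbitrary internal vertex and edge direction carries no meaning.

    ``unsampled_mass`` is the probability that a mutation falls on an edge
    of a larger tree with no sampled descendant; restriction accumulates it
    so that edge probabilities plus ``unsampled_mass`` always sum to one.
    A mutation drawn from that mass yields the all-zero pattern.
    """

    def __init__(self, root: _Node, rooted: bool = True, unsampled_mass=0):
        self.root = root
        self.rooted = rooted
        self.unsampled_mass = unsampled_mass

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def from_nested(spec, rooted: bool = True) -> "LineageTree":
        """Build a tree from nested tuples/lists.

        Leaves are ``label`` or ``(label, prob)`` or ``(label, prob, fake)``;
        internal vertices are ``(children_list, prob)`` or ``children_list``.
        """

        def build(node_spec):
            if isinstance(node_spec, str):
                return _Node(node_spec)
            if isinstance(node_spec, tuple) and node_spec and isinstance(node_spec[0], str):
                label = node_spec[0]
                prob = node_spec[1] if len(node_spec) > 1 else None
                fake = node_spec[2] if len(node_spec) > 2 else False
                return _Node(label, prob, fake)
            if isinstance(node_spec, tuple) and isinstance(node_spec[0], list):
                children, prob = node_spec
                n = _Node(prob=prob)
                n.children = [build(c) for c in children]
                return n
            if isinstance(node_spec, list):
                n = _Node()
                n.children = [build(c) for c in node_spec]
                return n
            raise TypeError(f"bad node spec: {node_spec!r}")

        return LineageTree(build(spec), rooted=rooted)

    def copy(self) -> "LineageTree":
        return LineageTree(self.root.copy(), self.rooted, self.unsampled_mass)

    # -- basic traversal -----------------------------------------------------

    def nodes(self) -> Iterator[_Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def edges(self) -> Iterator[_Node]:
        """Each edge is identified with its child node (anchor has no edge)."""
        for n in self.nodes():
            if n is not self.root:
                yield n

    def leaves(self) -> Iterator[_Node]:
        for n in self.nodes():
            if n.is_leaf():
                yield n

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def has_probabilities(self) -> bool:
        return all(e.prob is not None for e in self.edges())

    # -- validation ----------------------------------------------------------

    def validate(self, require_probabilities: bool = False) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        if any(lbl is None for lbl in labels):
            raise ValueError("every leaf must carry a label")
        for n in self.nodes():
            deg = len(n.children) + (0 if n is self.root else 1)
            if deg == 2 and n is not self.root:
                raise ValueError("internal vertex of degree 2 (must be suppressed)")
            if not n.is_leaf() and n.label is not None:
                raise ValueError("internal vertices must be unlabelled")
            if n.fake and (not n.is_leaf() or n is self.root):
                raise ValueError("fake edges must be terminal")
        if not self.rooted and len(self.root.children) < 3 and self.n_leaves > 2:
            raise ValueError("unrooted anchor must have degree >= 3")
        if require_probabilities or self.has_probabilities():
            probs = [e.prob for e in self.edges()]
            if any(p is None for p in probs):
                if require_probabilities:
                    raise ValueError("edge probabilities are required but missing")
                return
            total = sum(probs) + self.unsampled_mass
            if abs(float(total) - 1.0) > PROB_SUM_TOL:
                raise ValueError(f"edge probabilities sum to {float(total)}, not 1")
            for e in self.edges():
                if float(e.prob) < 0:
                    raise ValueError("negative edge probability")
                if e.fake and float(e.prob) != 0.0:
                    raise ValueError("fake edges must have probability 0")
                if not e.is_leaf() and float(e.prob) <= 0.0:
                    raise ValueError("internal edges must have probability > 0")

    # -- Newick I/O ----------------------------------------------------------

    def to_newick(self, include_probabilities: Optional[bool] = None) -> str:
        if include_probabilities is None:
            include_probabilities = self.has_probabilities()

        def fmt(p):
            if isinstance(p, Fraction):
                return repr(float(p))
            return repr(float(p))

        def render(n: _Node) -> str:
            if n.is_leaf():
                s = n.label
            else:
                s = "(" + ",".join(render(c) for c in n.children) + ")"
            if include_probabilities and n.prob is not None:
                s += ":" + fmt(n.prob)
            return s

        return render(self.root) + ";"

    def canonical_newick(self) -> str:
        """Deterministic topology-only string used for tie-breaking.

        Unrooted trees are first re-anchored at the neighbour of the
        lexicographically smallest leaf so the form is rotation-invariant.
        """
        tree = self
        if not self.rooted:
            tree = self._reanchored_at_min_leaf()

        def render(n: _Node) -> str:
            if n.is_leaf():
                return n.label
            return "(" + ",".join(sorted(render(c) for c in n.children)) + ")"

        return render(tree.root) + ";"

    def _reanchored_at_min_leaf(self) -> "LineageTree":
        adj = self._adjacency()
        min_leaf = min(self.leaf_labels())
        leaf_node = next(n for n in self.nodes() if n.label == min_leaf)
        (hub, _, _), = adj[id(leaf_node)][:1] or [(None, None, None)]
        if hub is None:  # two-leaf tree
            return self.copy()
        return LineageTree(_rebuild_rooted(hub, None, adj), rooted=False,
                           unsampled_mass=self.unsampled_mass)

    def _adjacency(self):
        adj: dict = {}
        for n in self.nodes():
            adj.setdefault(id(n), [])
        # map ids back to nodes for traversal
        for n in self.nodes():
            for c in n.children:
                adj[id(n)].append((c, c.prob, c.fake))
                adj[id(c)].append((n, c.prob, c.fake))
        return adj

    # -- rooting operations --------------------------------------------------

    def unroot(self) -> "LineageTree":
        """Return the unrooted version; a degree-2 root is suppressed and its
        two incident edge probabilities are added."""
        if not self.rooted:
            return self.copy()
        t = self.copy()
        root = t.root
        if len(root.children) == 2:
            a, b = root.children
            keep, merge = (a, b) if not a.is_leaf() else (b, a)
            if keep.is_leaf():
                # two-leaf tree: nothing to suppress meaningfully
                return LineageTree(root, rooted=False, unsampled_mass=t.unsampled_mass)
            if merge.prob is not None and keep.prob is not None:
                merge.prob = merge.prob + keep.prob
            keep.children.append(merge)
            keep.prob = None
            keep.fake = False
            return LineageTree(keep, rooted=False, unsampled_mass=t.unsampled_mass)
        return LineageTree(root, rooted=False, unsampled_mass=t.unsampled_mass)

    def rooted_at_leaf(self, label: str) -> "LineageTree":
        """Root the tree on the terminal edge of the given leaf (e.g. the
        healthy cell): the leaf becomes one of two children of a new root."""
        adj = self._adjacency()
        leaf_node = next((n for n in self.nodes() if n.label == label), None)
        if leaf_node is None:
            raise KeyError(f"no leaf labelled {label!r}")
        hub = adj[id(leaf_node)][0][0]
        prob = leaf_node.prob if leaf_node is not self.root else adj[id(leaf_node)][0][1]
        new_root = _Node()
        leaf_copy = _Node(label, prob=None if prob is None else prob * 0, fake=leaf_node.fake)
        sub = _rebuild_rooted(hub, leaf_node, adj)
        sub.prob = prob
        new_root.children = [leaf_copy, sub]
        out = LineageTree(new_root, rooted=True, unsampled_mass=self.unsampled_mass)
        return out

    # -- restriction ---------------------------------------------------------

    def restrict(self, labels: Iterable[str]) -> "LineageTree":
        """Restrict to a label subset.

        Deleted degree-2 vertices merge their incident edges with
        probabilities added.  For a rooted tree the result stays rooted: the
        probability mass of all edges ancestral to the MRCA of the kept
        leaves becomes a root-stem edge (a mutation there produces the
        all-ones pattern), and mass on edges with no kept descendant is
        added to ``unsampled_mass`` (the all-zero pattern).
        """
        S = frozenset(labels)
        missing = S - self.leaf_labels()
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if not S:
            raise ValueError("restriction subset must be non-empty")

        has_probs = self.has_probabilities()
        dropped = [self.unsampled_mass if has_probs else None]

        def prune(node: _Node):
            if node.is_leaf():
                if node.label in S:
                    return _Node(node.label, node.prob, node.fake)
                if has_probs:
                    dropped[0] = dropped[0] + node.prob
                return None
            kept = []
            for c in node.children:
                r = prune(c)
                if r is not None:
                    kept.append(r)
            if not kept:
                if has_probs and node.prob is not None:
                    dropped[0] = dropped[0] + node.prob
                return None
            if len(kept) == 1:
                child = kept[0]
                # suppress this degree-2 vertex: merge the two edges
                if node.prob is not None and child.prob is not None:
                    child.prob = child.prob + node.prob
                elif node.prob is not None and child.prob is None:
                    child.prob = node.prob
                if child.fake and child.prob is not None and float(child.prob) != 0.0:
                    child.fake = False  # a real edge was merged into it
                return child
            n = _Node(prob=node.prob, fake=False)
            n.children = kept
            return n

        top = prune(self.root)
        assert top is not None

        if self.rooted:
            if top.prob is not None:
                # ancestral mass survives as a root-stem edge
                new_root = _Node()
                new_root.children = [top]
                result = LineageTree(new_root, rooted=True,
                                     unsampled_mass=dropped[0] if has_probs else 0)
            else:
                result = LineageTree(top, rooted=True,
                                     unsampled_mass=dropped[0] if has_probs else 0)
        else:
            top.prob = None
            top.fake = False
            if not top.is_leaf() and len(top.children) == 2:
                # re-anchor: suppress a degree-2 anchor
                a, b = top.children
                keep, merge = (a, b) if not a.is_leaf() else (b, a)
                if not keep.is_leaf():
                    if merge.prob is not None and keep.prob is not None:
                        merge.prob = merge.prob + keep.prob
                    keep.children.append(merge)
                    keep.prob = None
                    top = keep
            result = LineageTree(top, rooted=False,
                                 unsampled_mass=dropped[0] if has_probs else 0)
        return result

    # -- encodings and bipartitions -------------------------------------------

    def bipartition_set(self) -> set:
        """One bipartition per edge of the unrooted view of the tree."""
        t = self.unroot() if self.rooted else self
        all_labels = t.leaf_labels()
        if len(all_labels) < 2:
            return set()
        out = set()

        def walk(node: _Node) -> frozenset:
            if node.is_leaf():
                side = frozenset([node.label])
            else:
                side = frozenset().union(*(walk(c) for c in node.children))
            if node is not t.root and side != all_labels:
                out.add(Bipartition.of(side, all_labels - side))
            return side

        walk(t.root)
        return out

    def internal_bipartitions(self) -> set:
        return {b for b in self.bipartition_set() if b.is_internal}

    def quartet_encoding(self) -> set:
        """All quartets displayed by the unrooted tree: for each internal
        bipartition, every pair from one side against every pair from the
        other.  Four-subsets whose restriction is a star contribute nothing."""
        if self.n_leaves < 4:
            raise ValueError("quartet encoding needs at least 4 leaves")
        out = {}
        for bip in self.internal_bipartitions():
            for pa in itertools.combinations(sorted(bip.side1), 2):
                for pb in itertools.combinations(sorted(bip.side2), 2):
                    q = Quartet.of(pa, pb)
                    out[frozenset(q.labels)] = q
        return set(out.values())

    def displayed_quartet(self, subset: Iterable[str]):
        """The quartet displayed on a 4-subset, or None for a star."""
        S = frozenset(subset)
        t = self.unroot() if self.rooted else self
        for bip in t.bipartition_set():
            inter = S & bip.side1
            if len(inter) == 2 and len(S & bip.side2) == 2:
                return Quartet.of(inter, S - inter)
        return None

    def clades(self) -> set:
        """All proper clades (leaf sets below a non-root vertex) of a rooted tree."""
        if not self.rooted:
            raise ValueError("clades are defined for rooted trees only")
        out = set()

        def below(node: _Node) -> frozenset:
            if node.is_leaf():
                cl = frozenset([node.label])
            else:
                cl = frozenset().union(*(below(c) for c in node.children))
            if node is not self.root:
                out.add(cl)
            return cl

        below(self.root)
        return out

    def triplet_encoding(self) -> set:
        """All triplets displayed by the rooted tree."""
        if not self.rooted:
            raise ValueError("triplet encoding requires a rooted tree")
        if self.n_leaves < 3:
            raise ValueError("triplet encoding needs at least 3 leaves")
        all_labels = self.leaf_labels()
        out = set()
        for clade in self.clades():
            if len(clade) < 2 or clade == all_labels:
                continue
            for pair in itertools.combinations(sorted(clade), 2):
                for og in all_labels - clade:
                    out.add(Triplet.of(og, pair))
        return out

    def displayed_triplet(self, subset: Iterable[str]):
        """The triplet displayed on a 3-subset of a rooted tree, or None."""
        S = frozenset(subset)
        if not self.rooted:
            raise ValueError("triplets require a rooted tree")
        best = None
        for clade in self.clades():
            inter = S & clade
            if len(inter) == 2 and len(S - clade) == 1:
                best = Triplet.of(next(iter(S - inter)), inter)
        return best

    # -- comparisons -----------------------------------------------------------

    def is_refinement_of(self, other: "LineageTree") -> bool:
        """True iff every internal bipartition of ``other`` is one of ours."""
        if self.leaf_labels() != other.leaf_labels():
            raise ValueError("refinement comparison needs identical label sets")
        return other.internal_bipartitions() <= self.internal_bipartitions()


def parse_newick(text: str, require_probabilities: bool = False) -> LineageTree:
    """Parse a Newick string into a :class:`LineageTree`.

    Edge probabilities ride in the branch-length slot; a terminal edge with
    probability exactly 0 is interpreted as fake.  When
    ``require_probabilities`` is set, the probabilities must be present on
    every edge and sum to 1 (tolerance 1e-9).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except ValueError:
        raise
    except Exception as exc:  # dendropy parse errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    rooted = True  # rootedness is a modelling choice; use unroot() when needed

    def convert(dnode) -> _Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        prob = dnode.edge.length
        n = _Node(label=label if not dnode.child_nodes() else None, prob=prob)
        n.children = [convert(c) for c in dnode.child_nodes()]
        if n.is_leaf() and prob is not None and float(prob) == 0.0:
            n.fake = True
        return n

    root = convert(dtree.seed_node)
    root.prob = None
    tree = LineageTree(root, rooted=rooted)
    tree.validate(require_probabilities=require_probabilities)
    return tree


def tree_error(reference: LineageTree, estimate: LineageTree) -> TreeErrorReport:
    """False-negative / false-positive branch counts between two trees
    (unrooted comparison of internal bipartitions)."""
    if reference.leaf_labels() != estimate.leaf_labels():
        raise ValueError("tree error needs identical label sets")
    ref = reference.internal_bipartitions()
    est = estimate.internal_bipartitions()
    return TreeErrorReport(
        false_negative_branches=len(ref - est),
        false_positive_branches=len(est - ref),
    )


def _rebuild_rooted(node: _Node, parent: Optional[_Node], adj) -> _Node:
    """Rebuild the tree as rooted at ``node``, excluding the ``parent`` arm."""
    n = _Node(node.label if node.is_leaf() else None)
    for nbr, prob, fake in adj[id(node)]:
        if parent is not None and nbr is parent:
            continue
        child = _rebuild_rooted(nbr, node, adj)
        child.prob = prob
        child.fake = fake if child.is_leaf() else False
        n.children.append(child)
    if not n.children and node.label is None:
        raise ValueError("re-anchoring produced an unlabelled leaf")
    return n


# ---------------------------------------------------------------------------
# exhaustive topology enumeration
# ---------------------------------------------------------------------------


def enumerate_unrooted_binary(labels: Sequence[str], cap: int = DEFAULT_ENUM_CAP) -> Iterator[LineageTree]:
    """All (2n-5)!! unrooted binary topologies on the labels, each once, in a
    deterministic order (leaf-insertion order on sorted labels)."""
    lab = sorted(set(labels))
    n = len(lab)
    if n < 4:
        raise ValueError("need at least 4 labels")
    if n > cap:
        raise ValueError(f"{n} labels exceeds the enumeration cap ({cap})")

    def seed() -> _Node:
        anchor = _Node()
        anchor.children = [_Node(lab[0]), _Node(lab[1]), _Node(lab[2])]
        return anchor

    def insert_on_each_edge(root: _Node, label: str) -> Iterator[_Node]:
        # edges are indexed in a fixed traversal order; for each, produce a
        # copy with the new leaf attached in the middle of that edge
        def count_edges(node):
            return sum(1 + count_edges(c) for c in node.children)

        total = count_edges(root)
        for idx in range(total):
            new_root = root.copy()
            counter = [0]

            def attach(node):
                for i, c in enumerate(node.children):
                    if counter[0] == idx:
                        mid = _Node()
                        mid.children = [c, _Node(label)]
                        node.children[i] = mid
                        counter[0] += 1
                        return True
                    counter[0] += 1
                    if attach(c):
                        return True
                return False

            attach(new_root)
            yield new_root

    partial = [seed()]
    for label in lab[3:]:
        partial = [t for p in partial for t in insert_on_each_edge(p, label)]
    for root in partial:
        yield LineageTree(root, rooted=False)


def enumerate_rooted_binary(labels: Sequence[str], cap: int = DEFAULT_ENUM_CAP) -> Iterator[LineageTree]:
    """All (2n-3)!! rooted binary topologies, via unrooted enumeration on the
    labels plus a root sentinel."""
    lab = sorted(set(labels))
    if len(lab) < 2:
        raise ValueError("need at least 2 labels")
    if len(lab) > cap:
        raise ValueError(f"{len(lab)} labels exceeds the enumeration cap ({cap})")
    sentinel = "\x00ROOT"
    if len(lab) == 2:
        r = _Node()
        r.children = [_Node(lab[0]), _Node(lab[1])]
        yield LineageTree(r, rooted=True)
        return
    for unrooted in enumerate_unrooted_binary(lab + [sentinel], cap=cap + 1):
        adj = unrooted._adjacency()
        sent = next(n for n in unrooted.nodes() if n.label == sentinel)
        hub = adj[id(sent)][0][0]
        root = _rebuild_rooted(hub, sent, adj)
        yield LineageTree(root, rooted=True)
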