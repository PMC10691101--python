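"""Seedable simulation of mutation matrices under IS+UEM, and construction
of the lineage-tree fixtures the analytic results are illustrated on.

Generation is hierarchical.  First, for each of k i.i.d. mutations an edge
of the rooted lineage tree is drawn with probability p(e) and every cell
below it is set to 1, producing the ground-truth matrix G (a perfect
phylogeny).  Second, each entry passes independently through the unbiased
channel: 0->1 with probability alpha, 1->0 with beta, and masking to '?'
with gamma, producing the observed matrix D.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .matrix import MISSING_CODE, MutationMatrix
from .model import ErrorModel
from .tree import LineageTree, _Node

__all__ = [
    "SimConfig",
    "simulate",
    "build_shape_tree",
    "build_augmented_lineage_fixture",
    "random_lineage_tree",
    "assign_uniform_probabilities",
    "assign_random_probabilities",
    "FOUR_LEAF_SHAPES",
]

# the five rooted shapes on four leaves (a,b,c,d); the first three unroot to
# the quartet ab|cd, the last two to a star
FOUR_LEAF_SHAPES = ("balanced", "caterpillar", "cherry_star", "triple_star", "star")


@dataclass
class SimConfig:
    """Parameters of one simulation run."""

    sigma: LineageTree
    em: ErrorModel
    k: int
    seed: Optional[int] = None
    emit_ground_truth: bool = False
    drop_fake_leaves: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def simulate(cfg: SimConfig):
    """Simulate an observed mutation matrix D (and optionally the ground
    truth G) under IS+UEM.

    The pseudo-random stream is consumed in a fixed order (the k edge draws,
    then the error draws, then the missingness draws) so the same seed gives
    identical output.  Fake leaves receive observed states through the same
    channel as real leaves — their ground truth is the state at their
    attachment point — and can be excluded via ``drop_fake_leaves``.
    """
    sigma = cfg.sigma
    if not sigma.rooted:
        raise ValueError("simulation requires a rooted tree")
    if not sigma.has_probabilities():
        raise ValueError("tree has no edge probabilities")
    rng = np.random.default_rng(cfg.seed)

    cells = sorted(sigma.leaf_labels())
    index = {l: i for i, l in enumerate(cells)}
    n = len(cells)

    # per-edge descendant masks, in a fixed traversal order
    masks = []
    probs = []

    def walk(node) -> np.ndarray:
        if node.is_leaf():
            mask = np.zeros(n, dtype=bool)
            mask[index[node.label]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for c in node.children:
                mask |= walk(c)
        if node is not sigma.root:
            masks.append(mask)
            probs.append(float(node.prob))
        return mask

    walk(sigma.root)
    p = np.asarray(probs, dtype=float)
    extra = float(sigma.unsampled_mass)
    if extra > 0:
        masks.append(np.zeros(n, dtype=bool))
        p = np.append(p, extra)
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"edge probabilities sum to {total}, not 1")
    p = p / total

    edge_idx = rng.choice(len(p), size=cfg.k, p=p)
    G = np.stack([masks[e] for e in edge_idx], axis=1).astype(np.int8)

    a, b, g = float(cfg.em.alpha), float(cfg.em.beta), float(cfg.em.gamma)
    flip = rng.random((n, cfg.k))
    miss = rng.random((n, cfg.k))
    D = G.copy()
    D[(G == 0) & (flip < a)] = 1
    D[(G == 1) & (flip < b)] = 0
    D[miss < g] = MISSING_CODE

    keep = list(range(n))
    if cfg.drop_fake_leaves:
        fake = {leaf.label for leaf in sigma.leaves() if leaf.fake}
        keep = [i for i, c in enumerate(cells) if c not in fake]
    cells_out = [cells[i] for i in keep]
    ids = [f"m{j}" for j in range(cfg.k)]
    D_mat = MutationMatrix(D[keep], cells_out, ids)
    if cfg.emit_ground_truth:
        return D_mat, MutationMatrix(G[keep], cells_out, ids)
    return D_mat


# ---------------------------------------------------------------------------
# fixture trees
# ---------------------------------------------------------------------------


def assign_uniform_probabilities(tree: LineageTree) -> LineageTree:
    """Equal exact probability on every non-fake edge; fake edges get 0."""
    t = tree.copy()
    real = [e for e in t.edges() if not e.fake]
    p = Fraction(1, len(real))
    for e in t.edges():
        e.prob = Fraction(0) if e.fake else p
    return t


def assign_random_probabilities(tree: LineageTree, rng, denominator: int = 10**6) -> LineageTree:
    """Random exact edge probabilities: a symmetric Dirichlet draw rounded
    onto a common denominator and renormalised, so downstream arithmetic can
    stay rational.  Fake edges keep probability 0."""
    t = tree.copy()
    real = [e for e in t.edges() if not e.fake]
    weights = rng.dirichlet(np.ones(len(real)))
    ints = np.maximum(1, np.round(weights * denominator).astype(int))
    total = int(ints.sum())
    for e, w in zip(real, ints):
        e.prob = Fraction(int(w), total)
    for e in t.edges():
        if e.fake:
            e.prob = Fraction(0)
    return t


def build_shape_tree(shape: str, labels: Sequence[str],
                     probabilities: str = "uniform") -> LineageTree:
    """One of the five rooted tree shapes on four leaves.

    balanced      ((a,b),(c,d))
    caterpillar   (((a,b),c),d)
    cherry_star   ((a,b),c,d)      trifurcating root
    triple_star   ((a,b,c),d)
    star          (a,b,c,d)

    The first three unroot to the quartet a,b|c,d; the last two to a star.
    """
    if len(labels) != 4:
        raise ValueError("shape trees need exactly 4 labels")
    a, b, c, d = labels
    shapes = {
        "balanced": [[a, b], [c, d]],
        "caterpillar": [[[a, b], c], d],
        "cherry_star": [[a, b], c, d],
        "triple_star": [[a, b, c], d],
        "star": [a, b, c, d],
    }
    if shape not in shapes:
        raise ValueError(f"unknown shape {shape!r}; choose from {FOUR_LEAF_SHAPES}")
    tree = LineageTree.from_nested(shapes[shape], rooted=True)
    if probabilities == "uniform":
        tree = assign_uniform_probabilities(tree)
    elif probabilities is not None:
        raise ValueError("probabilities must be 'uniform' or None")
    return tree


def build_triplet_shape_tree(binary: bool, labels: Sequence[str],
                             probabilities: str = "uniform") -> LineageTree:
    """The two rooted shapes on three leaves: ((a,b),c) or the star (a,b,c)."""
    if len(labels) != 3:
        raise ValueError("triplet shape trees need exactly 3 labels")
    a, b, c = labels
    spec = [[a, b], c] if binary else [a, b, c]
    tree = LineageTree.from_nested(spec, rooted=True)
    if probabilities == "uniform":
        tree = assign_uniform_probabilities(tree)
    return tree


def build_augmented_lineage_fixture(m: int = 1000) -> LineageTree:
    """The worked anomalous-triplet fixture: a lineage tree containing cells
    1, 4 and 10 in which a long chain of m+9 mutation-bearing edges leads to
    cell 10.

    With equal probability on every non-fake edge, restricting to {1, 4, 10}
    yields a rooted triplet 10|1,4 with edge probabilities (denominator
    m+12): stem 1, cherry{1,4} 1, terminal-4 1, terminal-1 0 (fake), and
    terminal-10 m+9.  Side cells along the chain attach by fake edges so
    they do not perturb the restricted distribution.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    root = _Node()
    healthy = _Node("healthy", fake=True)
    v = _Node()  # ancestor of the sampled clade; root->v is the stem edge
    root.children = [healthy, v]

    cherry = _Node()
    cherry.children = [_Node("1", fake=True), _Node("4")]

    chain_len = m + 9
    top = _Node("10")
    for i in range(chain_len - 1, 0, -1):
        node = _Node()
        node.children = [_Node(f"s{i}", fake=True), top]
        top = node
    v.children = [cherry, top]

    tree = LineageTree(root, rooted=True)
    tree = assign_uniform_probabilities(tree)
    tree.validate(require_probabilities=True)
    return tree


def random_lineage_tree(n: int, resolution: float = 1.0, seed=None,
                        rng=None) -> LineageTree:
    """A random rooted lineage tree on n cells.

    A random binary topology is grown by sequential leaf attachment; then a
    (1 - resolution) fraction of its internal edges is contracted, and the
    remaining edges receive symmetric-Dirichlet probabilities (rounded to
    exact rationals and renormalised).
    """
    if n < 3:
        raise ValueError("need at least 3 leaves")
    if not (0 <= resolution <= 1):
        raise ValueError("resolution must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = [f"c{i+1}" for i in range(n)]

    root = _Node()
    root.children = [_Node(labels[0]), _Node(labels[1])]
    for label in labels[2:]:
        # pick a uniformly random edge (child node) and bisect it
        edges = []

        def collect(node):
            for ch in node.children:
                edges.append((node, ch))
                collect(ch)

        collect(root)
        parent, child = edges[rng.integers(len(edges))]
        mid = _Node()
        mid.children = [child, _Node(label)]
        parent.children[parent.children.index(child)] = mid

    tree = LineageTree(root, rooted=True)

    # contract a fraction of internal edges
    internal = [nd for nd in tree.nodes()
                if nd is not tree.root and not nd.is_leaf()]
    n_contract = int(round((1 - resolution) * len(internal)))
    if n_contract:
        order = rng.permutation(len(internal))
        chosen = {id(internal[i]) for i in order[:n_contract]}

        def contract(node):
            new_children = []
            for ch in node.children:
                contract(ch)
                if id(ch) in chosen:
                    new_children.extend(ch.children)
                else:
                    new_children.append(ch)
            node.children = new_children

        contract(tree.root)

    tree = assign_random_probabilities(tree, rng)
    tree.validate(require_probabilities=True)
    return tree
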