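"""Maximum Quartet/Triplet Support Supertree (MQSS / MTSS) solvers.

MQSS: given mutations viewed as unrooted split-trees, find the unrooted
binary tree maximizing the total weight of displayed quartets.  An optimal
solution is a consistent estimator of the (possibly highly unresolved)
unrooted lineage tree, with error counted as false negative branches.
MTSS is the rooted, triplet analogue; its guarantee needs alpha = 0, and
the anomalous-triplet construction shows it can fail when alpha > 0.

Three search modes are provided:

* ``exhaustive`` — score all (2n-5)!! topologies (small n);
* ``constrained`` — exact clade dynamic programming over a bipartition
  constraint space harvested from the mutations themselves (the ASTRAL-style
  search-space restriction);
* ``nni`` — seeded nearest-neighbour-interchange hill climbing.

The user-facing surface is a pair of scikit-learn style estimators,
:class:`QuartetSupertree` and :class:`TripletSupertree`; the module-level
functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import MISSING_CODE, MutationMatrix
from .model import ErrorModel
from .simulate import SimConfig, simulate
from .support import (
    QuartetWeightTable,
    TripletWeightTable,
    column_to_split,
    quartet_support,
    quartet_weights,
    triplet_support,
    triplet_weights,
)
from .tree import (
    Bipartition,
    LineageTree,
    Quartet,
    _Node,
    enumerate_rooted_binary,
    enumerate_unrooted_binary,
    tree_error,
)

__all__ = [
    "SolverResult",
    "ConstraintSpace",
    "QuartetSupertree",
    "TripletSupertree",
    "mqss_exhaustive",
    "mqss_constrained",
    "mqss_nni",
    "mtss_exhaustive",
    "build_constraint_space",
    "consistency_experiment",
]

DEFAULT_CAP = 8


@dataclass
class SolverResult:
    """A solver's output: the optimal tree found, its support score, and
    bookkeeping (search mode, trees evaluated, co-optimum count, seed)."""

    tree: LineageTree
    score: int
    mode: str
    evaluations: int
    ties: int = 1
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------


def _best_of(trees: Iterable[LineageTree], score_fn) -> SolverResult:
    best = None
    best_score = None
    best_canon = None
    ties = 0
    count = 0
    for tree in trees:
        count += 1
        s = score_fn(tree)
        if best_score is None or s > best_score:
            best, best_score, best_canon, ties = tree, s, tree.canonical_newick(), 1
        elif s == best_score:
            ties += 1
            canon = tree.canonical_newick()
            if canon < best_canon:
                best, best_canon = tree, canon
    return SolverResult(best, best_score, "exhaustive", count, ties)


def mqss_exhaustive(D: MutationMatrix, cap: int = DEFAULT_CAP) -> SolverResult:
    """Globally optimal MQSS over all unrooted binary topologies.

    Tie-break: the lexicographically smallest canonical Newick string among
    co-optima; the co-optimum count is reported in ``ties``.
    """
    table = quartet_weights(D)
    trees = enumerate_unrooted_binary(D.cell_labels, cap=cap)
    return _best_of(trees, lambda t: quartet_support(table, t))


def mtss_exhaustive(D: MutationMatrix, cap: int = DEFAULT_CAP) -> SolverResult:
    """Globally optimal MTSS over all rooted binary topologies."""
    table = triplet_weights(D)
    trees = enumerate_rooted_binary(D.cell_labels, cap=cap)
    return _best_of(trees, lambda t: triplet_support(table, t))


# ---------------------------------------------------------------------------
# constrained search (clade dynamic programming)
# ---------------------------------------------------------------------------


@dataclass
class ConstraintSpace:
    """A set of bipartitions of the full cell set within which the
    constrained solver searches.  Contains all trivial bipartitions and is
    closed under complement by construction (a Bipartition stores both
    sides)."""

    labels: frozenset
    bipartitions: set = field(default_factory=set)

    def add(self, bip: Bipartition) -> None:
        if bip.labels != self.labels:
            raise ValueError("bipartition does not span the full cell set")
        self.bipartitions.add(bip)

    def clades(self, ref: str) -> set:
        """Clades after rooting at leaf ``ref``: for each bipartition, the
        side not containing ``ref``, plus all singletons and the full
        complement of ``ref``."""
        rest = self.labels - {ref}
        out = {frozenset([x]) for x in rest}
        out.add(frozenset(rest))
        for bip in self.bipartitions:
            side = bip.side2 if ref in bip.side1 else bip.side1
            out.add(frozenset(side))
        return out


def build_constraint_space(
    D: MutationMatrix,
    missing_policy: str = "zero",
    extra_trees: Optional[Sequence[LineageTree]] = None,
) -> ConstraintSpace:
    """Harvest a bipartition constraint space from the mutations.

    Each informative split is completed to a bipartition of the full cell
    set; under the default ``missing_policy='zero'`` missing cells join the
    0-side (the ancestral-majority reading), under ``'drop'`` any column
    with missing entries is skipped.  Trivial bipartitions are always
    included, and bipartitions of optional starting trees may be added.
    """
    if missing_policy not in ("zero", "drop"):
        raise ValueError("missing_policy must be 'zero' or 'drop'")
    labels = frozenset(D.cell_labels)
    space = ConstraintSpace(labels)
    for x in labels:
        if len(labels) > 2:
            space.add(Bipartition.of([x], labels - {x}))
    for j in range(D.n_mutations):
        split = column_to_split(D, j)
        missing = labels - split.one_side - split.zero_side
        if missing and missing_policy == "drop":
            continue
        ones = split.one_side
        zeros = split.zero_side | missing
        if ones and zeros:
            space.add(Bipartition.of(ones, zeros))
    if extra_trees:
        for t in extra_trees:
            if t.leaf_labels() != labels:
                raise ValueError("starting tree is not on the full cell set")
            for bip in t.bipartition_set():
                space.add(bip)
    return space


def mqss_constrained(D: MutationMatrix, space: Optional[ConstraintSpace] = None,
                     missing_policy: str = "zero") -> SolverResult:
    """Optimal MQSS among binary trees all of whose bipartitions lie in the
    constraint space, by dynamic programming over clades.

    Rooting the candidate tree at the smallest-label leaf L, every displayed
    quartet ab|cd is counted exactly once as (number of pair-merges {c,d}
    with {a,b} outside the merged clade) minus (pairs-within-one-child times
    pairs-within-the-other), both of which are local to a clade join, so the
    objective decomposes over the clade tree and the DP is exact.
    """
    if space is None:
        space = build_constraint_space(D, missing_policy=missing_policy)
    table = quartet_weights(D)
    labels = sorted(space.labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 cells")
    ref = labels[0]
    clades = space.clades(ref)
    universe = frozenset(labels)

    def w(pair_in, pair_out) -> int:
        return table.weight(Quartet.of(pair_in, pair_out))

    def contrib(c1: frozenset, c2: frozenset) -> int:
        outside = universe - c1 - c2
        out_pairs = list(itertools.combinations(sorted(outside), 2))
        total = 0
        for cd in itertools.product(sorted(c1), sorted(c2)):
            for ab in out_pairs:
                total += w(cd, ab)
        for ab in itertools.combinations(sorted(c1), 2):
            for cd in itertools.combinations(sorted(c2), 2):
                total -= w(ab, cd)
        return total

    order = sorted(clades, key=lambda c: (len(c), tuple(sorted(c))))
    best: dict = {}
    evaluations = 0
    for clade in order:
        if len(clade) == 1:
            best[clade] = (0, None, 1, min(clade))
            continue
        anchor = min(clade)
        best_entry = None
        for c1 in order:
            if len(c1) >= len(clade) or anchor not in c1 or not c1 < clade:
                continue
            c2 = clade - c1
            if c2 not in best or c1 not in best:
                continue
            evaluations += 1
            s = best[c1][0] + best[c2][0] + contrib(c1, c2)
            canon = "(" + ",".join(sorted([best[c1][3], best[c2][3]])) + ")"
            prod = best[c1][2] * best[c2][2]
            if best_entry is None or s > best_entry[0]:
                best_entry = (s, (c1, c2), prod, canon)
            elif s == best_entry[0]:
                ties = best_entry[2] + prod
                if canon < best_entry[3]:
                    best_entry = (s, (c1, c2), ties, canon)
                else:
                    best_entry = (best_entry[0], best_entry[1], ties, best_entry[3])
        if best_entry is not None:
            best[clade] = best_entry

    full = frozenset(labels) - {ref}
    if full not in best:
        raise ValueError("constraint space admits no binary tree on the full cell set")

    def build(clade: frozenset) -> _Node:
        if len(clade) == 1:
            return _Node(next(iter(clade)))
        _, (c1, c2), _, _ = best[clade]
        n = _Node()
        n.children = [build(c1), build(c2)]
        return n

    top = build(full)
    anchor_node = _Node()
    anchor_node.children = [_Node(ref)] + top.children
    tree = LineageTree(anchor_node, rooted=False)
    score = quartet_support(table, tree)
    assert score == best[full][0], "DP score must match direct recomputation"
    return SolverResult(tree, score, "constrained", evaluations, best[full][2])


# ---------------------------------------------------------------------------
# NNI hill climbing
# ---------------------------------------------------------------------------


def _nni_neighbors(tree: LineageTree):
    """All nearest-neighbour-interchange neighbours of an unrooted binary
    tree (anchored representation): for each internal edge (u, v), exchange
    one u-side subtree with each child of v."""
    ops = []

    def walk(node, path):
        for i, child in enumerate(node.children):
            if not child.is_leaf():
                for j in range(len(child.children)):
                    ops.append((path, i, j))
            walk(child, path + (i,))

    walk(tree.root, ())
    for path, i, j in ops:
        t = tree.copy()
        u = t.root
        for idx in path:
            u = u.children[idx]
        v = u.children[i]
        # deterministic sibling choice: the first other arm of u
        sib_idx = next(s for s in range(len(u.children)) if s != i)
        u.children[sib_idx], v.children[j] = v.children[j], u.children[sib_idx]
        yield t


def mqss_nni(D: MutationMatrix, start: LineageTree, max_rounds: int = 100,
             seed: Optional[int] = None) -> SolverResult:
    """Hill climbing over NNI moves from a starting binary tree.  The score
    never decreases; terminates at a local optimum or the round cap.  Move
    evaluation order is seeded, which breaks ties among equally good
    neighbours deterministically."""
    table = quartet_weights(D)
    rng = np.random.default_rng(seed)
    current = start.unroot() if start.rooted else start.copy()
    current_score = quartet_support(table, current)
    evaluations = 1
    for _ in range(max_rounds):
        neighbors = list(_nni_neighbors(current))
        order = rng.permutation(len(neighbors))
        best_n, best_s = None, current_score
        for idx in order:
            cand = neighbors[idx]
            s = quartet_support(table, cand)
            evaluations += 1
            if s > best_s:
                best_n, best_s = cand, s
        if best_n is None:
            break
        current, current_score = best_n, best_s
    return SolverResult(current, current_score, "nni", evaluations, 1, seed)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------


def _coerce_matrix(X, cell_labels=None) -> MutationMatrix:
    if isinstance(X, MutationMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        data = X.replace("?", MISSING_CODE).astype(float).to_numpy()
        return MutationMatrix(data.astype(np.int8),
                              [str(i) for i in X.index],
                              [str(c) for c in X.columns])
    arr = np.asarray(X)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.where(np.isnan(arr), MISSING_CODE, arr)
    arr = arr.astype(np.int8)
    labels = cell_labels or [f"c{i}" for i in range(arr.shape[0])]
    return MutationMatrix(arr, labels)


class QuartetSupertree(BaseEstimator):
    """Estimate an unrooted cell lineage tree by maximum quartet support.

    Parameters
    ----------
    method : {"auto", "exhaustive", "constrained", "nni"}
        "auto" uses exhaustive search up to ``exhaustive_cap`` cells and the
        constrained clade DP beyond it.
    exhaustive_cap : int
        Largest cell count for exhaustive enumeration.
    missing_policy : {"zero", "drop"}
        How missing entries complete a mutation's split when building the
        constraint space.
    max_rounds : int
        NNI round cap.
    random_state : int or None
        Seed for the NNI move order.
    root_at : str or None
        If given, the fitted tree is additionally rooted on this leaf's
        terminal edge (the healthy-cell convention) as ``rooted_tree_``.

    Attributes
    ----------
    tree_ : LineageTree
        The estimated unrooted tree.
    score_ : int
        Its quartet support, re-verified against the fitted matrix.
    n_ties_, n_evaluations_, mode_ : search bookkeeping.
    """

    def __init__(self, method: str = "auto", exhaustive_cap: int = DEFAULT_CAP,
                 missing_policy: str = "zero", max_rounds: int = 100,
                 random_state: Optional[int] = None, root_at: Optional[str] = None):
        self.method = method
        self.exhaustive_cap = exhaustive_cap
        self.missing_policy = missing_policy
        self.max_rounds = max_rounds
        self.random_state = random_state
        self.root_at = root_at

    def fit(self, X, y=None, cell_labels=None):
        D = _coerce_matrix(X, cell_labels)
        if D.n_cells < 4:
            raise ValueError("quartet-based estimation needs at least 4 cells")
        method = self.method
        if method == "auto":
            method = "exhaustive" if D.n_cells <= self.exhaustive_cap else "constrained"
        if method == "exhaustive":
            result = mqss_exhaustive(D, cap=self.exhaustive_cap)
        elif method == "constrained":
            result = mqss_constrained(D, missing_policy=self.missing_policy)
        elif method == "nni":
            start = mqss_constrained(D, missing_policy=self.missing_policy).tree
            result = mqss_nni(D, start, max_rounds=self.max_rounds,
                              seed=self.random_state)
        else:
            raise ValueError(f"unknown method {method!r}")
        self.result_ = result
        self.tree_ = result.tree
        self.score_ = quartet_support(D, result.tree)
        assert self.score_ == result.score
        self.mode_ = result.mode
        self.n_evaluations_ = result.evaluations
        self.n_ties_ = result.ties
        if self.root_at is not None:
            self.rooted_tree_ = result.tree.rooted_at_leaf(self.root_at)
        return self

    def score(self, X, y=None) -> float:
        """Quartet support of the fitted tree on a (possibly new) matrix."""
        D = _coerce_matrix(X)
        return float(quartet_support(D, self.tree_))


class TripletSupertree(BaseEstimator):
    """Estimate a rooted cell lineage tree by maximum triplet support
    (exhaustive search; consistent only when the false-positive rate is 0,
    and demonstrably anomalous otherwise)."""

    def __init__(self, exhaustive_cap: int = DEFAULT_CAP):
        self.exhaustive_cap = exhaustive_cap

    def fit(self, X, y=None, cell_labels=None):
        D = _coerce_matrix(X, cell_labels)
        if D.n_cells < 3:
            raise ValueError("triplet-based estimation needs at least 3 cells")
        result = mtss_exhaustive(D, cap=self.exhaustive_cap)
        self.result_ = result
        self.tree_ = result.tree
        self.score_ = triplet_support(D, result.tree)
        assert self.score_ == result.score
        self.mode_ = result.mode
        self.n_evaluations_ = result.evaluations
        self.n_ties_ = result.ties
        return self

    def score(self, X, y=None) -> float:
        D = _coerce_matrix(X)
        return float(triplet_support(D, self.tree_))


# ---------------------------------------------------------------------------
# consistency experiments
# ---------------------------------------------------------------------------


def consistency_experiment(
    sigma: LineageTree,
    em: ErrorModel,
    k_grid: Sequence[int],
    replicates: int,
    solver: str = "exhaustive",
    mode: str = "quartet",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate-and-estimate over a grid of mutation counts.

    For each (k, replicate): simulate a matrix under IS+UEM, run the chosen
    solver, and record false-negative / false-positive branch counts against
    the model tree (unrooted comparison).  Fully seeded: identical seeds
    give identical tables.
    """
    rng = np.random.default_rng(seed)
    reference = sigma.unroot() if sigma.rooted else sigma
    rows = []
    for k in k_grid:
        for rep in range(replicates):
            rep_seed = int(rng.integers(2**31))
            D = simulate(SimConfig(sigma, em, k, seed=rep_seed))
            if mode == "quartet":
                est = QuartetSupertree(method=solver, random_state=rep_seed).fit(D)
            elif mode == "triplet":
                est = TripletSupertree().fit(D)
            else:
                raise ValueError("mode must be 'quartet' or 'triplet'")
            err = tree_error(reference, est.tree_)
            rows.append({
                "k": k,
                "replicate": rep,
                "seed": rep_seed,
                "fn": err.false_negative_branches,
                "fp": err.false_positive_branches,
                "score": est.score_,
            })
    return pd.DataFrame(rows)
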