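"""Quartet and triplet support counting from mutation matrices.

Each mutation column partitions the non-missing cells into a 1-side and a
0-side, i.e. an unrooted tree with at most one internal branch (or, read
with 0 as the ancestral state, a rooted tree with one clade).  A column
with a cells in state 1 and b in state 0 implies C(a,2)*C(b,2) quartets —
one per pair-versus-pair choice — and C(a,2)*b triplets (cherry pair from
the 1-side, outgroup from the 0-side).

The quartet support QS_D(T) of a tree T is the total number of (mutation,
4-subset) incidences in which the quartet implied by the mutation is
displayed by T; the triplet support TS_D is the rooted analogue.  These are
the objective functions of the supertree solvers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

from .matrix import MISSING_CODE, MutationMatrix
from .tree import LineageTree, Quartet, Triplet

__all__ = [
    "MutationSplit",
    "QuartetWeightTable",
    "TripletWeightTable",
    "column_to_split",
    "quartet_weights",
    "triplet_weights",
    "quartet_support",
    "triplet_support",
    "export_split_trees",
]


@dataclass(frozen=True)
class MutationSplit:
    """The bipartition of the non-missing cells induced by one mutation."""

    one_side: frozenset
    zero_side: frozenset

    @property
    def quartet_informative(self) -> bool:
        return len(self.one_side) >= 2 and len(self.zero_side) >= 2

    @property
    def triplet_informative(self) -> bool:
        return len(self.one_side) >= 2 and len(self.zero_side) >= 1


def column_to_split(D: MutationMatrix, j: int) -> MutationSplit:
    """Partition the non-missing cells of column j by observed state."""
    col = D.column(j)
    ones = frozenset(c for c, v in zip(D.cell_labels, col) if v == 1)
    zeros = frozenset(c for c, v in zip(D.cell_labels, col) if v == 0)
    return MutationSplit(ones, zeros)


class QuartetWeightTable:
    """Sparse map from a 4-subset of cells to per-topology support counts."""

    def __init__(self):
        self._table: Dict[frozenset, Dict[Quartet, int]] = {}
        self.total = 0

    def add(self, q: Quartet, weight: int = 1) -> None:
        sub = self._table.setdefault(q.labels, {})
        sub[q] = sub.get(q, 0) + weight
        self.total += weight

    def weight(self, q: Quartet) -> int:
        return self._table.get(q.labels, {}).get(q, 0)

    def subsets(self):
        return self._table.items()

    def __len__(self) -> int:
        return len(self._table)


class TripletWeightTable:
    """Sparse map from a 3-subset of cells to per-triplet support counts."""

    def __init__(self):
        self._table: Dict[frozenset, Dict[Triplet, int]] = {}
        self.total = 0

    def add(self, t: Triplet, weight: int = 1) -> None:
        sub = self._table.setdefault(t.labels, {})
        sub[t] = sub.get(t, 0) + weight
        self.total += weight

    def weight(self, t: Triplet) -> int:
        return self._table.get(t.labels, {}).get(t, 0)

    def subsets(self):
        return self._table.items()

    def __len__(self) -> int:
        return len(self._table)


def quartet_weights(D: MutationMatrix) -> QuartetWeightTable:
    """Count, for every 4-subset, how many mutations imply each quartet.

    A split with 1-side A and 0-side B contributes one unit to quartet
    aa'|bb' for every pair {a,a'} from A and {b,b'} from B.  Splits on fewer
    than four cells (after removing missing entries) are uninformative.
    """
    table = QuartetWeightTable()
    for j in range(D.n_mutations):
        split = column_to_split(D, j)
        if not split.quartet_informative:
            continue
        for pa in itertools.combinations(sorted(split.one_side), 2):
            for pb in itertools.combinations(sorted(split.zero_side), 2):
                table.add(Quartet.of(pa, pb))
    return table


def triplet_weights(D: MutationMatrix) -> TripletWeightTable:
    """Count, for every 3-subset, how many mutations imply each triplet.

    Reading 1 as the derived state, a split with 1-side A and 0-side B
    contributes one unit to triplet b|aa' for every cherry pair {a,a'} from
    A and outgroup b from B.
    """
    table = TripletWeightTable()
    for j in range(D.n_mutations):
        split = column_to_split(D, j)
        if not split.triplet_informative:
            continue
        for pair in itertools.combinations(sorted(split.one_side), 2):
            for og in sorted(split.zero_side):
                table.add(Triplet.of(og, pair))
    return table


def quartet_support(source: Union[MutationMatrix, QuartetWeightTable],
                    T: LineageTree) -> int:
    """QS_D(T): the summed weight of quartets displayed by T.

    T may be non-binary; 4-subsets on which T restricts to a star contribute
    nothing.  Only subsets with non-zero weight are visited (the table is
    sparse), which equals the brute-force sum over all 4-subsets.
    """
    table = quartet_weights(source) if isinstance(source, MutationMatrix) else source
    unrooted = T.unroot() if T.rooted else T
    labels = unrooted.leaf_labels()
    bips = [b for b in unrooted.bipartition_set() if b.is_internal]
    score = 0
    for subset, weights in table.subsets():
        if not subset <= labels:
            raise ValueError(f"cells {sorted(subset - labels)} absent from the tree")
        q = _displayed_quartet(bips, subset)
        if q is not None:
            score += weights.get(q, 0)
    return score


def _displayed_quartet(internal_bips, subset: frozenset) -> Optional[Quartet]:
    for bip in internal_bips:
        inter = subset & bip.side1
        if len(inter) == 2 and len(subset & bip.side2) == 2:
            return Quartet.of(inter, subset - inter)
    return None


def triplet_support(source: Union[MutationMatrix, TripletWeightTable],
                    T: LineageTree) -> int:
    """TS_D(T): the summed weight of triplets displayed by the rooted tree T."""
    if not T.rooted:
        raise ValueError("triplet support requires a rooted tree")
    table = triplet_weights(source) if isinstance(source, MutationMatrix) else source
    labels = T.leaf_labels()
    clades = [c for c in T.clades() if len(c) >= 2]
    score = 0
    for subset, weights in table.subsets():
        if not subset <= labels:
            raise ValueError(f"cells {sorted(subset - labels)} absent from the tree")
        t = _displayed_triplet(clades, subset)
        if t is not None:
            score += weights.get(t, 0)
    return score


def _displayed_triplet(clades, subset: frozenset) -> Optional[Triplet]:
    for clade in clades:
        inter = subset & clade
        if len(inter) == 2 and len(subset - clade) == 1:
            return Triplet.of(next(iter(subset - inter)), inter)
    return None


def export_split_trees(D: MutationMatrix, path, mode: str = "quartet") -> int:
    """Write one Newick tree per informative mutation (the split viewed as a
    tree with at most one internal branch), for use with external supertree
    tools.  In quartet mode, splits on fewer than four cells are omitted.
    Returns the number of trees written."""
    count = 0
    with open(path, "w") as fh:
        for j in range(D.n_mutations):
            split = column_to_split(D, j)
            ok = split.quartet_informative if mode == "quartet" else split.triplet_informative
            if not ok:
                continue
            ones = ",".join(sorted(split.one_side))
            zeros = ",".join(sorted(split.zero_side))
            fh.write(f"(({ones}),{zeros});\n")
            count += 1
    return count
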