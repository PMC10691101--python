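"""Exact probability calculators under the infinite-sites model with an
unbiased error-and-missingness channel (IS+UEM).

Under the IS model a mutation falls on edge *e* of the rooted lineage tree
with probability p(e); every cell below *e* carries state 1, all others 0.
The observed matrix passes each entry through an unbiased channel: a true 0
is flipped to 1 with probability alpha (false positive), a true 1 to 0 with
probability beta (false negative), and any entry is masked with probability
gamma (missingness), independently per matrix cell.

Two computation routes are provided for quartet and triplet probabilities:
a closed form and an exhaustive error-enumeration oracle; they must agree
exactly.  Exact rational arithmetic (``fractions.Fraction``) is the default
because the probability differences that drive anomaly detection can be
tiny (the worked lineage fixture operates at the 1/1012 scale).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .tree import (
    LineageTree,
    Quartet,
    Triplet,
    quartet_topologies,
    triplet_topologies,
)

__all__ = [
    "ErrorModel",
    "PatternDistribution",
    "QuartetDistribution",
    "TripletDistribution",
    "AnomalyRecord",
    "AnomalyReport",
    "is_pattern_distribution",
    "uem_channel",
    "corrupted_pattern_distribution",
    "quartet_distribution_uem",
    "triplet_distribution_uem",
    "triplet_anomaly_condition",
    "find_anomalies",
    "error_cancellation_identity",
]

MISSING = "?"
PATTERN_CAP = 8
FLOAT_MARGIN = 1e-12


def _exact(x):
    """Convert a decimal-given parameter to an exact rational."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class ErrorModel:
    """The (alpha, beta, gamma) error channel.

    alpha: probability a true 0 is observed as 1 (false positive).
    beta:  probability a true 1 is observed as 0 (false negative).
    gamma: probability an entry is masked as missing.

    All three must lie in [0, 1).  ``degenerate`` flags alpha + beta == 1,
    the line on which the quartet signal vanishes entirely and no guarantee
    about anomalies holds.
    """

    alpha: object = 0
    beta: object = 0
    gamma: object = 0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = float(getattr(self, name))
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @property
    def degenerate(self) -> bool:
        return float(self.alpha) + float(self.beta) == 1.0

    def as_exact(self) -> "ErrorModel":
        return ErrorModel(_exact(self.alpha), _exact(self.beta), _exact(self.gamma))


@dataclass
class PatternDistribution:
    """Exact probability map over the state patterns of an ordered subset of
    cells.  Patterns are strings over {0,1} (optionally with '?' once a
    missingness channel has been applied)."""

    labels: tuple
    probs: dict

    def __post_init__(self):
        self.labels = tuple(self.labels)

    @property
    def m(self) -> int:
        return len(self.labels)

    def __getitem__(self, pattern: str):
        zero = Fraction(0) if self._is_exact() else 0.0
        return self.probs.get(pattern, zero)

    def _is_exact(self) -> bool:
        return all(isinstance(v, (Fraction, int)) for v in self.probs.values())

    def total(self):
        return sum(self.probs.values())

    def validate(self, tol: float = 1e-12) -> None:
        if any(float(v) < -tol for v in self.probs.values()):
            raise ValueError("negative pattern probability")
        if abs(float(self.total()) - 1.0) > tol:
            raise ValueError(f"pattern probabilities sum to {float(self.total())}")

    def marginalize(self, labels: Sequence[str]) -> "PatternDistribution":
        """Marginal distribution over a sub-list of the cells."""
        idx = [self.labels.index(l) for l in labels]
        out: dict = {}
        for pattern, p in self.probs.items():
            sub = "".join(pattern[i] for i in idx)
            out[sub] = out.get(sub, 0) + p
        return PatternDistribution(tuple(labels), out)


def is_pattern_distribution(sigma: LineageTree, subset: Sequence[str]) -> PatternDistribution:
    """IS-model pattern distribution on an ordered subset of cells.

    For each edge *e*, the pattern with 1s exactly on the subset leaves below
    *e* receives mass p(e); ``unsampled_mass`` (and edges with no subset leaf
    below) map to the all-zero pattern.  The result is identical whether
    computed on the full tree or on its restriction to the subset.
    """
    subset = tuple(subset)
    if len(subset) > PATTERN_CAP:
        raise ValueError(f"pattern distribution capped at {PATTERN_CAP} cells")
    missing = set(subset) - sigma.leaf_labels()
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    if not sigma.has_probabilities():
        raise ValueError("tree has no edge probabilities")
    if not sigma.rooted:
        raise ValueError("the IS model is defined on a rooted tree")

    probs: dict = {}
    index = {l: i for i, l in enumerate(subset)}

    def add(pattern: str, p):
        probs[pattern] = probs.get(pattern, 0) + p

    def walk(node) -> frozenset:
        if node.is_leaf():
            below = frozenset([node.label]) if node.label in index else frozenset()
        else:
            below = frozenset().union(*(walk(c) for c in node.children))
        if node is not sigma.root:
            bits = ["0"] * len(subset)
            for l in below:
                bits[index[l]] = "1"
            add("".join(bits), node.prob)
        return below

    walk(sigma.root)
    add("0" * len(subset), sigma.unsampled_mass)
    dist = PatternDistribution(subset, probs)
    dist.validate(tol=1e-9)
    return dist


def uem_channel(g_pattern: str, d_pattern: str, em: ErrorModel):
    """Probability of observing pattern *d* given true pattern *g*: a product
    of independent per-cell channel terms.  *d* may contain '?'."""
    if len(g_pattern) != len(d_pattern):
        raise ValueError("patterns must have equal length")
    a, b, c = em.alpha, em.beta, em.gamma
    one = 1 if isinstance(a, (Fraction, int)) else 1.0
    p = one
    for g, d in zip(g_pattern, d_pattern):
        if g not in "01":
            raise ValueError(f"invalid true-state symbol {g!r}")
        if d == MISSING:
            p *= c
        elif d == "0":
            p *= (one - c) * ((one - a) if g == "0" else b)
        elif d == "1":
            p *= (one - c) * (a if g == "0" else (one - b))
        else:
            raise ValueError(f"invalid observed symbol {d!r}")
    return p


def corrupted_pattern_distribution(base: PatternDistribution, em: ErrorModel) -> PatternDistribution:
    """Push a true-pattern distribution through the error channel by
    exhaustively enumerating every observed pattern.

    This is the table-style enumeration that underlies the closed forms; it
    is deliberately brute force so it can serve as an independent oracle.
    Observed patterns range over {0,1} when gamma is 0 and {0,1,?} otherwise.
    """
    alphabet = "01" + (MISSING if float(em.gamma) > 0 else "")
    out: dict = {}
    for d_tuple in itertools.product(alphabet, repeat=base.m):
        d = "".join(d_tuple)
        mass = 0
        for g, p in base.probs.items():
            if float(p) == 0.0:
                continue
            mass = mass + p * uem_channel(g, d, em)
        out[d] = mass
    dist = PatternDistribution(base.labels, out)
    dist.validate(tol=1e-9)
    return dist


@dataclass
class QuartetDistribution:
    """Probabilities of the three quartet topologies on a 4-cell subset under
    the IS+UEM model, plus the background term ``f`` (the probability of a
    given quartet-informative observation arising from errors on
    quartet-uninformative true patterns)."""

    labels: tuple
    probs: dict  # Quartet -> probability
    background: object  # f

    def topologies(self) -> list:
        return quartet_topologies(self.labels)

    def __getitem__(self, q: Quartet):
        return self.probs[q]


@dataclass
class TripletDistribution:
    """Probabilities of the three triplets on a 3-cell subset under IS+UEM,
    plus the background term ``g`` (errors on invariant patterns)."""

    labels: tuple
    probs: dict  # Triplet -> probability
    background: object  # g

    def topologies(self) -> list:
        return triplet_topologies(self.labels)

    def __getitem__(self, t: Triplet):
        return self.probs[t]


def _pattern_for_quartet(q: Quartet, labels: Sequence[str]) -> str:
    bits = ["0"] * 4
    for l in q.pair1:
        bits[list(labels).index(l)] = "1"
    return "".join(bits)


def quartet_distribution_uem(
    sigma: LineageTree, subset: Sequence[str], em: ErrorModel,
    base: Optional[PatternDistribution] = None,
) -> QuartetDistribution:
    """Closed-form quartet probabilities on a 4-cell subset.

    With P(x) the IS pattern probabilities, the probability of quartet q_i is

        (1-gamma)^4 * [ f
            + ((1-a)^2 (1-b)^2 + a^2 b^2) * P(q_i)
            + 2 a b (1-a)(1-b) * (P(q_j) + P(q_k)) ]

    where f collects the ways the invariant and singleton/triple patterns can
    be corrupted into a quartet-informative observation.  Agrees with
    :func:`corrupted_pattern_distribution` exactly.
    """
    subset = tuple(sorted(subset))
    if len(subset) != 4:
        raise ValueError("quartet distribution needs exactly 4 cells")
    if base is None:
        base = is_pattern_distribution(sigma, subset)
    a, b, g = em.alpha, em.beta, em.gamma
    one = 1 if isinstance(a, (Fraction, int)) else 1.0

    P = base.__getitem__
    singles = ["1000", "0100", "0010", "0001"]
    triples = ["0111", "1011", "1101", "1110"]
    f = (
        2 * a * a * (one - a) * (one - a) * P("0000")
        + 2 * b * b * (one - b) * (one - b) * P("1111")
        + (a * (one - a) ** 2 * (one - b) + a * a * (one - a) * b)
        * sum(P(x) for x in singles)
        + (b * (one - b) ** 2 * (one - a) + b * b * (one - b) * a)
        * sum(P(x) for x in triples)
    )

    qs = quartet_topologies(subset)
    base_q = {}
    for q in qs:
        pat = _pattern_for_quartet(q, subset)
        comp = pat.translate(str.maketrans("01", "10"))
        base_q[q] = P(pat) + P(comp)

    keep = (one - a) ** 2 * (one - b) ** 2 + a * a * b * b
    cross = 2 * a * b * (one - a) * (one - b)
    scale = (one - g) ** 4
    probs = {}
    for i, q in enumerate(qs):
        others = sum(base_q[qs[j]] for j in range(3) if j != i)
        probs[q] = scale * (f + keep * base_q[q] + cross * others)
    return QuartetDistribution(subset, probs, scale * f)


def triplet_distribution_uem(
    sigma: LineageTree, subset: Sequence[str], em: ErrorModel,
    base: Optional[PatternDistribution] = None,
) -> TripletDistribution:
    """Closed-form triplet probabilities on a 3-cell subset.

    With x_i the singleton pattern putting the 1 on the *outgroup* cell of
    triplet t_i, the probability of t_i is

        (1-gamma)^3 * [ g + a^2 b * P(x_i)
            + a (1-a)(1-b) * (P(x_j) + P(x_k))
            + (1-a)(1-b)^2 * P(t_i)
            + a b (1-b) * (P(t_j) + P(t_k)) ]

    where g = a^2 (1-a) P(000) + b (1-b)^2 P(111).  Requires a rooted tree:
    state 0 is ancestral, 1 derived.
    """
    subset = tuple(sorted(subset))
    if len(subset) != 3:
        raise ValueError("triplet distribution needs exactly 3 cells")
    if base is None:
        if not sigma.rooted:
            raise ValueError("triplet probabilities require a rooted tree")
        base = is_pattern_distribution(sigma, subset)
    a, b, g = em.alpha, em.beta, em.gamma
    one = 1 if isinstance(a, (Fraction, int)) else 1.0

    P = base.__getitem__
    bg = a * a * (one - a) * P("000") + b * (one - b) ** 2 * P("111")

    ts = triplet_topologies(subset)

    def singleton_pattern(t: Triplet) -> str:
        # the variant pattern whose single 1 sits on the outgroup cell
        return "".join("1" if l == t.outgroup else "0" for l in subset)

    def informative_pattern(t: Triplet) -> str:
        # 1s on the cherry pair, 0 on the outgroup
        return "".join("0" if l == t.outgroup else "1" for l in subset)

    scale = (one - g) ** 3
    probs = {}
    for i, t in enumerate(ts):
        others = [ts[j] for j in range(3) if j != i]
        val = (
            bg
            + a * a * b * P(singleton_pattern(t))
            + a * (one - a) * (one - b) * sum(P(singleton_pattern(o)) for o in others)
            + (one - a) * (one - b) ** 2 * P(informative_pattern(t))
            + a * b * (one - b) * sum(P(informative_pattern(o)) for o in others)
        )
        probs[t] = scale * val
    return TripletDistribution(subset, probs, scale * bg)


def triplet_anomaly_condition(px_i, px_j, pt_i, pt_j, em: ErrorModel) -> bool:
    """Whether triplet t_j beats the displayed triplet t_i.

    The displayed/alternative probability difference under the channel is
    proportional to (1-beta)(1-(a+b)) [ (pt_i - pt_j) - a/(1-b) (px_i - px_j) ],
    so with a + b < 1 the alternative t_j is anomalous exactly when

        a/(1-b) * (px_i - px_j) - (pt_i - pt_j) > 0.

    ``px_*`` are the IS probabilities of the singleton patterns (the 1 on the
    outgroup cell), ``pt_*`` the IS probabilities of the triplets themselves.
    """
    a, b = em.alpha, em.beta
    if float(b) == 1.0:
        raise ValueError("beta must be < 1")
    if float(a) + float(b) >= 1.0:
        raise ValueError("condition derived for alpha + beta < 1")
    one = 1 if isinstance(a, (Fraction, int)) else 1.0
    lhs = (a / (one - b)) * (px_i - px_j) - (pt_i - pt_j)
    if isinstance(lhs, Fraction):
        return lhs > 0
    return lhs > FLOAT_MARGIN


@dataclass
class AnomalyRecord:
    """Scan result for one 3- or 4-cell subset."""

    subset: tuple
    displayed: object  # Quartet/Triplet, or "star"/"non-binary"
    probabilities: dict  # topology -> model probability
    anomalous: list = field(default_factory=list)  # topologies beating the displayed one


@dataclass
class AnomalyReport:
    mode: str
    records: list

    @property
    def anomalies(self) -> list:
        return [r for r in self.records if r.anomalous]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("subset\tdisplayed_topology\tp_displayed\tp_alt1\tp_alt2\tanomalous_flags\n")
            for r in self.records:
                tops = sorted(r.probabilities, key=str)
                if isinstance(r.displayed, (Quartet, Triplet)):
                    disp = r.displayed
                    alts = [t for t in tops if t != disp]
                    p_disp = float(r.probabilities[disp])
                else:
                    disp = r.displayed
                    alts = tops[1:]
                    p_disp = float(r.probabilities[tops[0]])
                flags = ",".join(str(t) for t in r.anomalous) or "-"
                fh.write(
                    f"{','.join(r.subset)}\t{disp}\t{p_disp!r}\t"
                    f"{float(r.probabilities[alts[0]])!r}\t{float(r.probabilities[alts[1]])!r}\t{flags}\n"
                )


def find_anomalies(
    sigma: LineageTree,
    em: ErrorModel,
    mode: str = "quartet",
    max_leaves: int = 20,
    subsets: Optional[Iterable[Sequence[str]]] = None,
    exact: bool = True,
) -> AnomalyReport:
    """Scan every 4-cell (or 3-cell) subset for anomalous topologies.

    A topology is anomalous if its IS+UEM probability strictly exceeds that
    of the topology actually displayed by the model tree on the subset.  For
    subsets whose restriction is unresolved (star / non-binary) the model
    predicts equal probabilities, so any strict ordering is reported as an
    anomaly (reference = the minimum of the three).
    """
    if mode not in ("quartet", "triplet"):
        raise ValueError("mode must be 'quartet' or 'triplet'")
    if exact:
        em = em.as_exact()
    labels = sorted(sigma.leaf_labels())
    size = 4 if mode == "quartet" else 3
    if subsets is None:
        if len(labels) > max_leaves:
            raise ValueError(
                f"{len(labels)} leaves exceeds the full-scan cap ({max_leaves}); "
                "pass an explicit subset sample"
            )
        subsets = itertools.combinations(labels, size)
    records = []
    for subset in subsets:
        subset = tuple(sorted(subset))
        base = is_pattern_distribution(sigma, subset)
        restricted = sigma.restrict(subset)
        if mode == "quartet":
            dist = quartet_distribution_uem(sigma, subset, em, base=base)
            displayed = restricted.displayed_quartet(subset)
        else:
            dist = triplet_distribution_uem(sigma, subset, em, base=base)
            displayed = restricted.displayed_triplet(subset)
        if displayed is not None:
            ref = dist.probs[displayed]
            disp = displayed
        else:
            ref = min(dist.probs.values())
            disp = "star" if mode == "quartet" else "non-binary"
        anomalous = [t for t, p in dist.probs.items() if t != displayed and _gt(p, ref)]
        records.append(AnomalyRecord(subset, disp, dict(dist.probs), anomalous))
    return AnomalyReport(mode, records)


def _gt(x, y) -> bool:
    if isinstance(x, Fraction) and isinstance(y, Fraction):
        return x > y
    return float(x) > float(y) + FLOAT_MARGIN


def error_cancellation_identity(em: ErrorModel):
    """Return the expanded quartet-signal coefficient and its factored form.

    The coefficient multiplying the IS quartet-probability difference after
    the error channel is ((1-b)^2 (1-a)^2 + b^2 a^2) - 2 b (1-b) a (1-a),
    which factors as (1 - (a+b))^2: strictly positive unless a + b = 1, the
    single degenerate line on which the topological signal cancels.
    """
    a, b = em.alpha, em.beta
    one = 1 if isinstance(a, (Fraction, int)) else 1.0
    expanded = ((one - b) ** 2 * (one - a) ** 2 + b * b * a * a) - 2 * b * (one - b) * a * (one - a)
    factored = (one - (a + b)) ** 2
    return expanded, factored
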