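# Methods

## Model

A cell lineage tree σ is a rooted phylogenetic tree whose leaves are
sampled cells; each edge *e* carries a mutation probability *p(e)*, with
Σ_e p(e) = 1 and every internal edge strictly positive.  Terminal edges may
have *p(e)* = 0; such "fake" edges attach a sampled cell that is identical
to one of its ancestors (e.g. the healthy cell at the root), so it can
never acquire a private mutation.  Under the infinite-sites (IS) model each
of *k* i.i.d. mutations selects one edge from this distribution; the cells
below it get state 1, all others state 0, so a mutation is exactly an
edge-induced bipartition and the error-free matrix is a perfect phylogeny.
The unbiased error-and-missingness (UEM) channel then acts independently
per matrix entry: 0→1 with probability α (false positive), 1→0 with β
(false negative), and masking to '?' with γ, each in [0, 1).

State 0 is ancestral and 1 derived; this orientation matters for triplets
(a mutation shared by two cells implies their cherry) but not for quartets.

## Restriction and the sub-model convention

Restricting σ to a cell subset S deletes the other leaves and suppresses
degree-2 vertices, adding the merged edges' probabilities.  Two kinds of
probability mass have no edge to live on in the restricted tree:

* mass on edges **ancestral to the MRCA of S** — every cell of S is below
  such an edge, so a mutation there yields the all-ones pattern.  It is
  assigned to a synthetic root-stem edge of the restricted tree.
* mass on edges **with no descendant in S** — a mutation there yields the
  all-zero pattern on S.  No edge of a plain tree can produce all-zeros, so
  the restricted tree stores it in an explicit `unsampled_mass` field; edge
  probabilities plus `unsampled_mass` always sum to one, and the pattern
  calculator maps this mass to the all-zero pattern.

With these two conventions the pattern distribution computed on the
restriction equals, pattern for pattern, the one computed on the full tree
(tested exactly), which is the property the quartet/triplet theory needs.

## Exact calculators and the enumeration oracle

Pattern, quartet and triplet probabilities are computed in exact rational
arithmetic (`fractions.Fraction`) by default: the anomaly analysis operates
on differences at the 1/1012 scale on the worked fixture, which would be
fragile in floating point once multiplied through the channel polynomials.
Decimal-given rates are converted via `Fraction(str(x))`, so 0.001 means
exactly 1/1000.  Floating-point inputs are accepted everywhere and simply
propagate; strict inequalities in anomaly checks then use a 1e-12 margin
instead of exact comparison.

Quartet and triplet probabilities under the channel have closed forms (the
quartet one scales pairwise differences by (1−(α+β))²(1−γ)⁴, the triplet
one mixes singleton-pattern and triplet-pattern terms).  Independently, a
brute-force oracle pushes the base distribution through the per-cell
channel by enumerating all observed patterns over {0,1,?}^m.  The two
routes must agree exactly; the test suite and the acceptance script check
this on all five rooted 4-leaf shapes and both 3-leaf shapes across
hundreds of random rational parameter draws.  Missingness enters the
informative-pattern masses as (1−γ)^4 (quartets) and (1−γ)^3 (triplets),
reflecting per-cell independence.

Anomaly scans visit every 4- (or 3-) cell subset, compare each alternative
topology's probability against the displayed one, and flag strict
excesses.  For subsets whose restriction is unresolved the model predicts
exact equality of the three topologies, so any strict ordering is flagged
(the reference is the minimum).  Full scans are capped at 20 leaves by
default; larger trees require an explicit subset sample.

## Simulator

The simulator consumes a single seeded generator stream in a fixed order —
the k edge draws, then the error draws, then the missingness draws — so a
seed fully determines the output.  Fake leaves pass through the channel
like any other leaf (their ground truth is the state at their attachment
point) and can be dropped from the output.

The anomalous-triplet fixture is constructed to realize the published
restricted distribution rather than any particular full topology: a stem
edge, a cherry containing a fake cell 1 and a real cell 4, and a chain of
m+9 mutation-bearing edges leading to cell 10, with all side cells attached
by fake edges so they do not perturb the restriction.  With uniform
probabilities on the m+12 non-fake edges and m = 1000, the sub-model on
{1, 4, 10} is exactly {0, 1/1012, 1009/1012, 1/1012} on the patterns
{x₁, x₄, x₁₀, t₁₀}.  Random trees for property tests grow a binary
topology by sequential leaf attachment, contract a (1−resolution) fraction
of internal edges, and draw symmetric-Dirichlet edge probabilities rounded
onto a 10⁻⁶ grid and renormalised so they stay exact rationals.

What the generator emulates: i.i.d. mutations, unbiased entrywise errors,
unbiased missingness.  What it does not: doublets, copy-number events,
cell- or site-specific error rates, and any dependence between mutations.
Passing tests therefore speak to the model's identifiability and the
solvers' correctness, not to robustness against those real-data phenomena.

## Solvers

Support counting turns each informative column into quartet (pairs × pairs)
or triplet (pairs × outgroup) weights stored sparsely per subset.
QS_D(T) visits only subsets with non-zero weight, which equals the full
brute-force sum over 4-subsets (tested on random matrices up to 8 cells).

* **Exhaustive** search enumerates all (2n−5)!! unrooted (or (2n−3)!!
  rooted) topologies, capped at n = 8 by default (10 395 topologies).
  Tie-break everywhere: lexicographically smallest canonical topology
  string; the number of co-optima is reported.
* **Constrained** search solves MQSS exactly within the space Σ of
  bipartitions harvested from the mutations (plus trivial ones and any
  starting trees), by dynamic programming over clades after rooting at the
  smallest-label leaf.  The objective decomposes over clade joins: a
  displayed quartet ab|cd is counted once per pair-merge with the other
  pair outside the merged clade, minus the pairs-within-C₁ ×
  pairs-within-C₂ correction for quartets whose two pair-clades are
  disjoint — both terms are local to a join, so the DP is exact; the
  returned score is re-verified by direct recomputation.  Missing cells
  join the 0-side of a split by default ("zero" policy, the
  ancestral-majority reading) or the column can be dropped ("drop"); this
  completion rule is a documented package choice, as no canonical rule
  exists.
* **NNI** hill climbing applies nearest-neighbour interchanges with a
  seeded move order and monotone acceptance, for instances beyond the
  exhaustive cap.

The estimators follow the scikit-learn protocol (`fit`, `get_params`,
fitted attributes with trailing underscores); `QuartetSupertree(method=
"auto")` picks exhaustive search up to the cap and the constrained DP
beyond it.  Estimated trees are unrooted; rooting on a designated healthy
cell's terminal edge is available post hoc.

Tree error is the number of false negative branches (internal bipartitions
of the reference missing from the estimate) and false positives (the
converse), compared unrooted.  For unresolved reference trees zero FN means
the estimate is a refinement, which is the guarantee MQSS affords.

## Experiment scales

The consistency experiments use 6-cell model trees with **uniform edge
probabilities** (the convention of equal mutation probability on non-fake
edges), α=0.05, β=0.2, γ=0.1, k=2000, 20 replicates — sizes chosen so the
exhaustive solver is the oracle and a full run takes seconds.  Randomized
scans use 200 instances on 5–7 cells.  The triplet-fragility comparison
runs on the anomalous fixture restricted to {healthy, 1, 4, 10} at
α=0.001, β=0.2, γ=0.05 with k up to 2×10⁴: quartet-support error decays
toward zero while triplet-support error persists.  This contrast is
reported descriptively (the acceptance script records both means); it is a
finite-k illustration of the asymptotic statement, not a hypothesis test.

## Known limitations

* Exhaustive modes are factorial in n; the constrained DP is exponential in
  the worst case (it is exact, not heuristic) and depends on Σ containing a
  refinement's bipartitions, which for few mutations it may not.
* The NNI search has no optimality guarantee and is only as good as its
  start.
* Newick writing renders exact rationals as floats, so a parse round-trip
  of an exact tree preserves topology and ~17 significant digits, not
  exactness.
* The DP's co-optimum count multiplies counts along the chosen partition
  only; it is a lower bound on the true number of co-optimal trees (the
  exhaustive solver's count is exact).
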