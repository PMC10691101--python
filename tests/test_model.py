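"""Exact IS+UEM probability calculators and anomaly detection."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from qlineage.model import (
    ErrorModel,
    _pattern_for_quartet,
    corrupted_pattern_distribution,
    error_cancellation_identity,
    find_anomalies,
    is_pattern_distribution,
    quartet_distribution_uem,
    triplet_anomaly_condition,
    triplet_distribution_uem,
    uem_channel,
)
from qlineage.simulate import (
    FOUR_LEAF_SHAPES,
    assign_random_probabilities,
    build_shape_tree,
    build_triplet_shape_tree,
    random_lineage_tree,
)
from qlineage.tree import parse_newick


def random_exact_em(rng, with_gamma=True, bound=400):
    a = Fraction(int(rng.integers(0, bound)), 1000)
    b = Fraction(int(rng.integers(0, bound)), 1000)
    g = Fraction(int(rng.integers(0, bound)), 1000) if with_gamma else Fraction(0)
    return ErrorModel(a, b, g)


class TestErrorModel:
    def test_bounds(self):
        with pytest.raises(ValueError):
            ErrorModel(alpha=1.0)
        with pytest.raises(ValueError):
            ErrorModel(beta=-0.1)

    def test_degenerate_line_flagged(self):
        assert ErrorModel(0.5, 0.5).degenerate
        assert not ErrorModel(0.5, 0.4).degenerate

    def test_as_exact_is_decimal_exact(self):
        em = ErrorModel(0.001, 0.2, 0.05).as_exact()
        assert em.alpha == Fraction(1, 1000)
        assert em.beta == Fraction(1, 5)
        assert em.gamma == Fraction(1, 20)


class TestChannel:
    def test_false_positive_case(self):
        assert uem_channel("0", "1", ErrorModel(0.1, 0, 0)) == pytest.approx(0.1)

    def test_double_true_positive(self):
        assert uem_channel("11", "11", ErrorModel(0, 0.2, 0)) == pytest.approx(0.64)

    def test_missing_mass(self):
        assert uem_channel("01", "??", ErrorModel(0, 0, 0.5)) == pytest.approx(0.25)

    def test_invalid_symbols(self):
        with pytest.raises(ValueError):
            uem_channel("02", "01", ErrorModel())
        with pytest.raises(ValueError):
            uem_channel("01", "0x", ErrorModel())


class TestPatternDistribution:
    def test_one_pattern_per_edge(self):
        t = parse_newick("((A:0.25,B:0.25):0.25,C:0.25);", require_probabilities=True)
        d = is_pattern_distribution(t, ("A", "B", "C"))
        nz = {k: float(v) for k, v in d.probs.items() if v}
        assert nz == {"100": 0.25, "010": 0.25, "001": 0.25, "110": 0.25}

    def test_augmented_fixture_values(self, augmented_fixture):
        d = is_pattern_distribution(augmented_fixture, ("1", "4", "10"))
        assert d["100"] == 0
        assert d["010"] == Fraction(1, 1012)
        assert d["001"] == Fraction(1009, 1012)
        assert d["110"] == Fraction(1, 1012)

    def test_full_tree_equals_restricted(self, augmented_fixture):
        sub = augmented_fixture.restrict(["1", "4", "10"])
        d_full = is_pattern_distribution(augmented_fixture, ("1", "4", "10"))
        d_sub = is_pattern_distribution(sub, ("1", "4", "10"))
        for p in d_full.probs.keys() | d_sub.probs.keys():
            assert d_full[p] == d_sub[p]

    def test_marginalization_consistency(self, rng):
        for _ in range(5):
            t = random_lineage_tree(7, resolution=0.7, rng=rng)
            labels = sorted(t.leaf_labels())
            big = tuple(labels[:5])
            small = (labels[0], labels[2], labels[4])
            marg = is_pattern_distribution(t, big).marginalize(small)
            direct = is_pattern_distribution(t, small)
            for p in set(marg.probs) | set(direct.probs):
                assert marg[p] == direct[p]

    def test_single_informative_quartet_under_is(self, rng):
        # at most one quartet topology has positive probability per 4-subset
        for _ in range(5):
            t = random_lineage_tree(6, resolution=0.6, rng=rng)
            labels = sorted(t.leaf_labels())
            for S in itertools.combinations(labels, 4):
                d = is_pattern_distribution(t, S)
                masses = []
                for pat in ("1100", "1010", "1001"):
                    comp = pat.translate(str.maketrans("01", "10"))
                    masses.append(d[pat] + d[comp])
                assert sum(m > 0 for m in masses) <= 1


class TestCorruption:
    def test_zero_error_is_identity(self, rng):
        t = random_lineage_tree(5, rng=rng)
        base = is_pattern_distribution(t, tuple(sorted(t.leaf_labels()))[:4])
        out = corrupted_pattern_distribution(base, ErrorModel(0, 0, 0))
        for p in set(base.probs) | set(out.probs):
            assert base[p] == out[p]

    def test_single_false_negative_row(self):
        # base concentrated on 1100: observing 0100 needs one false negative
        # on the first cell, a true positive on the second and no false
        # positives on the last two
        from qlineage.model import PatternDistribution

        base = PatternDistribution(("A", "B", "C", "D"), {"1100": Fraction(1)})
        a, b = Fraction(1, 50), Fraction(3, 10)
        out = corrupted_pattern_distribution(base, ErrorModel(a, b, Fraction(0)))
        assert out["0100"] == b * (1 - b) * (1 - a) ** 2
        assert out["1100"] == (1 - b) ** 2 * (1 - a) ** 2
        assert out["0011"] == b * b * a * a

    def test_sums_to_one_exactly(self, rng):
        for _ in range(10):
            t = random_lineage_tree(5, resolution=0.8, rng=rng)
            S = tuple(sorted(t.leaf_labels()))[:4]
            base = is_pattern_distribution(t, S)
            em = random_exact_em(rng)
            out = corrupted_pattern_distribution(base, em)
            assert out.total() == 1


class TestClosedFormsAgainstOracle:
    @pytest.mark.parametrize("shape", FOUR_LEAF_SHAPES)
    def test_quartet_closed_form(self, shape, rng):
        for _ in range(20):
            t = assign_random_probabilities(build_shape_tree(shape, list("abcd")),
                                            rng, denominator=1000)
            em = random_exact_em(rng)
            base = is_pattern_distribution(t, tuple("abcd"))
            oracle = corrupted_pattern_distribution(base, em)
            qd = quartet_distribution_uem(t, list("abcd"), em)
            for q in qd.topologies():
                pat = _pattern_for_quartet(q, tuple(sorted("abcd")))
                comp = pat.translate(str.maketrans("01", "10"))
                assert qd.probs[q] == oracle[pat] + oracle[comp]

    @pytest.mark.parametrize("binary", [True, False])
    def test_triplet_closed_form(self, binary, rng):
        for _ in range(20):
            t = assign_random_probabilities(build_triplet_shape_tree(binary, list("abc")),
                                            rng, denominator=1000)
            em = random_exact_em(rng)
            base = is_pattern_distribution(t, tuple("abc"))
            oracle = corrupted_pattern_distribution(base, em)
            td = triplet_distribution_uem(t, list("abc"), em)
            for tr in td.topologies():
                pat = "".join("0" if l == tr.outgroup else "1" for l in tuple(sorted("abc")))
                assert td.probs[tr] == oracle[pat]

    def test_quartet_difference_identity(self, rng):
        # P(qi) - P(qj) = (1-(a+b))^2 (1-g)^4 (P_IS(qi) - P_IS(qj)) exactly
        for _ in range(10):
            t = random_lineage_tree(6, resolution=0.8, rng=rng)
            labels = sorted(t.leaf_labels())
            S = tuple(labels[i] for i in sorted(rng.choice(6, 4, replace=False)))
            em = random_exact_em(rng)
            base = is_pattern_distribution(t, S)
            qd = quartet_distribution_uem(t, S, em)
            a, b, g = em.alpha, em.beta, em.gamma
            factor = (1 - (a + b)) ** 2 * (1 - g) ** 4
            qs = qd.topologies()
            for qi, qj in itertools.combinations(qs, 2):
                pi = base[_pattern_for_quartet(qi, S)] + base[
                    _pattern_for_quartet(qi, S).translate(str.maketrans("01", "10"))]
                pj = base[_pattern_for_quartet(qj, S)] + base[
                    _pattern_for_quartet(qj, S).translate(str.maketrans("01", "10"))]
                assert qd.probs[qi] - qd.probs[qj] == factor * (pi - pj)

    def test_difference_ratio_at_reference_rates(self):
        # alpha=0.001, beta=0.2, gamma=0.05 retains 52% of the IS signal
        em = ErrorModel(0.001, 0.2, 0.05).as_exact()
        t = build_shape_tree("balanced", list("abcd"))
        base = is_pattern_distribution(t, tuple("abcd"))
        qd = quartet_distribution_uem(t, list("abcd"), em)
        qs = qd.topologies()
        p_is = base["1100"] + base["0011"]
        ratio = (qd.probs[qs[0]] - qd.probs[qs[1]]) / p_is
        assert round(float(ratio), 2) == 0.52


class TestTripletAnomalies:
    def test_coefficient(self):
        em = ErrorModel(Fraction(1, 1000), Fraction(1, 5))
        assert em.alpha / (1 - em.beta) == Fraction(125, 100000)

    def test_fixture_condition_true(self):
        em = ErrorModel(Fraction(1, 1000), Fraction(1, 5))
        # displayed 10|1,4 vs alternative 4|1,10
        assert triplet_anomaly_condition(
            Fraction(1009, 1012), Fraction(1, 1012), Fraction(1, 1012), Fraction(0), em)

    def test_alpha_zero_never_anomalous(self):
        em = ErrorModel(Fraction(0), Fraction(1, 5))
        assert not triplet_anomaly_condition(
            Fraction(1009, 1012), Fraction(1, 1012), Fraction(1, 1012), Fraction(0), em)

    def test_fixture_scan_flags_both_alternatives(self, augmented_fixture):
        em = ErrorModel(0.001, 0.2)
        rep = find_anomalies(augmented_fixture, em, mode="triplet",
                             subsets=[("1", "4", "10")])
        flagged = {str(t) for t in rep.records[0].anomalous}
        assert flagged == {"1|10,4", "4|1,10"}

    def test_alpha_zero_scan_clean(self, augmented_fixture):
        em = ErrorModel(0.0, 0.2)
        rep = find_anomalies(augmented_fixture, em, mode="triplet",
                             subsets=[("1", "4", "10")])
        assert rep.anomalies == []

    def test_triplet_difference_formula(self, rng):
        # difference = (1-g)^3 [ a(1-(a+b))(P(x_j)-P(x_i))
        #                        + (1-b)(1-(a+b))(P(t_i)-P(t_j)) ]
        for _ in range(10):
            t = random_lineage_tree(5, resolution=0.8, rng=rng)
            labels = sorted(t.leaf_labels())
            S = tuple(labels[:3])
            em = random_exact_em(rng)
            a, b, g = em.alpha, em.beta, em.gamma
            base = is_pattern_distribution(t, S)
            td = triplet_distribution_uem(t, S, em)
            ts = td.topologies()

            def px(tr):
                return base["".join("1" if l == tr.outgroup else "0" for l in S)]

            def pt(tr):
                return base["".join("0" if l == tr.outgroup else "1" for l in S)]

            for ti, tj in itertools.combinations(ts, 2):
                lhs = td.probs[ti] - td.probs[tj]
                rhs = (1 - g) ** 3 * (
                    a * (1 - (a + b)) * (px(tj) - px(ti))
                    + (1 - b) * (1 - (a + b)) * (pt(ti) - pt(tj))
                )
                assert lhs == rhs


class TestQuartetAnomalies:
    def test_no_anomalous_quartets_on_fixture(self, augmented_fixture, rng):
        em = ErrorModel(0.001, 0.2, 0.05)
        labels = ["1", "4", "10", "healthy", "s1", "s500"]
        subsets = list(itertools.combinations(labels, 4))
        rep = find_anomalies(augmented_fixture, em, mode="quartet", subsets=subsets)
        assert rep.anomalies == []

    def test_no_anomalous_quartets_random(self, rng):
        for _ in range(20):
            t = random_lineage_tree(6, resolution=float(rng.uniform(0.3, 1.0)), rng=rng)
            em = random_exact_em(rng)
            if em.degenerate:
                continue
            rep = find_anomalies(t, em, mode="quartet")
            assert rep.anomalies == []

    def test_scan_cap(self, rng):
        t = random_lineage_tree(25, rng=rng)
        with pytest.raises(ValueError):
            find_anomalies(t, ErrorModel(), mode="quartet", max_leaves=20)


class TestCancellationIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        (Fraction(3, 10), Fraction(4, 10), Fraction(9, 100)),
        (Fraction(5, 10), Fraction(5, 10), Fraction(0)),
        (Fraction(0), Fraction(0), Fraction(1)),
    ])
    def test_expanded_equals_factored(self, a, b, expected):
        expanded, factored = error_cancellation_identity(ErrorModel(a, b))
        assert expanded == factored == expected
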