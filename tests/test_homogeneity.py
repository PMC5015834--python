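"""Hypergeometric homogeneity scoring, set shuffling, and enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from homoset import (CommonNeighborSet, XYState, assess_homogeneity,
                     bilateral_ratio, enrichment_tests, hgt_pvalue,
                     shuffle_sets, synapse_coverage)
from homoset.homogeneity import _z_and_p, is_bilateral_pair

from conftest import build


def exact_hgt(k, n, K, N):
    """Big-integer upper-tail hypergeometric oracle."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


def make_set(types, x="X", y="Y", connected=True):
    from homoset import type_by_id
    s = CommonNeighborSet(x, y, connected,
                          XYState.RECIPROCAL if connected else XYState.NONE)
    s.members = [(f"Z{i}", type_by_id(t)) for i, t in enumerate(types)]
    return s


class TestHGT:
    def test_k_zero_is_certain(self):
        assert hgt_pvalue(0, 5, 50, 100) == 1.0

    def test_all_draws_are_all_successes(self):
        # k = n = K: exactly one favourable draw out of C(N, n)
        assert hgt_pvalue(4, 4, 4, 12) == pytest.approx(1 / comb(12, 4), rel=1e-12)

    def test_reference_value(self):
        # C(50,5)/C(100,5), frozen from the exact combinatorial oracle
        assert hgt_pvalue(5, 5, 50, 100) == pytest.approx(0.028142247214412164,
                                                          rel=1e-12)

    def test_inconsistent_arguments_rejected(self):
        for bad in [(6, 5, 50, 100), (2, 5, 1, 100), (0, 5, 50, 4)]:
            with pytest.raises(ValueError):
                hgt_pvalue(*bad)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_exact_oracle(self, data):
        N = data.draw(st.integers(2, 120))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        expect = float(exact_hgt(k, n, K, N))
        assert hgt_pvalue(k, n, K, N) == pytest.approx(expect, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_monotone_nonincreasing_in_k(self, data):
        N = data.draw(st.integers(5, 80))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ps = [hgt_pvalue(k, n, K, N) for k in range(min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_matches_monte_carlo_urn(self):
        """Agreement with direct urn sampling within 3 Monte-Carlo SE."""
        rng = np.random.default_rng(0)
        for (k, n, K, N) in [(3, 6, 20, 60), (5, 8, 30, 90), (2, 5, 10, 40)]:
            draws = rng.hypergeometric(K, N - K, n, size=20_000)
            est = float(np.mean(draws >= k))
            se = np.sqrt(est * (1 - est) / 20_000)
            assert abs(hgt_pvalue(k, n, K, N) - est) <= 3 * max(se, 1e-4)


class TestAssess:
    def test_rare_pure_set_is_homogeneous(self):
        # one pure set of a globally rare type among heterogeneous others
        sets = [make_set([10] * 6)] + [make_set([1, 2, 3, 4, 5])] * 6
        res = assess_homogeneity(sets)
        assert res[0].dominant_type.id == 10
        assert res[0].homogeneous

    def test_majority_rule_vetoes_small_fraction(self):
        """k/n < 1/2 is never homogeneous, however small the p-value."""
        focal = make_set([10, 10, 10, 10] + [1, 2, 3, 5, 16, 17])  # k/n = 0.4
        background = [make_set([1, 2, 3, 5, 16, 17, 19, 20, 21, 11])] * 40
        res = assess_homogeneity([focal] + background)
        r = res[0]
        assert r.dominant_type.id == 10 and r.k == 4
        assert r.p_hgt < 0.001
        assert not r.majority and not r.homogeneous

    def test_order_invariance(self):
        sets = [make_set([10] * 5), make_set([1, 2, 10, 10, 13]),
                make_set([13] * 7)]
        a = assess_homogeneity(sets)
        b = assess_homogeneity(sets[::-1])
        assert {(r.k, r.n, r.p_hgt) for r in a} == {(r.k, r.n, r.p_hgt) for r in b}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assess_homogeneity([])


class TestShuffleSets:
    def test_single_set_unchanged_composition(self):
        s = make_set([10, 10, 13])
        (out,) = shuffle_sets([s], seed=1)
        assert sorted(t.id for _, t in out.members) == [10, 10, 13]

    @pytest.mark.parametrize("seed", range(5))
    def test_conserves_sizes_and_global_multiset(self, seed):
        sets = [make_set([10] * 5), make_set([1, 2, 3, 13, 13, 13]),
                make_set([15] * 7)]
        out = shuffle_sets(sets, seed=seed)
        assert [s.n for s in out] == [s.n for s in sets]
        before = sorted(t.id for s in sets for _, t in s.members)
        after = sorted(t.id for s in out for _, t in s.members)
        assert before == after
        # member Z names stay attached to their sets
        assert [[z for z, _ in s.members] for s in out] == \
               [[z for z, _ in s.members] for s in sets]

    def test_two_pure_sets_follow_hypergeometric_frequencies(self):
        """Shuffling (5xA, 5xB) across two size-5 sets: the count of A in the
        first set follows hypergeometric(10, 5, 5) (chi-square check)."""
        sets = [make_set([10] * 5), make_set([13] * 5)]
        counts = np.zeros(6)
        reps = 10_000
        rng_seeds = range(reps)
        for seed in rng_seeds:
            out = shuffle_sets(sets, seed=seed)
            counts[sum(1 for _, t in out[0].members if t.id == 10)] += 1
        expected = np.array([stats.hypergeom.pmf(k, 10, 5, 5) for k in range(6)]) * reps
        mask = expected > 5
        chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
        df = int(mask.sum()) - 1
        assert chi2 < stats.chi2.ppf(0.999, df)


class TestEnrichment:
    def test_z_formula_toy(self):
        z, p, degen = _z_and_p(10.0, np.array([1.0, 2.0, 3.0]), 3)
        assert z == pytest.approx(8.0)
        assert not degen

    def test_degenerate_null_flagged_with_bound(self):
        z, p, degen = _z_and_p(5.0, np.array([2.0, 2.0, 2.0]), 100)
        assert degen and np.isinf(z) and p == pytest.approx(1 / 101)

    def test_planted_types_significant_noise_not(self):
        # A noise set can be genuinely homogeneous by chance (per-set alpha
        # carries no multiplicity correction), so a representative noise
        # draw is fixed.
        rng = np.random.default_rng(0)
        sets = [make_set([10] * 6) for _ in range(8)]
        for _ in range(20):
            sets.append(make_set(list(rng.integers(1, 22, size=6))))
        res = enrichment_tests(sets, R=100, seed=0)
        assert res.per_type[10]["significant"]
        others = [d for t, d in res.per_type.items() if t != 10]
        assert sum(d["significant"] for d in others) == 0

    def test_null_self_consistency(self):
        """A shuffle of the sets is typically not enriched vs re-shuffles."""
        rng = np.random.default_rng(11)
        base = [make_set(list(rng.integers(1, 22, size=rng.integers(5, 9))))
                for _ in range(15)]
        hits = 0
        reps = 20
        for r in range(reps):
            control = shuffle_sets(base, seed=5000 + r)
            res = enrichment_tests(control, R=60, seed=r)
            if not any(d["significant"] for d in res.per_type.values()):
                hits += 1
        assert hits >= 0.9 * reps


class TestCoverage:
    def _pipeline_results(self, c):
        from homoset import extract_sets
        sets = extract_sets(c, min_neighbors=5)
        return assess_homogeneity(sets)

    def test_no_homogeneous_sets_is_zero(self):
        c = build(chem=[("A", "B", 10)])
        assert synapse_coverage(c, []) == 0.0

    def test_single_planted_set_covers_everything(self):
        chem = [("X", "Y", 2), ("Y", "X", 1)]
        chem += [("X", f"Z{i}", 1) for i in range(5)]
        chem += [("Y", f"Z{i}", 1) for i in range(5)]
        c = build(chem=chem)
        res = self._pipeline_results(c)
        assert len(res) == 1
        # alone, a set is its own population (p = 1); coverage is what is
        # under test, so mark it homogeneous directly
        res[0].homogeneous = True
        assert synapse_coverage(c, res) == 1.0

    def test_partial_coverage_arithmetic(self):
        chem = [("X", "Y", 1)]
        chem += [("X", f"Z{i}", 1) for i in range(5)]
        # X-Z and X-Y edges weigh 6; stray edges add 4 more
        chem += [(f"Z{i}", f"W{i}", 1) for i in range(4)]
        c = build(chem=chem)
        for i in range(5):
            c.add_edge("Y", f"Z{i}", "chemical", 1)
        res = self._pipeline_results(c)
        assert len(res) == 1
        res[0].homogeneous = True
        # covered: X-Y (1) + 5 X-Z + 5 Y-Z = 11 of total 15
        assert synapse_coverage(c, res) == pytest.approx(11 / 15)


class TestBilateral:
    @pytest.mark.parametrize("a,b,expected", [
        ("PHAL", "PHAR", True),
        ("AVHR", "ADLR", False),
        ("AVAL", "AVAR", True),
        ("AVAL", "PVAR", False),
        ("L", "R", False),          # bare side letters are not a pair
        ("ASEL", "ASEL", False),
    ])
    def test_symmetry_rule(self, a, b, expected):
        assert is_bilateral_pair(a, b) is expected

    def test_ratio_arithmetic(self):
        res = []
        pairs = [("PHAL", "PHAR"), ("A1", "B1"), ("A2", "B2"),
                 ("A3", "B3"), ("A4", "B4")]
        sets = [make_set([10] * 5, x=a, y=b) for a, b in pairs]
        results = assess_homogeneity(sets)
        for r in results:
            r.homogeneous = True
        hom, allr = bilateral_ratio(results)
        assert hom == pytest.approx(0.25)
        assert allr == pytest.approx(0.25)
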