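import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gaitsim.errors import EmptyInputError, SupportMismatchError
from gaitsim.fuzzy import (
    DISTANCE_MEASURES,
    CrispSet,
    FuzzySet,
    axiom_report,
    complement,
    hamming_distance,
    intersect,
    one_set,
    sim_bounds_complement,
    sim_bounds_sum,
    sim_containment,
    sim_minmax,
    union_of,
    zero_set,
)

TOL = 1e-12


def fs(*memberships):
    return FuzzySet.from_memberships(memberships)


membership_vectors = hnp.arrays(
    float,
    st.integers(1, 10),
    elements=st.floats(0.0, 1.0, allow_nan=False),
)


class TestFuzzySet:
    def test_valid_construction(self):
        s = FuzzySet(("a", "b"), [0.2, 0.9])
        assert len(s) == 2
        assert s.support == ("a", "b")

    def test_empty_support_rejected(self):
        with pytest.raises(EmptyInputError):
            FuzzySet((), [])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FuzzySet(("a", "a"), [0.1, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fs(0.5, 1.2)
        with pytest.raises(ValueError):
            fs(-0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FuzzySet(("a", "b", "c"), [0.1, 0.2])

    def test_memberships_immutable(self):
        s = fs(0.3, 0.4)
        with pytest.raises(ValueError):
            s.memberships[0] = 0.9

    def test_crisp_set_accepts_binary_only(self):
        CrispSet(("a", "b"), [1.0, 0.0])
        with pytest.raises(ValueError, match="crisp"):
            CrispSet(("a", "b"), [0.5, 1.0])


class TestHammingDistance:
    def test_identity_is_zero(self):
        a = fs(0.1, 0.7, 0.3)
        assert hamming_distance(a, a) == 0.0

    def test_crisp_complement_is_one(self):
        d = fs(1, 0, 1)
        assert hamming_distance(d, complement(d)) == 1.0

    def test_hand_computed_example(self):
        # (|0.2-0.4| + |0.6-0.4|) / 2
        assert hamming_distance(fs(0.2, 0.6), fs(0.4, 0.4)) == pytest.approx(0.2)

    def test_support_mismatch_raises(self):
        with pytest.raises(SupportMismatchError):
            hamming_distance(FuzzySet(("a",), [0.5]), FuzzySet(("b",), [0.5]))

    @given(membership_vectors, st.data())
    @settings(max_examples=50, deadline=None)
    def test_metric_properties(self, mu_a, data):
        n = mu_a.size
        elems = st.floats(0.0, 1.0, allow_nan=False)
        mu_b = data.draw(hnp.arrays(float, n, elements=elems))
        mu_c = data.draw(hnp.arrays(float, n, elements=elems))
        support = tuple(range(n))
        a, b, c = (FuzzySet(support, m) for m in (mu_a, mu_b, mu_c))
        assert hamming_distance(a, b) == pytest.approx(hamming_distance(b, a))
        assert 0.0 <= hamming_distance(a, b) <= 1.0
        assert hamming_distance(a, c) <= (
            hamming_distance(a, b) + hamming_distance(b, c) + TOL
        )

    def test_identity_of_indiscernibles(self):
        a, b = fs(0.3, 0.5), fs(0.3, 0.5000001)
        assert hamming_distance(a, b) > 0.0


class TestSetOperations:
    def test_intersect_pointwise_min(self):
        out = intersect(fs(0.3, 0.9), fs(0.5, 0.4))
        np.testing.assert_allclose(out.memberships, [0.3, 0.4])

    def test_union_pointwise_max(self):
        out = union_of(fs(0.3, 0.9), fs(0.5, 0.4))
        np.testing.assert_allclose(out.memberships, [0.5, 0.9])

    def test_complement_involution(self):
        a = fs(0.25, 0.6, 1.0)
        np.testing.assert_allclose(
            complement(complement(a)).memberships, a.memberships
        )

    def test_zero_one_sets(self):
        np.testing.assert_array_equal(zero_set(["x1", "x2"]).memberships, [0, 0])
        np.testing.assert_array_equal(one_set(["x1"]).memberships, [1])
        support = ("x1", "x2", "x3")
        assert hamming_distance(zero_set(support), one_set(support)) == 1.0

    def test_empty_support_rejected(self):
        with pytest.raises(EmptyInputError):
            zero_set([])

    def test_binary_op_support_mismatch(self):
        with pytest.raises(SupportMismatchError):
            intersect(FuzzySet(("a",), [0.5]), FuzzySet(("b",), [0.5]))


class TestSimilarityMeasures:
    @pytest.mark.parametrize("measure", DISTANCE_MEASURES.values(),
                             ids=DISTANCE_MEASURES.keys())
    def test_self_similarity_is_one(self, measure):
        c = fs(0.2, 0.7, 0.5)
        assert measure(c, c) == pytest.approx(1.0, abs=TOL)

    @pytest.mark.parametrize("measure", DISTANCE_MEASURES.values(),
                             ids=DISTANCE_MEASURES.keys())
    def test_crisp_complement_scores_zero(self, measure):
        d = fs(1, 0, 1, 0)
        assert measure(d, complement(d)) == pytest.approx(0.0, abs=TOL)

    def test_hand_computed_example(self):
        # equals 1 - hamming = 1 - 0.2, verified by direct evaluation
        assert sim_bounds_sum(fs(0.2, 0.6), fs(0.4, 0.4)) == pytest.approx(0.8)

    def test_all_four_equal_one_minus_hamming(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            support = tuple(range(n))
            a = FuzzySet(support, rng.random(n))
            b = FuzzySet(support, rng.random(n))
            expected = 1.0 - hamming_distance(a, b)
            for measure in DISTANCE_MEASURES.values():
                assert abs(measure(a, b) - expected) <= TOL

    @given(membership_vectors, st.data())
    @settings(max_examples=50, deadline=None)
    def test_range_and_symmetry(self, mu_a, data):
        mu_b = data.draw(
            hnp.arrays(float, mu_a.size, elements=st.floats(0.0, 1.0, allow_nan=False))
        )
        support = tuple(range(mu_a.size))
        a, b = FuzzySet(support, mu_a), FuzzySet(support, mu_b)
        for measure in DISTANCE_MEASURES.values():
            s = measure(a, b)
            assert -TOL <= s <= 1.0 + TOL
            assert abs(s - measure(b, a)) <= TOL


class TestAxiomReport:
    @pytest.mark.parametrize("measure", DISTANCE_MEASURES.values(),
                             ids=DISTANCE_MEASURES.keys())
    def test_shipped_measures_pass(self, measure):
        report = axiom_report(measure, trials=300, seed=1)
        assert report.ok, report.summary()

    def test_constant_measure_fails_s2_s3(self):
        report = axiom_report(lambda a, b: 0.5, trials=100, seed=1)
        assert report.counts["S2"] > 0
        assert report.counts["S3"] > 0

    def test_asymmetric_measure_fails_s1(self):
        def lopsided(a, b):
            return float(a.memberships[0])

        report = axiom_report(lopsided, trials=100, seed=1)
        assert report.counts["S1"] > 0

    def test_weak_s3_mode(self):
        # hamming-complement similarity passes the weaker ordering-based S3
        report = axiom_report(
            sim_minmax, trials=100, seed=2, self_similarity_target=None
        )
        assert report.counts["S3"] == 0

    def test_non_callable_rejected(self):
        with pytest.raises(TypeError):
            axiom_report("not a measure", trials=10, seed=0)

    def test_report_is_deterministic(self):
        r1 = axiom_report(sim_containment, trials=50, seed=9)
        r2 = axiom_report(sim_containment, trials=50, seed=9)
        assert r1.counts == r2.counts

    def test_summary_mentions_all_axioms(self):
        text = axiom_report(sim_bounds_complement, trials=20, seed=0).summary()
        for axiom in ("S1", "S2", "S3", "S4"):
            assert axiom in text
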