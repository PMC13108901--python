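"""Beta classification, consistent errors, and circular-triad statistics."""

import itertools

import numpy as np
import pytest

from transrank.behavior_metrics import PairAccuracy
from transrank.error_structure import (
    Tournament,
    classify_beta,
    cohort_consistency_counts,
    consistent_error_pairs,
    count_circular_triads,
    error_consistency_score,
    fit_beta,
    majority_tournament,
    max_circular_triads,
    max_circular_triads_exhaustive,
    permutation_test_consistency,
    self_consistency,
)


def pair_acc_from(acc_map, n=8):
    base = {p: 1.0 for p in itertools.combinations(range(1, n + 1), 2)}
    base.update(acc_map)
    return PairAccuracy("s000", base, 10, n)


def transitive_tournament(order, n=8):
    """Tournament where the item later in `order` beats earlier ones."""
    position = {item: k for k, item in enumerate(order)}
    direction = {}
    for a, b in itertools.combinations(range(1, n + 1), 2):
        direction[(a, b)] = b if position[b] > position[a] else a
    return Tournament(n, direction)


def random_tournament(n, rng):
    direction = {
        (a, b): (b if rng.random() < 0.5 else a)
        for a, b in itertools.combinations(range(1, n + 1), 2)
    }
    return Tournament(n, direction)


class TestFitBeta:
    def test_recovers_unimodal_shape(self):
        rng = np.random.default_rng(1)
        fit = fit_beta(rng.beta(2.0, 2.0, size=500))
        assert fit.category == "unimodal"
        assert fit.alpha_hat == pytest.approx(2.0, rel=0.3)

    def test_recovers_bimodal_shape(self):
        rng = np.random.default_rng(2)
        fit = fit_beta(rng.beta(0.3, 0.3, size=500))
        assert fit.category == "bimodal"

    @pytest.mark.parametrize("a,b,expected", [
        (0.5, 0.5, "bimodal"),
        (2.0, 0.5, "high_accuracy"),
        (0.5, 2.0, "low_accuracy"),
        (3.0, 3.0, "unimodal"),
    ])
    def test_classification_rules(self, a, b, expected):
        assert classify_beta(a, b) == expected

    def test_degenerate_identical_values_flagged(self):
        fit = fit_beta([0.7] * 20)
        assert fit.degenerate

    def test_boundary_values_handled(self):
        fit = fit_beta([0.0] * 10 + [1.0] * 10)
        assert fit.category == "bimodal"


class TestConsistentErrors:
    def test_total_error_pair_included_at_strictest_threshold(self):
        pa = pair_acc_from({(3, 4): 0.0})
        assert (3, 4) in consistent_error_pairs(pa, 1.0)

    def test_partial_error_below_threshold_excluded(self):
        pa = pair_acc_from({(3, 4): 0.3})  # error proportion 0.7
        assert (3, 4) not in consistent_error_pairs(pa, 0.8)

    def test_all_correct_empty_at_every_threshold(self):
        pa = pair_acc_from({})
        for thr in (0.6, 0.7, 0.8, 0.9, 1.0):
            assert consistent_error_pairs(pa, thr) == set()

    def test_cohort_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        cohort = [
            pair_acc_from({
                p: rng.random()
                for p in itertools.combinations(range(1, 9), 2)
            })
            for _ in range(15)
        ]
        counts = cohort_consistency_counts(cohort)
        assert (np.diff(counts["count"]) <= 0).all()


class TestTournament:
    def test_all_correct_matrix_is_true_order(self):
        t = majority_tournament(pair_acc_from({}))
        assert t.is_true_order()
        assert len(t.direction) == 28

    def test_single_reversed_pair(self):
        t = majority_tournament(pair_acc_from({(3, 4): 0.0}))
        assert t.direction[(3, 4)] == 3
        assert all(w == hi for (lo, hi), w in t.direction.items()
                   if (lo, hi) != (3, 4))

    def test_tie_resolves_to_error_direction_and_flags(self):
        t = majority_tournament(pair_acc_from({(2, 6): 0.5}))
        assert t.direction[(2, 6)] == 2
        assert t.tie_pairs == ((2, 6),)


class TestCircularTriads:
    def test_transitive_tournament_has_none(self):
        t = transitive_tournament(list(range(1, 9)))
        assert count_circular_triads(t) == 0

    def test_rock_paper_scissors(self):
        t = Tournament(3, {(1, 2): 2, (2, 3): 3, (1, 3): 1})
        assert count_circular_triads(t) == 1
        assert count_circular_triads(t, method="enumerate") == 1

    def test_formula_equals_enumeration_on_random_tournaments(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            t = random_tournament(n, rng)
            assert count_circular_triads(t, "formula") == count_circular_triads(
                t, "enumerate"
            )

    def test_reversed_adjacent_edge_still_transitive(self):
        # swapping adjacent ranks 3,4 yields another strict order: no cycles
        t = majority_tournament(pair_acc_from({(3, 4): 0.0}))
        assert count_circular_triads(t) == 0


class TestMaxCircularTriads:
    @pytest.mark.parametrize("n,expected", [(3, 1), (5, 5), (8, 20)])
    def test_parity_closed_form(self, n, expected):
        assert max_circular_triads(n) == expected

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_exhaustive_search(self, n):
        assert max_circular_triads(n) == max_circular_triads_exhaustive(n)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            max_circular_triads(2)


class TestSelfConsistency:
    def test_true_order_is_correct_with_coefficient_one(self):
        res = self_consistency(transitive_tournament(list(range(1, 9))))
        assert res.coefficient == 1.0
        assert res.category == "correct"
        assert res.n_circular == 0

    def test_other_strict_order_is_consistent_incorrect(self):
        order = [2, 1] + list(range(3, 9))
        res = self_consistency(transitive_tournament(order))
        assert res.coefficient == 1.0
        assert res.category == "consistent_incorrect"

    def test_single_cycle_among_eight(self):
        # reversing one distance-2 edge of the true order creates exactly the
        # triad {1,2,3}: 1<2, 2<3, but 3<1
        direction = dict(transitive_tournament(list(range(1, 9))).direction)
        direction[(1, 3)] = 1
        res = self_consistency(Tournament(8, direction))
        assert res.n_circular == 1
        assert res.coefficient == pytest.approx(1 - 1 / 20)
        assert res.category == "inconsistent"

    def test_all_triads_denominator_option(self):
        direction = dict(transitive_tournament(list(range(1, 9))).direction)
        direction[(1, 3)] = 1
        res = self_consistency(Tournament(8, direction), nt=56)
        assert res.coefficient == pytest.approx(1 - 1 / 56)

    def test_coefficient_is_one_iff_acyclic(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = random_tournament(8, rng)
            res = self_consistency(t)
            assert 0.0 <= res.coefficient <= 1.0
            assert (res.coefficient == 1.0) == (count_circular_triads(t) == 0)


class TestErrorConsistencyScore:
    def test_single_total_error_pair(self):
        assert error_consistency_score(pair_acc_from({(3, 4): 0.0})) == 1.0

    def test_mean_over_error_pairs(self):
        pa = pair_acc_from({(3, 4): 0.1, (5, 6): 0.3})
        assert error_consistency_score(pa) == pytest.approx(0.8)

    def test_undefined_without_error_pairs(self):
        with pytest.raises(ValueError):
            error_consistency_score(pair_acc_from({}))


class TestPermutationTest:
    def _transitive_cohort(self, k=12):
        rng = np.random.default_rng(6)
        cohort = []
        for s in range(k):
            # high-confidence accuracies consistent with some strict order
            order = list(rng.permutation(range(1, 9)))
            pos = {p: i for i, p in enumerate(order)}
            acc = {
                (a, b): (0.9 if pos[b] > pos[a] else 0.1)
                for a, b in itertools.combinations(range(1, 9), 2)
            }
            cohort.append(PairAccuracy(f"s{s}", acc, 10, 8))
        return cohort

    def test_transitive_cohort_significant(self):
        res = permutation_test_consistency(
            self._transitive_cohort(), n_perm=1000, seed=7
        )
        assert res["observed"] == 1.0
        assert res["p"] < 0.01

    def test_p_in_unit_interval_and_deterministic(self):
        cohort = self._transitive_cohort(6)
        a = permutation_test_consistency(cohort, n_perm=200, seed=8)
        b = permutation_test_consistency(cohort, n_perm=200, seed=8)
        assert 0 < a["p"] <= 1
        assert a["p"] == b["p"]
        assert np.array_equal(a["null"], b["null"])

    def test_null_calibration_on_random_cohorts(self):
        """For cohorts with no consistency structure the p value is one draw
        from its own permutation distribution, so the false-positive rate at
        0.05 should stay near nominal over repeated cohorts."""
        rng = np.random.default_rng(9)
        n_reps, hits = 30, 0
        for rep in range(n_reps):
            cohort = [
                PairAccuracy(
                    f"s{s}",
                    {
                        p: float(rng.integers(0, 11)) / 10
                        for p in itertools.combinations(range(1, 9), 2)
                    },
                    10, 8,
                )
                for s in range(8)
            ]
            res = permutation_test_consistency(cohort, n_perm=100, seed=rep)
            hits += res["p"] <= 0.05
        # binomial(30, 0.05): P(hits > 6) < 1e-3
        assert hits <= 6
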