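"""Error-structure analyses: bimodality, consistent errors, and transitivity.

Three families of analysis distinguish a *constructive* ranker (who imposes
one idiosyncratic but internally consistent global order) from independent
noisy value estimates:

* **Beta-distribution classification** — fitting Beta(alpha, beta) to the
  cross-subject accuracy distribution of a pair. Both shapes below 1 means
  the mass sits at the extremes (bimodal: subjects are consistently right or
  consistently wrong), the signature of idiosyncratic-but-stable orders.
* **Consistent-error counts** — pairs whose error proportion exceeds a
  threshold, per subject.
* **Circular-triad statistics** — the majority direction of every pair forms
  a tournament; the number of 3-cycles Nd measures intransitivity, and the
  self-consistency coefficient 1 - Nd/NT (NT the parity-dependent maximum)
  is 1 exactly when the judgments admit a strict total order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_metrics import PairAccuracy

__all__ = [
    "Tournament",
    "BetaFit",
    "ConsistencyResult",
    "fit_beta",
    "consistent_error_pairs",
    "cohort_consistency_counts",
    "majority_tournament",
    "count_circular_triads",
    "max_circular_triads",
    "max_circular_triads_exhaustive",
    "self_consistency",
    "permutation_test_consistency",
    "error_consistency_score",
    "categorize_subjects",
]

STANDARD_THRESHOLDS = (0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class Tournament:
    """Complete majority-direction digraph over rank positions 1..n.

    ``direction`` maps each unordered pair (lo, hi) to the winning position.
    ``tie_pairs`` records pairs that sat exactly at 0.5 accuracy and were
    resolved by the documented rule (toward the error direction).
    """

    n_items: int
    direction: dict[tuple[int, int], int]
    tie_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        expected = set(itertools.combinations(range(1, self.n_items + 1), 2))
        if set(self.direction) != expected:
            raise ValueError("tournament is incomplete")
        for (a, b), w in self.direction.items():
            if w not in (a, b):
                raise ValueError(f"winner {w} not in pair ({a},{b})")

    def wins(self) -> np.ndarray:
        """Score sequence: number of wins per position (index 0 = position 1)."""
        w = np.zeros(self.n_items, dtype=int)
        for winner in self.direction.values():
            w[winner - 1] += 1
        return w

    def beats(self, a: int, b: int) -> bool:
        lo, hi = min(a, b), max(a, b)
        return self.direction[(lo, hi)] == a

    def is_true_order(self) -> bool:
        """Does every pair go to the truly higher position?"""
        return all(w == hi for (lo, hi), w in self.direction.items())


@dataclass
class BetaFit:
    """Beta-shape fit of an accuracy distribution with its category."""

    alpha_hat: float
    beta_hat: float
    category: str
    method: str = "mle"
    degenerate: bool = False


@dataclass
class ConsistencyResult:
    coefficient: float
    n_circular: int
    category: str  # correct | consistent_incorrect | inconsistent


def classify_beta(alpha_hat: float, beta_hat: float) -> str:
    """Category from the shape parameters relative to 1."""
    if alpha_hat > 1 and beta_hat > 1:
        return "unimodal"
    if alpha_hat > 1:
        return "high_accuracy"
    if beta_hat > 1:
        return "low_accuracy"
    return "bimodal"


def _shrink_boundaries(x: np.ndarray) -> np.ndarray:
    """Boundary correction x' = (x*(N-1) + 0.5)/N keeping values in (0,1)."""
    n = len(x)
    return (x * (n - 1) + 0.5) / n


def fit_beta(accuracies) -> BetaFit:
    """Fit Beta shapes to accuracy values in [0, 1] and classify the profile.

    Maximum likelihood with a method-of-moments fallback; exact 0/1 values
    are shrunk toward the interior first (MLE breaks at the boundary).
    """
    x = np.asarray(list(accuracies), dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 accuracy values")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    if x.min() <= 0.0 or x.max() >= 1.0:
        x = _shrink_boundaries(x)
    if np.ptp(x) == 0.0:
        # zero variance: shapes diverge along the mean direction; report a
        # very concentrated fit and flag it
        m = float(x.mean())
        c = 1e6
        a, b = m * c, (1 - m) * c
        return BetaFit(a, b, classify_beta(a, b), method="degenerate",
                       degenerate=True)
    try:
        a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        method = "mle"
        if not (np.isfinite(a) and np.isfinite(b)):
            raise RuntimeError
    except Exception:
        m, v = x.mean(), x.var()
        common = m * (1 - m) / v - 1
        a, b = m * common, (1 - m) * common
        method = "moments"
    return BetaFit(float(a), float(b), classify_beta(a, b), method=method)


def consistent_error_pairs(
    pair_acc: PairAccuracy, threshold: float
) -> set[tuple[int, int]]:
    """Pairs whose error proportion (1 - accuracy) reaches the threshold."""
    if threshold not in STANDARD_THRESHOLDS:
        warnings.warn(
            f"threshold {threshold} outside the standard levels "
            f"{STANDARD_THRESHOLDS}", stacklevel=2,
        )
    return {
        p for p, acc in pair_acc.acc.items() if (1.0 - acc) >= threshold - 1e-12
    }


def cohort_consistency_counts(
    pair_accs: list[PairAccuracy],
    thresholds=STANDARD_THRESHOLDS,
) -> pd.DataFrame:
    """Subjects with >= 1 consistent-error pair, per threshold.

    Counts are non-increasing in the threshold.
    """
    if not pair_accs:
        raise ValueError("empty cohort")
    rows = []
    for thr in thresholds:
        count = sum(
            1 for pa in pair_accs if len(consistent_error_pairs(pa, thr)) > 0
        )
        rows.append((thr, count, count / len(pair_accs)))
    return pd.DataFrame(rows, columns=["threshold", "count", "proportion"])


def majority_tournament(pair_acc: PairAccuracy) -> Tournament:
    """Direct each pair toward the majority-chosen item.

    Accuracy > 0.5 points to the truly higher position; accuracy exactly 0.5
    is resolved toward the error direction (the lower position), consistent
    with "accuracy > 50%" defining a correct pair, and flagged in
    ``tie_pairs``.
    """
    direction = {}
    ties = []
    for (lo, hi), acc in pair_acc.acc.items():
        if acc > 0.5:
            direction[(lo, hi)] = hi
        else:
            direction[(lo, hi)] = lo
            if acc == 0.5:
                ties.append((lo, hi))
    return Tournament(pair_acc.n_items, direction, tuple(ties))


def count_circular_triads(t: Tournament, method: str = "formula") -> int:
    """Number of 3-item directed cycles in a complete tournament.

    ``formula`` uses the score-sequence identity
    Nd = C(n,3) - sum_i C(wins_i, 2); ``enumerate`` checks all C(n,3) triads
    directly. The two agree on every complete tournament.
    """
    n = t.n_items
    if method == "formula":
        w = t.wins()
        return int(
            _comb3(n) - np.sum(w * (w - 1) // 2)
        )
    if method == "enumerate":
        count = 0
        for a, b, c in itertools.combinations(range(1, n + 1), 3):
            # a cycle among {a,b,c} exists iff no member beats both others
            if (
                max(
                    t.beats(a, b) + t.beats(a, c),
                    t.beats(b, a) + t.beats(b, c),
                    t.beats(c, a) + t.beats(c, b),
                )
                < 2
            ):
                count += 1
        return count
    raise ValueError(f"unknown method {method!r}")


def _comb3(n: int) -> int:
    return n * (n - 1) * (n - 2) // 6


def max_circular_triads(n: int) -> int:
    """Maximum circular triads in an n-item tournament (parity closed form).

    (n^3 - n)/24 for odd n, (n^3 - 4n)/24 for even n; equals 20 at n = 8.
    """
    if n < 3:
        raise ValueError("need at least 3 items")
    if n % 2 == 1:
        return (n**3 - n) // 24
    return (n**3 - 4 * n) // 24


def max_circular_triads_exhaustive(n: int) -> int:
    """Maximum over all 2^C(n,2) tournaments, by exhaustive search (small n)."""
    if n < 3:
        raise ValueError("need at least 3 items")
    pairs = list(itertools.combinations(range(1, n + 1), 2))
    best = 0
    for bits in range(2 ** len(pairs)):
        direction = {
            p: (p[1] if (bits >> k) & 1 else p[0])
            for k, p in enumerate(pairs)
        }
        t = Tournament(n, direction)
        best = max(best, count_circular_triads(t))
    return best


def self_consistency(t: Tournament, nt: int | None = None) -> ConsistencyResult:
    """Self-consistency coefficient 1 - Nd/NT with the triad category.

    NT defaults to the parity maximum (20 for 8 items); an alternative
    denominator such as the all-triads count (56 for 8 items) can be
    supplied via ``nt``. Category:
    ``correct`` if the tournament matches the true order; otherwise
    ``consistent_incorrect`` when Nd = 0 (a strict total order, just not the
    true one) and ``inconsistent`` when any cycle exists.
    """
    nd = count_circular_triads(t)
    if nt is None:
        nt = max_circular_triads(t.n_items)
    coefficient = 1.0 - nd / nt
    if nd > 0:
        category = "inconsistent"
    elif t.is_true_order():
        category = "correct"
    else:
        category = "consistent_incorrect"
    return ConsistencyResult(float(coefficient), int(nd), category)


def error_consistency_score(pair_acc: PairAccuracy) -> float:
    """Mean error proportion over the subject's majority-error pairs.

    A pair is a majority-error pair when its accuracy is <= 0.5 (ties count
    as errors). Undefined for subjects with no such pair (those belong to the
    correct-ranking group).
    """
    errs = [1.0 - acc for acc in pair_acc.acc.values() if acc <= 0.5]
    if not errs:
        raise ValueError("subject has no majority-error pairs")
    return float(np.mean(errs))


def categorize_subjects(
    pair_accs: list[PairAccuracy], nt: int | None = None
) -> pd.DataFrame:
    """Per-subject consistency table: coefficient, Nd, and triad category."""
    rows = []
    for pa in pair_accs:
        res = self_consistency(majority_tournament(pa), nt=nt)
        rows.append(
            (pa.subject_id, res.coefficient, res.n_circular, res.category)
        )
    return pd.DataFrame(
        rows, columns=["subject_id", "coefficient", "n_circular", "category"]
    )


def _coefficient_from_acc_vector(
    acc: np.ndarray, lo: np.ndarray, hi: np.ndarray, n_items: int, nt: int
) -> float:
    """Vectorized coefficient for one accuracy vector over fixed pair slots."""
    winners = np.where(acc > 0.5, hi, lo)
    wins = np.bincount(winners - 1, minlength=n_items)
    nd = _comb3(n_items) - int(np.sum(wins * (wins - 1) // 2))
    return 1.0 - nd / nt


def permutation_test_consistency(
    pair_accs: list[PairAccuracy],
    n_perm: int = 1000,
    seed=None,
    nt: int | None = None,
) -> dict:
    """Permutation test of group self-consistency against shuffled matrices.

    The observed statistic is the mean per-subject coefficient. Each null
    draw permutes every subject's pair accuracies across pair positions
    (preserving the multiset), rebuilds the majority tournaments, and
    recomputes the group mean. Add-one p value: (1 + #{null >= obs})/(1 + B).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n_items = pair_accs[0].n_items
    if nt is None:
        nt = max_circular_triads(n_items)
    pairs = list(itertools.combinations(range(1, n_items + 1), 2))
    lo = np.array([p[0] for p in pairs])
    hi = np.array([p[1] for p in pairs])

    acc_matrix = np.array(
        [[pa.acc[p] for p in pairs] for pa in pair_accs]
    )  # subjects x 28
    observed = float(
        np.mean(
            [
                _coefficient_from_acc_vector(row, lo, hi, n_items, nt)
                for row in acc_matrix
            ]
        )
    )
    null = np.empty(n_perm)
    for b in range(n_perm):
        coeffs = [
            _coefficient_from_acc_vector(
                row[rng.permutation(len(pairs))], lo, hi, n_items, nt
            )
            for row in acc_matrix
        ]
        null[b] = np.mean(coeffs)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return {"observed": observed, "null": null, "p": float(p)}
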