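"""Group-level behavioral signatures of transitive-inference performance.

The central object is the per-subject :class:`PairAccuracy`: for each of the
28 unordered pairs (8 items), the fraction of testing trials on which the
truly higher-ranked item was chosen. From it derive the classic ranking
signatures — the serial-position curve (accuracy by rank position, typically
U-shaped) and the symbolic-distance effect (accuracy rises with rank
distance) — plus the learned vs. non-learned pair comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import PairSet, RankOrder

__all__ = [
    "PairAccuracy",
    "pair_accuracy",
    "serial_position_curve",
    "distance_effect_slope",
    "learned_vs_nonlearned",
    "cohort_pair_accuracies",
    "filter_below_chance",
    "slope_summary",
]


@dataclass
class PairAccuracy:
    """Per-pair accuracy for one subject, keyed by unordered rank positions."""

    subject_id: str
    acc: dict[tuple[int, int], float]
    n_trials_per_pair: int
    n_items: int = 8

    def all_pairs(self) -> list[tuple[int, int]]:
        return list(itertools.combinations(range(1, self.n_items + 1), 2))

    def as_series(self) -> pd.Series:
        return pd.Series({p: self.acc.get(p, np.nan) for p in self.all_pairs()})

    @property
    def overall(self) -> float:
        return float(np.nanmean(list(self.acc.values())))


def pair_accuracy(choices: pd.DataFrame, rank: RankOrder) -> PairAccuracy:
    """Fraction of trials choosing the truly higher-ranked item, per pair.

    Pairs with no trials are left missing (absent from the map) rather than
    scored 0.
    """
    phases = set(choices["phase"].unique())
    if phases - {"testing"}:
        raise ValueError("pair accuracy is defined on testing-phase choices")
    r = rank.rank_of
    pos_i = choices["item_i"].map(r)
    pos_j = choices["item_j"].map(r)
    lo = np.minimum(pos_i, pos_j)
    hi = np.maximum(pos_i, pos_j)
    correct = (choices["chosen_item"].map(r) == hi).astype(float)
    df = pd.DataFrame({"lo": lo, "hi": hi, "correct": correct})
    grouped = df.groupby(["lo", "hi"])["correct"].agg(["mean", "size"])
    acc = {
        (int(a), int(b)): float(m)
        for (a, b), m in grouped["mean"].items()
    }
    n_per = int(grouped["size"].max()) if len(grouped) else 0
    subject = str(choices["subject_id"].iloc[0]) if len(choices) else ""
    return PairAccuracy(subject, acc, n_per, rank.n_items)


def serial_position_curve(pair_acc: PairAccuracy) -> dict[int, float]:
    """Mean accuracy per rank position over the n-1 pairs containing it."""
    curve = {}
    for pos in range(1, pair_acc.n_items + 1):
        vals = [v for p, v in pair_acc.acc.items() if pos in p]
        curve[pos] = float(np.mean(vals)) if vals else np.nan
    return curve


def distance_effect_slope(pair_acc: PairAccuracy) -> float:
    """OLS slope of pair accuracy on rank distance (1..n-1), one subject."""
    pairs = list(pair_acc.acc)
    dist = np.array([b - a for a, b in pairs], dtype=float)
    accs = np.array([pair_acc.acc[p] for p in pairs], dtype=float)
    if len(np.unique(dist)) < 2:
        raise ValueError("slope undefined: all pairs share one rank distance")
    slope, _ = np.polyfit(dist, accs, 1)
    return float(slope)


def learned_vs_nonlearned(
    pair_acc: PairAccuracy, pair_set: PairSet
) -> tuple[float, float]:
    """(mean accuracy over learned pairs, mean over the remaining pairs)."""
    learned = [v for p, v in pair_acc.acc.items() if p in pair_set]
    other = [v for p, v in pair_acc.acc.items() if p not in pair_set]
    return float(np.mean(learned)), float(np.mean(other))


def cohort_pair_accuracies(
    choices: pd.DataFrame, ranks: dict[str, RankOrder]
) -> list[PairAccuracy]:
    """Per-subject pair accuracies for a cohort choice table."""
    out = []
    for subject_id, grp in choices.groupby("subject_id", sort=True):
        out.append(pair_accuracy(grp, ranks[subject_id]))
    return out


def filter_below_chance(
    pair_accs: list[PairAccuracy], threshold: float = 0.5
) -> tuple[list[PairAccuracy], list[str]]:
    """Drop subjects whose overall testing accuracy is below chance.

    Returns (kept, excluded subject ids); applied before all cohort analyses.
    """
    kept, dropped = [], []
    for pa in pair_accs:
        if pa.overall < threshold:
            dropped.append(pa.subject_id)
        else:
            kept.append(pa)
    return kept, dropped


def slope_summary(pair_accs: list[PairAccuracy]) -> dict:
    """Mean distance-effect slope with a one-sample t test against zero."""
    slopes = np.array([distance_effect_slope(pa) for pa in pair_accs])
    t, p = stats.ttest_1samp(slopes, 0.0)
    return {
        "mean_slope": float(np.mean(slopes)),
        "t": float(t),
        "p": float(p),
        "n": len(slopes),
    }
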