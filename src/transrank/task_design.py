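"""Experimental structure of the few-shot transitive-inference task.

Eight items carry a strict latent ranking (rank 1 = lowest). Learners are
exposed to a fixed set of eight rank-position pairs, each shown once per
learning block, and are then tested on all C(8,2) = 28 pairwise comparisons,
once per testing block, without feedback. A sequential single-item stream is
used for the MEG-style task, where each item is judged against the previous
one.

Schedules are expressed in rank positions so that one design serves every
subject; a :class:`RankOrder` maps positions to that subject's item labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ITEMS",
    "DEFAULT_PAIR_SET",
    "RankOrder",
    "PairSet",
    "TrialSchedule",
    "make_rank_order",
    "signed_rank_distance",
    "build_learning_schedule",
    "build_test_schedule",
    "build_meg_sequence",
]

#: Item labels used throughout the default design.
DEFAULT_ITEMS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

SCHEDULE_COLUMNS = ["phase", "block", "trial", "pos_a", "pos_b"]


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class RankOrder:
    """A bijection between item labels and ranks 1..n (1 = lowest).

    Parameters
    ----------
    items
        Item labels ordered from rank 1 to rank n.
    """

    items: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.items)) != len(self.items):
            raise ValueError("item labels must be distinct")
        if len(self.items) < 1:
            raise ValueError("need at least one item")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def rank_of(self) -> dict[str, int]:
        """Map item label -> rank in 1..n."""
        return {item: r + 1 for r, item in enumerate(self.items)}

    def item_at(self, rank: int) -> str:
        """Inverse lookup: rank (1-based) -> item label."""
        if not 1 <= rank <= self.n_items:
            raise ValueError(f"rank {rank} outside 1..{self.n_items}")
        return self.items[rank - 1]

    def ranks(self) -> np.ndarray:
        """Rank vector aligned with ``items`` (always 1..n here)."""
        return np.arange(1, self.n_items + 1)


@dataclass(frozen=True)
class PairSet:
    """An unordered set of rank-position pairs used in the learning phase."""

    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("pair set must not be empty")
        norm = frozenset(tuple(sorted(p)) for p in self.pairs)
        object.__setattr__(self, "pairs", norm)
        for a, b in norm:
            if a == b:
                raise ValueError(f"degenerate pair ({a},{b})")

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __len__(self):
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(sorted(pair)) in self.pairs

    def positions(self) -> set[int]:
        return {p for pair in self.pairs for p in pair}


#: The fixed learned-pair set, identical across subjects:
#: (A,F),(B,C),(B,E),(C,G),(D,F),(D,G),(E,H),(A,H) in rank positions.
DEFAULT_PAIR_SET = PairSet(
    frozenset({(1, 6), (2, 3), (2, 5), (3, 7), (4, 6), (4, 7), (5, 8), (1, 8)})
)


@dataclass
class TrialSchedule:
    """Ordered trial list for one phase (or several concatenated phases)."""

    trials: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SCHEDULE_COLUMNS)
    )

    def __post_init__(self):
        missing = set(SCHEDULE_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"schedule missing columns: {sorted(missing)}")

    def __len__(self):
        return len(self.trials)

    @property
    def phases(self) -> list[str]:
        return list(pd.unique(self.trials["phase"]))

    def pairs(self) -> list[tuple[int, int]]:
        """Presented pairs in trial order (unordered position tuples)."""
        rows = self.trials.dropna(subset=["pos_b"])
        return [
            tuple(sorted((int(a), int(b))))
            for a, b in zip(rows["pos_a"], rows["pos_b"])
        ]


def make_rank_order(item_labels, seed=None) -> RankOrder:
    """Assign ranks 1..n to items, shuffled when a seed is given.

    Without a seed the given order is kept (identity assignment); with a
    seed the assignment is a deterministic permutation of the labels.
    """
    labels = list(item_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("item labels must be distinct")
    if seed is not None:
        rng = _as_rng(seed)
        labels = [labels[i] for i in rng.permutation(len(labels))]
    return RankOrder(tuple(labels))


def signed_rank_distance(m: int, n: int, n_items: int = 8) -> float:
    """Normalized signed distance (m - n)/(n_items - 1) between rank positions.

    Antisymmetric: ``signed_rank_distance(m, n) == -signed_rank_distance(n, m)``.
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if not (1 <= m <= n_items and 1 <= n <= n_items):
        raise ValueError(f"ranks must lie in 1..{n_items}")
    return (m - n) / (n_items - 1)


def build_learning_schedule(
    pair_set: PairSet, n_blocks: int = 4, seed=None
) -> TrialSchedule:
    """Learning-phase schedule: each pair exactly once per block, order shuffled.

    The default design is 4 blocks x 8 pairs = 32 trials, i.e. four few-shot
    presentations per pair.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if len(pair_set) == 0:
        raise ValueError("empty pair set")
    rng = _as_rng(seed)
    pairs = sorted(pair_set.pairs)
    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        for idx in rng.permutation(len(pairs)):
            a, b = pairs[idx]
            rows.append(("learning", block, trial, a, b))
            trial += 1
    return TrialSchedule(pd.DataFrame(rows, columns=SCHEDULE_COLUMNS))


def build_test_schedule(
    n_items: int = 8, n_blocks: int = 10, seed=None
) -> TrialSchedule:
    """Testing-phase schedule: all C(n,2) pairs once per block, order shuffled."""
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = _as_rng(seed)
    pairs = list(itertools.combinations(range(1, n_items + 1), 2))
    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        for idx in rng.permutation(len(pairs)):
            a, b = pairs[idx]
            rows.append(("testing", block, trial, a, b))
            trial += 1
    return TrialSchedule(pd.DataFrame(rows, columns=SCHEDULE_COLUMNS))


def build_meg_sequence(
    n_items: int = 8,
    n_blocks: int = 5,
    images_per_block: int = 81,
    seed=None,
    phase: str = "meg_post",
) -> TrialSchedule:
    """Sequential single-item stream for the MEG-style judgment task.

    Shuffled n-item sequences are concatenated (padding with extra shuffled
    sequences as needed) and sliced into blocks of ``images_per_block``.
    Each item after the first within a block yields one pairwise judgment
    against its predecessor, so a block of k images yields k - 1 judgments.

    Rows carry ``pos_a`` = current item position and ``pos_b`` = NaN; the
    judged pair at trial t is (pos_a[t-1], pos_a[t]) within a block.
    """
    if images_per_block < 2:
        raise ValueError("images_per_block must be >= 2")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = _as_rng(seed)
    needed = n_blocks * images_per_block
    stream: list[int] = []
    while len(stream) < needed:
        stream.extend(int(p) for p in rng.permutation(n_items) + 1)
    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        chunk = stream[(block - 1) * images_per_block : block * images_per_block]
        for pos in chunk:
            rows.append((phase, block, trial, pos, np.nan))
            trial += 1
    return TrialSchedule(pd.DataFrame(rows, columns=SCHEDULE_COLUMNS))


def meg_judged_pairs(schedule: TrialSchedule) -> pd.DataFrame:
    """Consecutive-item pairs judged in a single-item stream, per block."""
    out = []
    for block, grp in schedule.trials.groupby("block", sort=True):
        pos = grp["pos_a"].to_numpy()
        for prev, cur in zip(pos[:-1], pos[1:]):
            out.append((block, int(prev), int(cur)))
    return pd.DataFrame(out, columns=["block", "pos_prev", "pos_cur"])
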