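"""Global subjective-ranking reconstruction from pairwise judgments.

HodgeRank recovers a global score vector s minimizing
sum_(i,j) (s_i - s_j - Yhat_ij)^2, where Yhat_ij is the trial-averaged
+/-1-coded preference for item i over j. On a complete comparison graph the
solution is simply the row mean of the preference matrix; incomplete graphs
are handled through the graph-Laplacian pseudoinverse. Sorting items by
score yields the subject's reconstructed global ranking, and Kendall's tau
between subjects' rankings quantifies how idiosyncratic the cohort is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import kendalltau

from .task_design import RankOrder

__all__ = [
    "PreferenceMatrix",
    "SubjectiveRanking",
    "preference_matrix",
    "hodgerank",
    "kendall_tau",
    "inter_subject_similarity",
]


@dataclass
class PreferenceMatrix:
    """Antisymmetric trial-averaged preferences over rank positions.

    ``y[(i, j)]`` is the mean of +/-1 codes (+1 when position i was chosen
    over j); only one orientation per pair is stored, the other is implied by
    antisymmetry. Pairs never compared are simply absent.
    """

    n_items: int
    y: dict[tuple[int, int], float]

    def value(self, i: int, j: int) -> float:
        if (i, j) in self.y:
            return self.y[(i, j)]
        if (j, i) in self.y:
            return -self.y[(j, i)]
        raise KeyError(f"pair ({i},{j}) never compared")

    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(p)) for p in self.y]


@dataclass
class SubjectiveRanking:
    """Centered HodgeRank scores and the order they induce."""

    subject_id: str
    scores: dict[str, float]
    order: RankOrder
    tied: bool = False

    def rank_of(self) -> dict[str, int]:
        return self.order.rank_of


def preference_matrix(
    choices: pd.DataFrame, rank: RankOrder
) -> PreferenceMatrix:
    """Trial-averaged +/-1 preference per pair, in rank-position space."""
    phases = set(choices["phase"].unique())
    if phases - {"testing"}:
        raise ValueError("preference matrix is built from testing-phase rows")
    r = rank.rank_of
    pos_i = choices["item_i"].map(r).to_numpy()
    pos_j = choices["item_j"].map(r).to_numpy()
    chosen = choices["chosen_item"].map(r).to_numpy()
    lo = np.minimum(pos_i, pos_j)
    hi = np.maximum(pos_i, pos_j)
    code = np.where(chosen == hi, 1.0, -1.0)  # +1 = higher position chosen
    df = pd.DataFrame({"lo": lo, "hi": hi, "code": code})
    y = {
        (int(b), int(a)): float(m)  # key (hi, lo): mean preference for hi
        for (a, b), m in df.groupby(["lo", "hi"])["code"].mean().items()
    }
    return PreferenceMatrix(rank.n_items, y)


def hodgerank(
    y: PreferenceMatrix, rank: RankOrder, subject_id: str = ""
) -> SubjectiveRanking:
    """Least-squares global scores from pairwise preference differences.

    Solves L s = div(y) with the comparison-graph Laplacian L, via
    pseudoinverse; scores are centered to sum 0. On a complete graph this
    reduces to s_i = mean_j y(i, j). Ties in the resulting scores are broken
    by item-label order and flagged.
    """
    n = y.n_items
    adj = np.zeros((n, n))
    div = np.zeros(n)
    for (i, j) in y.edges():
        adj[i - 1, j - 1] = adj[j - 1, i - 1] = 1
        div[i - 1] += y.value(i, j)
        div[j - 1] += y.value(j, i)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [
            [rank.item_at(k + 1) for k in range(n) if labels[k] == c]
            for c in range(n_comp)
        ]
        raise ValueError(f"comparison graph disconnected: components {comps}")
    lap = np.diag(adj.sum(axis=1)) - adj
    s = np.linalg.pinv(lap) @ div
    s = s - s.mean()

    items = [rank.item_at(k + 1) for k in range(n)]
    scores = {item: float(s[k]) for k, item in enumerate(items)}
    tied = len(np.unique(np.round(s, 12))) < n
    # sort ascending score; ties broken by label order
    ordered = tuple(sorted(items, key=lambda it: (scores[it], it)))
    return SubjectiveRanking(subject_id, scores, RankOrder(ordered), tied)


def position_ranking(
    ranking: SubjectiveRanking, truth: RankOrder
) -> RankOrder:
    """Re-express a subjective ranking over true rank positions.

    Subjects learn differently shuffled item sequences, so rankings are only
    comparable across subjects after mapping each item to its true rank
    position: positions (labelled ``p1``..``pn``) are ordered by the score of
    the item holding them, making the ground truth the identity permutation
    for every subject.
    """
    r = truth.rank_of
    positions = sorted(
        truth.items, key=lambda it: (ranking.scores[it], r[it])
    )
    return RankOrder(tuple(f"p{r[it]}" for it in positions))


def kendall_tau(a: RankOrder, b: RankOrder) -> float:
    """Kendall's tau between two rankings of the same item set."""
    if set(a.items) != set(b.items):
        raise ValueError("rankings cover different item sets")
    items = sorted(a.items)
    ra = [a.rank_of[it] for it in items]
    rb = [b.rank_of[it] for it in items]
    tau, _ = kendalltau(ra, rb)
    return float(tau)


def inter_subject_similarity(rankings: list[SubjectiveRanking]) -> pd.DataFrame:
    """All C(k,2) pairwise Kendall tau values across subjects."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    rows = []
    for ra, rb in itertools.combinations(rankings, 2):
        rows.append(
            (ra.subject_id, rb.subject_id, kendall_tau(ra.order, rb.order))
        )
    return pd.DataFrame(rows, columns=["subject_a", "subject_b", "tau"])
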