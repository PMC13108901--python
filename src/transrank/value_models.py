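"""Value-learning and choice models for pairwise ranking judgments.

Five agents are implemented:

``qlearning``
    Delta-rule update of scalar item values toward the presented normalized
    rank difference, with a logistic (softmax) choice policy at test.
``betaq``
    Each item's value is a Beta(U, L) distribution; shape parameters are
    adjusted by the mismatch between the presented difference and the current
    expected-value difference. Choices sample from the two Beta distributions.
``betasort``
    Beta-Q plus updates to the *non-presented* items: items whose expected
    value lies between the presented pair's sharpen in place; items outside
    the presented interval are shifted.
``distance_avg``
    Non-learning baseline: an item's value is the mean signed rank distance
    over the learned pairs containing it (raw rank units).
``correct_rank``
    Oracle baseline: an item's value is its true rank.

All updates read pre-update values on their right-hand sides and are applied
atomically per trial. Learning happens only in the learning phase; choice
policies act on the frozen end-of-learning state (no feedback at test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .task_design import RankOrder, PairSet, TrialSchedule, signed_rank_distance

__all__ = [
    "MODEL_IDS",
    "ValueState",
    "BetaState",
    "AgentParams",
    "qlearning_update",
    "softmax_choice_prob",
    "betaq_update",
    "betasort_update",
    "beta_choice_prob",
    "distance_average_values",
    "correct_ranking_values",
    "end_of_learning_state",
    "pair_choice_probs",
    "simulate_agent",
]

MODEL_IDS = ("qlearning", "betaq", "betasort", "distance_avg", "correct_rank")

#: Shape parameters are clamped at this floor after every Beta update; the
#: Beta density requires strictly positive shapes and long runs can otherwise
#: drive them non-positive.
SHAPE_EPS = 1e-6

CHOICE_COLUMNS = [
    "subject_id",
    "phase",
    "block",
    "trial",
    "item_i",
    "item_j",
    "chosen_item",
    "is_correct",
]


@dataclass
class ValueState:
    """Scalar value per rank position (index 0 holds position 1)."""

    q: np.ndarray

    @classmethod
    def zeros(cls, n_items: int) -> "ValueState":
        return cls(np.zeros(n_items))

    def value(self, pos: int) -> float:
        return float(self.q[pos - 1])


@dataclass
class BetaState:
    """Beta(U, L) shape parameters per rank position."""

    u: np.ndarray
    l: np.ndarray

    @classmethod
    def uniform(cls, n_items: int) -> "BetaState":
        """Beta(1,1) for every item — the uninformative prior."""
        return cls(np.ones(n_items), np.ones(n_items))

    @property
    def v(self) -> np.ndarray:
        """Expected values V = U/(U+L)."""
        return self.u / (self.u + self.l)

    def check(self) -> None:
        if np.any(self.u <= 0) or np.any(self.l <= 0):
            raise ValueError("Beta shape parameters must be positive")


@dataclass
class AgentParams:
    """Model identity plus its free parameters.

    ``alpha`` is the learning rate / boundary-bias factor in (0, 1] (unused
    by distance_avg and correct_rank); ``gamma`` is the softmax inverse
    temperature >= 0 (unused by the Beta models, whose sampling policy has no
    temperature).
    """

    model: str
    alpha: float = 0.5
    gamma: float = 1.0

    def __post_init__(self):
        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model in ("qlearning", "betaq", "betasort") and not (
            0 < self.alpha <= 1
        ):
            raise ValueError("alpha must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


# ---------------------------------------------------------------------------
# learning updates
# ---------------------------------------------------------------------------


def qlearning_update(
    state: ValueState, pair: tuple[int, int], alpha: float, n_items: int
) -> ValueState:
    """Delta-rule update of both presented items toward the shown difference.

    Q_m += alpha * [D(m,n) - (Q_m - Q_n)] / 2 and symmetrically for n, both
    reading pre-update values. The update is antisymmetric, so the sum of all
    values is conserved.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    m, n = pair
    if m == n:
        raise ValueError("pair items must be distinct")
    q = state.q.copy()
    d = signed_rank_distance(m, n, n_items)
    qm, qn = q[m - 1], q[n - 1]
    q[m - 1] = qm + alpha * (d - (qm - qn)) / 2.0
    q[n - 1] = qn + alpha * (-d - (qn - qm)) / 2.0
    return ValueState(q)


def softmax_choice_prob(qi: float, qj: float, gamma: float) -> float:
    """P(choose i over j) = logistic(gamma * (Q_i - Q_j))."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(special.expit(gamma * (qi - qj)))


def _betaq_pair_increments(state: BetaState, m: int, n: int, alpha: float, n_items: int):
    """Increments for the presented pair (m truly above n), pre-update V."""
    v = state.v
    d_mn = signed_rank_distance(m, n, n_items)
    dv_mn = v[m - 1] - v[n - 1]
    up = d_mn - dv_mn          # D(m,n) - dV(m,n)
    down = -d_mn + dv_mn       # D(n,m) - dV(n,m) = -up
    du = np.zeros(len(v))
    dl = np.zeros(len(v))
    du[m - 1] += up
    dl[m - 1] += alpha * down
    du[n - 1] += alpha * down
    dl[n - 1] += up
    return du, dl, dv_mn


def betaq_update(
    state: BetaState, pair: tuple[int, int], alpha: float, n_items: int
) -> BetaState:
    """Beta-Q update of the presented pair's shape parameters.

    The pair is oriented by true rank (m = higher position). The upper shape
    of m and lower shape of n grow by the full prediction error
    D(m,n) - dV(m,n); the opposing shapes move by alpha times the mirrored
    error. Results are clamped to stay positive.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    state.check()
    m, n = max(pair), min(pair)
    du, dl, _ = _betaq_pair_increments(state, m, n, alpha, n_items)
    u = np.maximum(state.u + du, SHAPE_EPS)
    l = np.maximum(state.l + dl, SHAPE_EPS)
    return BetaState(u, l)


def betasort_update(
    state: BetaState, pair: tuple[int, int], alpha: float, n_items: int
) -> BetaState:
    """Betasort update: Beta-Q on the pair plus non-presented-item updates.

    With all case assignments read from pre-update expected values V, every
    non-presented item o falls in exactly one case:

    * V_n <= V_o <= V_m — confirmation: U_o += V_o, L_o += 1 - V_o (mean kept,
      concentration raised). Ties with V_n or V_m are treated as this case.
    * V_o < V_n — U_o += dV(m,n), L_o += alpha * dV(m,n).
    * V_o > V_m — U_o += alpha * dV(m,n), L_o += dV(m,n).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    state.check()
    m, n = max(pair), min(pair)
    v = state.v
    du, dl, dv_mn = _betaq_pair_increments(state, m, n, alpha, n_items)
    vm, vn = v[m - 1], v[n - 1]
    lo, hi = min(vn, vm), max(vn, vm)
    for o in range(n_items):
        if o in (m - 1, n - 1):
            continue
        vo = v[o]
        if lo <= vo <= hi:
            du[o] += vo
            dl[o] += 1.0 - vo
        elif vo < lo:
            du[o] += dv_mn
            dl[o] += alpha * dv_mn
        else:
            du[o] += alpha * dv_mn
            dl[o] += dv_mn
    u = np.maximum(state.u + du, SHAPE_EPS)
    l = np.maximum(state.l + dl, SHAPE_EPS)
    return BetaState(u, l)


# ---------------------------------------------------------------------------
# choice policies
# ---------------------------------------------------------------------------


def _prob_beta_greater(ui: float, li: float, uj: float, lj: float) -> float:
    """P(X > Y) for independent X ~ Beta(ui, li), Y ~ Beta(uj, lj).

    Evaluated as the integral of pdf_X(x) * cdf_Y(x) by adaptive quadrature;
    endpoint singularities (shapes < 1) are integrable and handled by quad.
    """

    def integrand(x):
        return stats.beta.pdf(x, ui, li) * special.betainc(uj, lj, x)

    with warnings.catch_warnings():
        # near-symmetric integrands trip quad's roundoff heuristic even
        # though the value is accurate; verified against closed forms
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return float(min(max(val, 0.0), 1.0))


def beta_choice_prob(
    state: BetaState,
    i: int,
    j: int,
    method: str = "integral",
    n_samples: int = 10_000,
    seed=None,
) -> float:
    """P(choose item at position i over position j) under the Beta policy.

    ``integral`` evaluates P(X_i > X_j) deterministically; ``sampling`` draws
    ``n_samples`` independent value pairs and compares them.
    """
    state.check()
    ui, li = state.u[i - 1], state.l[i - 1]
    uj, lj = state.u[j - 1], state.l[j - 1]
    if method == "integral":
        return _prob_beta_greater(ui, li, uj, lj)
    if method == "sampling":
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        xi = rng.beta(ui, li, size=n_samples)
        xj = rng.beta(uj, lj, size=n_samples)
        return float(np.mean(xi > xj))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# non-learning baselines
# ---------------------------------------------------------------------------


def distance_average_values(
    pair_set: PairSet, rank: RankOrder, normalized: bool = False
) -> ValueState:
    """Mean signed rank distance per item over its learned pairs.

    By default distances are in raw rank units (e.g. an item whose two pairs
    give +3 and +7 has value +5); set ``normalized=True`` to divide by
    n_items - 1, matching the learning models' distance convention.
    """
    n = rank.n_items
    scale = (n - 1) if normalized else 1
    q = np.zeros(n)
    for pos in range(1, n + 1):
        ds = [
            (a - b if a == pos else b - a) / scale
            for a, b in pair_set
            if pos in (a, b)
        ]
        if not ds:
            raise ValueError(f"rank position {pos} appears in no learned pair")
        q[pos - 1] = float(np.mean(ds))
    return ValueState(q)


def correct_ranking_values(rank: RankOrder) -> ValueState:
    """Oracle values: Q_i equals the item's true rank position."""
    return ValueState(rank.ranks().astype(float))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def end_of_learning_state(
    params: AgentParams,
    learn_sched: TrialSchedule,
    n_items: int,
    pair_set: PairSet | None = None,
    rank: RankOrder | None = None,
):
    """Replay the learning schedule and return the frozen pre-test state.

    Deterministic: no choices occur during learning, so the state is a pure
    function of the model, alpha, and the trial order.
    """
    model = params.model
    if model == "qlearning":
        state = ValueState.zeros(n_items)
        for pair in learn_sched.pairs():
            state = qlearning_update(state, pair, params.alpha, n_items)
        return state
    if model in ("betaq", "betasort"):
        update = betaq_update if model == "betaq" else betasort_update
        state = BetaState.uniform(n_items)
        for pair in learn_sched.pairs():
            state = update(state, pair, params.alpha, n_items)
        return state
    if model == "distance_avg":
        if pair_set is None:
            pair_set = PairSet(frozenset(learn_sched.pairs()))
        if rank is None:
            rank = RankOrder(tuple(f"r{i}" for i in range(1, n_items + 1)))
        return distance_average_values(pair_set, rank)
    if model == "correct_rank":
        if rank is None:
            rank = RankOrder(tuple(f"r{i}" for i in range(1, n_items + 1)))
        return correct_ranking_values(rank)
    raise ValueError(f"unknown model {model!r}")


def pair_choice_probs(
    params: AgentParams, state, pairs: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """P(choose the higher-positioned item) per unordered pair, frozen state.

    For the Beta models the deterministic integral of the sampling policy is
    used, cached per unique pair.
    """
    probs: dict[tuple[int, int], float] = {}
    for pair in set(tuple(sorted(p)) for p in pairs):
        lo, hi = pair
        if params.model in ("betaq", "betasort"):
            p = beta_choice_prob(state, hi, lo, method="integral")
        else:
            p = softmax_choice_prob(state.value(hi), state.value(lo), params.gamma)
        probs[pair] = p
    return probs


def simulate_agent(
    params: AgentParams,
    rank: RankOrder,
    learn_sched: TrialSchedule,
    test_sched: TrialSchedule,
    seed=None,
    subject_id: str = "s000",
) -> pd.DataFrame:
    """Simulate one subject: silent learning pass, then stochastic test choices.

    Returns a choice table with columns
    ``subject_id, phase, block, trial, item_i, item_j, chosen_item, is_correct``
    where correctness means choosing the truly higher-ranked item. The state
    is frozen after learning; no updating occurs at test (no feedback).
    """
    rng = np.random.default_rng(seed)
    n_items = rank.n_items
    state = end_of_learning_state(params, learn_sched, n_items, rank=rank)
    test_pairs = test_sched.pairs()
    probs = pair_choice_probs(params, state, test_pairs)

    rows = []
    tdf = test_sched.trials
    u = rng.random(len(tdf))
    for k, (_, row) in enumerate(tdf.iterrows()):
        a, b = int(row["pos_a"]), int(row["pos_b"])
        lo, hi = min(a, b), max(a, b)
        p_hi = probs[(lo, hi)]
        chosen_pos = hi if u[k] < p_hi else lo
        rows.append(
            (
                subject_id,
                row["phase"],
                int(row["block"]),
                int(row["trial"]),
                rank.item_at(a),
                rank.item_at(b),
                rank.item_at(chosen_pos),
                int(chosen_pos == hi),
            )
        )
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)
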