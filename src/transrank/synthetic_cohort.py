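"""Synthetic cohorts with the statistical structure the analyses assume.

Two generators cover the study's two data modalities:

* :func:`generate_behavioral_cohort` — per-subject learning/testing choice
  tables from a configurable mix of agents. Besides the five value models,
  a **constructive** agent holds an idiosyncratic but internally consistent
  subjective ranking (a noisy permutation of the truth) and answers every
  test pair from it, producing the human-like signature: stable, transitive,
  subject-specific errors.
* :func:`generate_meg_cohort` — sensor-level item patterns per subject and
  phase. Model RDM structure is embedded by factorizing the RDM's induced
  correlation structure into item coordinates (so 1 - Pearson between the
  resulting patterns reproduces the RDM), mixed into sensors through a
  random orthogonal map per subject, gated by a boxcar time window, plus
  i.i.d. Gaussian sensor noise. The subject's own subjective-rank RDM
  appears only in the post-learning phase, inside its configured window.

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning, so cohorts are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .task_design import (
    DEFAULT_ITEMS,
    DEFAULT_PAIR_SET,
    PairSet,
    RankOrder,
    TrialSchedule,
    build_learning_schedule,
    build_meg_sequence,
    build_test_schedule,
    make_rank_order,
)
from .value_models import CHOICE_COLUMNS, AgentParams, simulate_agent
from .rsa import RDM, NeuralPatterns, feature_rdm, model_rdm_from_ranks

__all__ = [
    "CohortConfig",
    "BehavioralCohort",
    "MegCohort",
    "sample_subjective_ranking",
    "constructive_agent_choices",
    "generate_behavioral_cohort",
    "generate_meg_cohort",
]

AGENT_KINDS = (
    "qlearning",
    "betaq",
    "betasort",
    "distance_avg",
    "correct_rank",
    "constructive",
)


@dataclass
class CohortConfig:
    """Study-condition defaults for synthetic cohorts.

    The behavioral design mirrors the experiment: 8 items, the fixed 8-pair
    learning set shown once per block over 4 blocks, and 10 testing blocks of
    all 28 pairs. The default agent mix is constructive-dominant with a
    veridical minority, the regime the human cohort exhibited.
    """

    n_subjects: int = 77
    items: tuple[str, ...] = DEFAULT_ITEMS
    pair_set: PairSet = field(default_factory=lambda: DEFAULT_PAIR_SET)
    n_learning_blocks: int = 4
    n_testing_blocks: int = 10
    agent_mix: dict = field(
        default_factory=lambda: {"constructive": 0.9, "correct_rank": 0.1}
    )
    alpha_range: tuple[float, float] = (0.2, 0.6)
    gamma_range: tuple[float, float] = (3.0, 8.0)
    constructive_gamma: float = 8.0
    #: SD (rank units) of the Gaussian perturbation defining subjective orders.
    dispersion: float = 1.2
    master_seed: int = 0
    # --- MEG-like geometry ---
    n_sensors: int = 64
    sfreq: float = 100.0
    tmin: float = -0.2
    tmax: float = 1.2
    n_meg_blocks: int = 5
    images_per_block: int = 81
    noise_sd: float = 1.0
    effect_amplitude: float = 1.0
    effect_windows: dict = field(
        default_factory=lambda: {
            "lowlevel": (0.10, 0.30),
            "size": (0.20, 0.48),
            "subjective": (0.685, 0.775),
        }
    )

    def __post_init__(self):
        total = sum(self.agent_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"agent mix proportions sum to {total}, not 1")
        unknown = set(self.agent_mix) - set(AGENT_KINDS)
        if unknown:
            raise ValueError(f"unknown agent kinds {sorted(unknown)}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sfreq)) + 1
        return self.tmin + np.arange(n) / self.sfreq


@dataclass
class BehavioralCohort:
    choices: pd.DataFrame
    ranks: dict[str, RankOrder]
    learn_scheds: dict[str, TrialSchedule]
    test_scheds: dict[str, TrialSchedule]
    manifest: list[dict]


@dataclass
class MegCohort:
    patterns: NeuralPatterns
    lowlevel_rdm: RDM
    size_rdm: RDM
    subjective_rdms: dict[str, RDM]
    sequences: pd.DataFrame
    manifest: list[dict]


def _spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def sample_subjective_ranking(
    truth: RankOrder, dispersion: float, seed=None
) -> RankOrder:
    """Perturb true ranks with N(0, dispersion) noise and re-sort.

    Dispersion 0 returns the truth; expected Kendall tau to the truth
    decreases as dispersion grows.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return truth
    rng = np.random.default_rng(seed)
    noisy = truth.ranks() + rng.normal(0.0, dispersion, truth.n_items)
    order = np.argsort(noisy, kind="stable")
    return RankOrder(tuple(truth.items[i] for i in order))


def constructive_agent_choices(
    subjective: RankOrder,
    truth: RankOrder,
    gamma: float,
    test_sched: TrialSchedule,
    seed=None,
    subject_id: str = "s000",
) -> pd.DataFrame:
    """Test choices drawn from the logistic policy on *subjective* ranks.

    Errors relative to the truth are therefore consistent and transitive:
    with large gamma the subject's majority tournament is exactly their
    subjective order.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    rng = np.random.default_rng(seed)
    sub_rank = subjective.rank_of
    rows = []
    u = rng.random(len(test_sched.trials))
    for k, (_, row) in enumerate(test_sched.trials.iterrows()):
        a, b = int(row["pos_a"]), int(row["pos_b"])
        lo, hi = min(a, b), max(a, b)
        item_lo, item_hi = truth.item_at(lo), truth.item_at(hi)
        diff = sub_rank[item_hi] - sub_rank[item_lo]
        p_hi = float(special.expit(gamma * diff)) if np.isfinite(gamma) else (
            1.0 if diff > 0 else 0.0 if diff < 0 else 0.5
        )
        chosen = item_hi if u[k] < p_hi else item_lo
        rows.append(
            (
                subject_id,
                row["phase"],
                int(row["block"]),
                int(row["trial"]),
                truth.item_at(a),
                truth.item_at(b),
                chosen,
                int(chosen == item_hi),
            )
        )
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


def _assign_agents(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of the mix, then shuffled."""
    kinds = sorted(config.agent_mix)
    raw = np.array([config.agent_mix[k] * config.n_subjects for k in kinds])
    counts = np.floor(raw).astype(int)
    remainder = config.n_subjects - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i % len(kinds)]] += 1
    assignment = [k for k, c in zip(kinds, counts) for _ in range(c)]
    return [assignment[i] for i in rng.permutation(len(assignment))]


def generate_behavioral_cohort(config: CohortConfig) -> BehavioralCohort:
    """Full behavioral dataset: choices, schedules, and a truth manifest."""
    master = np.random.SeedSequence(config.master_seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    agents = _assign_agents(config, rng)
    subject_seeds = master.spawn(config.n_subjects)

    tables, manifest = [], []
    ranks: dict[str, RankOrder] = {}
    learn_scheds: dict[str, TrialSchedule] = {}
    test_scheds: dict[str, TrialSchedule] = {}
    for s, (agent, ss) in enumerate(zip(agents, subject_seeds)):
        subject_id = f"s{s:03d}"
        seeds = ss.generate_state(6) % (2**31)
        truth = make_rank_order(config.items, seed=int(seeds[0]))
        learn = build_learning_schedule(
            config.pair_set, config.n_learning_blocks, seed=int(seeds[1])
        )
        test = build_test_schedule(
            len(config.items), config.n_testing_blocks, seed=int(seeds[2])
        )
        prng = np.random.default_rng(int(seeds[3]))
        entry = {"subject_id": subject_id, "agent": agent,
                 "true_order": list(truth.items)}
        if agent == "constructive":
            subjective = sample_subjective_ranking(
                truth, config.dispersion, seed=int(seeds[4])
            )
            gamma = config.constructive_gamma
            table = constructive_agent_choices(
                subjective, truth, gamma, test, seed=int(seeds[5]),
                subject_id=subject_id,
            )
            entry.update(
                {"gamma": gamma, "subjective_order": list(subjective.items)}
            )
        else:
            alpha = float(prng.uniform(*config.alpha_range))
            gamma = float(prng.uniform(*config.gamma_range))
            params = AgentParams(agent, alpha=alpha, gamma=gamma)
            table = simulate_agent(
                params, truth, learn, test, seed=int(seeds[5]),
                subject_id=subject_id,
            )
            entry.update(
                {
                    "alpha": alpha,
                    "gamma": gamma,
                    "subjective_order": list(truth.items),
                }
            )
        entry["seed"] = int(seeds[5])
        tables.append(table)
        manifest.append(entry)
        ranks[subject_id] = truth
        learn_scheds[subject_id] = learn
        test_scheds[subject_id] = test

    return BehavioralCohort(
        pd.concat(tables, ignore_index=True),
        ranks, learn_scheds, test_scheds, manifest,
    )


def _correlation_coords(rdm: RDM) -> np.ndarray:
    """Item coordinates whose pairwise correlations encode the RDM.

    Factorizes K = 1 - d/c (a valid correlation matrix for negative-type
    dissimilarities, with c large enough to keep K positive semidefinite)
    into unit-norm item vectors, so that 1 - Pearson between the mixed
    sensor patterns reproduces the target RDM up to the scale c.
    """
    d = rdm.d
    c = float(d.max())
    for _ in range(20):
        k = 1.0 - d / c
        vals, vecs = np.linalg.eigh(k)
        if vals.min() > -1e-10:
            break
        c *= 2.0
    coords = vecs[:, vals > 1e-12] * np.sqrt(np.clip(vals[vals > 1e-12], 0, None))
    norms = np.linalg.norm(coords, axis=1)
    return coords / norms[:, None]


def _orthogonal_map(k: int, n_sensors: int, rng: np.random.Generator):
    """Orthonormal-row map into sensor space with zero-sum rows.

    Zero-sum rows give every mixed pattern a zero sensor mean, so Pearson
    correlation between patterns equals the cosine of the coordinates.
    """
    base = np.column_stack(
        [np.ones(n_sensors), rng.standard_normal((n_sensors, k))]
    )
    q, _ = np.linalg.qr(base)
    return q[:, 1 : k + 1].T * np.sqrt(n_sensors / k)


def generate_meg_cohort(
    config: CohortConfig, n_subjects: int | None = None
) -> MegCohort:
    """Sensor patterns embedding known RDM structure, plus judgment streams.

    Per subject and phase (``meg_pre``, ``meg_post``), patterns are the sum
    of window-gated embeddings of the shared lowlevel and size RDMs and — in
    the post phase only — the subject's own subjective-rank RDM, plus
    Gaussian noise.
    """
    if n_subjects is None:
        n_subjects = config.n_subjects
    master = np.random.SeedSequence((config.master_seed, 7))
    shared_rng = np.random.default_rng(master.spawn(1)[0])
    items = tuple(sorted(config.items))

    # shared structure: stimulus features and canonical size ranking
    features = {
        it: shared_rng.standard_normal(48) for it in items
    }
    lowlevel = feature_rdm(features, label="lowlevel")
    size_order = make_rank_order(
        items, seed=int(shared_rng.integers(2**31))
    )
    size = model_rdm_from_ranks(size_order, items, label="size")

    times = config.times()
    gates = {
        name: (times >= w[0]) & (times <= w[1])
        for name, w in config.effect_windows.items()
    }

    subject_seeds = master.spawn(n_subjects)
    data: dict[tuple[str, str], np.ndarray] = {}
    subjective_rdms: dict[str, RDM] = {}
    seq_tables = []
    manifest = []
    for s, ss in enumerate(subject_seeds):
        subject_id = f"m{s:03d}"
        seeds = ss.generate_state(5) % (2**31)
        srng = np.random.default_rng(int(seeds[0]))
        truth = make_rank_order(config.items, seed=int(seeds[1]))
        subjective = sample_subjective_ranking(
            truth, config.dispersion, seed=int(seeds[2])
        )
        subj_rdm = model_rdm_from_ranks(subjective, items, label="subjective")
        subjective_rdms[subject_id] = subj_rdm

        embeddings = {}
        for name, rdm in (
            ("lowlevel", lowlevel), ("size", size), ("subjective", subj_rdm)
        ):
            coords = _correlation_coords(rdm)
            mix = _orthogonal_map(coords.shape[1], config.n_sensors, srng)
            embeddings[name] = config.effect_amplitude * coords @ mix

        for phase in ("meg_pre", "meg_post"):
            signal = np.zeros((len(items), config.n_sensors, len(times)))
            active = ["lowlevel", "size"]
            if phase == "meg_post":
                active.append("subjective")
            for name in active:
                signal += (
                    embeddings[name][:, :, None] * gates[name][None, None, :]
                )
            noise = srng.normal(0.0, config.noise_sd, signal.shape)
            data[(subject_id, phase)] = signal + noise

            seq = build_meg_sequence(
                len(items), config.n_meg_blocks, config.images_per_block,
                seed=int(seeds[3 if phase == "meg_pre" else 4]), phase=phase,
            )
            sdf = seq.trials.copy()
            sdf.insert(0, "subject_id", subject_id)
            seq_tables.append(sdf)

        manifest.append(
            {
                "subject_id": subject_id,
                "true_order": list(truth.items),
                "subjective_order": list(subjective.items),
                "size_order": list(size_order.items),
            }
        )

    patterns = NeuralPatterns(items, times, data)
    return MegCohort(
        patterns, lowlevel, size, subjective_rdms,
        pd.concat(seq_tables, ignore_index=True), manifest,
    )
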