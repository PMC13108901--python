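"""Readers, writers, run configuration, and the end-to-end pipeline.

All tabular data move as CSV, manifests and statistical summaries as JSON,
and sensor patterns as an ``.npz`` container with a JSON sidecar. The
pipeline is fully deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_metrics as bm
from . import error_structure as es
from . import ranking_reconstruction as rr
from . import rsa as rsa_mod
from .model_fitting import fit_participant, simulate_from_fit
from .synthetic_cohort import (
    BehavioralCohort,
    CohortConfig,
    generate_behavioral_cohort,
    generate_meg_cohort,
)
from .task_design import RankOrder, TrialSchedule
from .value_models import CHOICE_COLUMNS

__all__ = [
    "RunConfig",
    "read_choice_table",
    "write_choice_table",
    "write_schedule",
    "run_pipeline",
]

log = logging.getLogger("transrank")


def write_choice_table(table: pd.DataFrame, path) -> None:
    missing = set(CHOICE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"choice table missing columns: {sorted(missing)}")
    table.to_csv(path, index=False)


def read_choice_table(path, ranks: dict[str, RankOrder] | None = None):
    """Read and schema-validate a choice table.

    Returns ``(table, n_warnings)``; when rank orders are supplied the stored
    ``is_correct`` flags are recomputed and mismatches counted as warnings.
    Malformed rows raise with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    missing = set(CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~df["is_correct"].isin([0, 1])].tolist()
    if bad:
        lines = [i + 2 for i in bad[:10]]
        raise ValueError(f"{path}: malformed is_correct at lines {lines}")
    bad = df.index[
        (df["chosen_item"] != df["item_i"]) & (df["chosen_item"] != df["item_j"])
    ].tolist()
    if bad:
        lines = [i + 2 for i in bad[:10]]
        raise ValueError(f"{path}: chosen_item outside the pair at lines {lines}")
    n_warn = 0
    if ranks is not None:
        for subject_id, grp in df.groupby("subject_id"):
            r = ranks[subject_id].rank_of
            hi = np.maximum(grp["item_i"].map(r), grp["item_j"].map(r))
            expect = (grp["chosen_item"].map(r) == hi).astype(int)
            n_bad = int((expect != grp["is_correct"]).sum())
            if n_bad:
                log.warning(
                    "%s: %d is_correct mismatches for %s", path, n_bad, subject_id
                )
                n_warn += n_bad
    return df, n_warn


def write_schedule(
    schedule: TrialSchedule, rank: RankOrder, subject_id: str, path
) -> None:
    """Serialize a schedule with item labels resolved through a rank order."""
    df = schedule.trials.copy()
    df.insert(0, "subject_id", subject_id)
    df["item_a"] = df.pop("pos_a").map(lambda p: rank.item_at(int(p)))
    df["item_b"] = df.pop("pos_b").map(
        lambda p: "" if pd.isna(p) else rank.item_at(int(p))
    )
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "transrank_out"
    n_subjects: int = 77
    agent_mix: dict = field(
        default_factory=lambda: {"constructive": 0.9, "correct_rank": 0.1}
    )
    dispersion: float = 1.2
    constructive_gamma: float = 8.0
    # analysis settings
    consistency_thresholds: tuple = es.STANDARD_THRESHOLDS
    n_perm: int = 1000
    cluster_p: float = 0.05
    # stage toggles
    run_fit: bool = True
    fit_model: str = "qlearning"
    fit_restarts: int = 6
    run_rsa: bool = False
    rsa_n_subjects: int = 20

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_subjects=self.n_subjects,
            agent_mix=dict(self.agent_mix),
            dispersion=self.dispersion,
            constructive_gamma=self.constructive_gamma,
            master_seed=self.seed,
        )


def analyze_cohort(
    pair_accs: list[bm.PairAccuracy], thresholds, n_perm: int, seed: int
) -> dict:
    """All pair-level and consistency analyses for one cohort.

    Subjects with every pair majority-correct (the "correct" group) are
    excluded from pair-level analyses, matching the cohort-filter rule.
    """
    categories = es.categorize_subjects(pair_accs)
    noncorrect_ids = set(
        categories.loc[categories["category"] != "correct", "subject_id"]
    )
    pair_level = [pa for pa in pair_accs if pa.subject_id in noncorrect_ids]

    pairs = pair_accs[0].all_pairs()
    beta_rows = []
    for p in pairs:
        vals = [pa.acc[p] for pa in pair_level if p in pa.acc]
        if len(vals) >= 5:
            fit = es.fit_beta(vals)
            beta_rows.append(
                (p[0], p[1], fit.alpha_hat, fit.beta_hat, fit.category, fit.method)
            )
    beta_fits = pd.DataFrame(
        beta_rows, columns=["pos_lo", "pos_hi", "alpha_hat", "beta_hat",
                            "category", "method"]
    )

    counts = es.cohort_consistency_counts(pair_level, thresholds) if pair_level \
        else pd.DataFrame(columns=["threshold", "count", "proportion"])
    scores = []
    for pa in pair_level:
        try:
            scores.append((pa.subject_id, es.error_consistency_score(pa)))
        except ValueError:
            pass
    error_scores = pd.DataFrame(scores, columns=["subject_id", "score"])
    perm = es.permutation_test_consistency(pair_accs, n_perm=n_perm, seed=seed)

    slopes = bm.slope_summary(pair_accs)
    serial = pd.DataFrame(
        [
            {"subject_id": pa.subject_id, **{
                f"pos_{k}": v for k, v in bm.serial_position_curve(pa).items()
            }}
            for pa in pair_accs
        ]
    )
    return {
        "categories": categories,
        "beta_fits": beta_fits,
        "consistency_counts": counts,
        "error_scores": error_scores,
        "permutation": perm,
        "slopes": slopes,
        "serial_position": serial,
    }


def reconstruct_rankings(
    cohort: BehavioralCohort, pair_accs: list[bm.PairAccuracy]
) -> tuple[list[rr.SubjectiveRanking], pd.DataFrame]:
    """HodgeRank subjective rankings for all non-correct subjects.

    Returns the rankings re-expressed over true rank positions (comparable
    across subjects) plus the per-item score table.
    """
    categories = es.categorize_subjects(pair_accs)
    keep = set(categories.loc[categories["category"] != "correct", "subject_id"])
    rankings = []
    for subject_id, grp in cohort.choices.groupby("subject_id", sort=True):
        if subject_id not in keep:
            continue
        rank = cohort.ranks[subject_id]
        y = rr.preference_matrix(grp, rank)
        hodge = rr.hodgerank(y, rank, subject_id=subject_id)
        pos_order = rr.position_ranking(hodge, rank)
        rankings.append((hodge, pos_order))
    rows = [
        (hodge.subject_id, item, hodge.scores[item], subj_rank)
        for hodge, _ in rankings
        for item, subj_rank in hodge.order.rank_of.items()
    ]
    table = pd.DataFrame(rows, columns=["subject_id", "item", "score", "rank"])
    position_rankings = [
        rr.SubjectiveRanking(hodge.subject_id, hodge.scores, pos, hodge.tied)
        for hodge, pos in rankings
    ]
    return position_rankings, table


def run_pipeline(config: RunConfig) -> dict:
    """Generate, analyze, optionally fit and run RSA; write a report bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    log.info("generating behavioral cohort (n=%d)", config.n_subjects)
    cohort = generate_behavioral_cohort(config.cohort_config())
    write_choice_table(cohort.choices, out / "choices.csv")
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2))

    pair_accs = bm.cohort_pair_accuracies(cohort.choices, cohort.ranks)
    pair_accs, dropped = bm.filter_below_chance(pair_accs)
    if dropped:
        log.info("excluded below-chance subjects: %s", dropped)
    analysis = analyze_cohort(
        pair_accs, config.consistency_thresholds, config.n_perm, config.seed + 1
    )
    results["behavior"] = analysis
    analysis["categories"].to_csv(out / "consistency.csv", index=False)
    analysis["beta_fits"].to_csv(out / "beta_fits.csv", index=False)
    analysis["consistency_counts"].to_csv(
        out / "consistency_counts.csv", index=False
    )
    perm = analysis["permutation"]
    (out / "permutation.json").write_text(
        json.dumps({"observed": perm["observed"], "p": perm["p"]}, indent=2)
    )

    rankings, rank_table = reconstruct_rankings(cohort, pair_accs)
    rank_table.to_csv(out / "rankings.csv", index=False)
    if len(rankings) >= 2:
        similarity = rr.inter_subject_similarity(rankings)
        similarity.to_csv(out / "similarity.csv", index=False)
        results["similarity"] = similarity

    if config.run_fit:
        log.info("fitting %s to each subject", config.fit_model)
        fit_rows, sim_tables = [], []
        fit_seeds = np.random.SeedSequence((config.seed, 11)).spawn(
            len(pair_accs)
        )
        kept = {pa.subject_id for pa in pair_accs}
        for ss, (subject_id, grp) in zip(
            fit_seeds,
            (
                (sid, g)
                for sid, g in cohort.choices.groupby("subject_id", sort=True)
                if sid in kept
            ),
        ):
            s1, s2 = ss.generate_state(2) % (2**31)
            fit = fit_participant(
                config.fit_model, grp, cohort.learn_scheds[subject_id],
                cohort.ranks[subject_id], n_restarts=config.fit_restarts,
                seed=int(s1),
            )
            fit_rows.append(
                (subject_id, fit.model, fit.alpha_hat, fit.gamma_hat,
                 fit.nll, fit.converged)
            )
            sim_tables.append(
                simulate_from_fit(
                    fit, cohort.learn_scheds[subject_id],
                    cohort.test_scheds[subject_id],
                    cohort.ranks[subject_id], seed=int(s2),
                    subject_id=subject_id,
                )
            )
        fits = pd.DataFrame(
            fit_rows,
            columns=["subject_id", "model", "alpha_hat", "gamma_hat", "nll",
                     "converged"],
        )
        fits.to_csv(out / "fits.csv", index=False)
        sim_choices = pd.concat(sim_tables, ignore_index=True)
        write_choice_table(sim_choices, out / "simulated_choices.csv")
        sim_accs = bm.cohort_pair_accuracies(sim_choices, cohort.ranks)
        sim_analysis = analyze_cohort(
            sim_accs, config.consistency_thresholds, config.n_perm,
            config.seed + 2,
        )
        sim_analysis["categories"].to_csv(
            out / "simulated_consistency.csv", index=False
        )
        sim_analysis["beta_fits"].to_csv(
            out / "simulated_beta_fits.csv", index=False
        )
        results["fits"] = fits
        results["simulated"] = sim_analysis

    if config.run_rsa:
        log.info("running RSA stage (n=%d)", config.rsa_n_subjects)
        meg = generate_meg_cohort(
            config.cohort_config(), n_subjects=config.rsa_n_subjects
        )
        meg.patterns.save(out / "patterns")
        betas = rsa_mod.compute_rsa_betas(
            meg.patterns, meg.lowlevel_rdm, meg.size_rdm, meg.subjective_rdms
        )
        betas.to_csv(out / "rsa_betas.csv", index=False)
        contrasts = rsa_mod.learning_contrast(betas)
        clusters = {}
        times = meg.patterns.times
        for k, predictor in enumerate(rsa_mod.PREDICTORS):
            sub = contrasts[contrasts["predictor"] == predictor]
            mat = sub.pivot(
                index="subject_id", columns="time", values="contrast"
            ).to_numpy()
            clusters[predictor] = rsa_mod.cluster_permutation_test(
                mat, times, n_perm=config.n_perm,
                cluster_p=config.cluster_p, seed=config.seed + 20 + k,
            )
        (out / "rsa_clusters.json").write_text(json.dumps(clusters, indent=2))
        window = CohortConfig().effect_windows["subjective"]
        shuffle = rsa_mod.subject_shuffle_test(
            meg.patterns, meg.lowlevel_rdm, meg.size_rdm, meg.subjective_rdms,
            window=window, n_perm=config.n_perm, seed=config.seed + 30,
        )
        (out / "rsa_shuffle.json").write_text(
            json.dumps(
                {"observed": shuffle["observed"], "p": shuffle["p"]}, indent=2
            )
        )
        results["rsa"] = {
            "betas": betas, "clusters": clusters, "shuffle": shuffle
        }

    _write_summary(out, config, results)
    return results


def _write_summary(out: Path, config: RunConfig, results: dict) -> None:
    lines = ["# transrank pipeline summary", ""]
    analysis = results["behavior"]
    cat_counts = analysis["categories"]["category"].value_counts().to_dict()
    lines += [
        f"Seed: {config.seed}; subjects: {config.n_subjects}",
        "",
        "## Self-consistency categories",
        "",
    ] + [f"- {k}: {v}" for k, v in sorted(cat_counts.items())]
    beta_counts = analysis["beta_fits"]["category"].value_counts().to_dict()
    lines += ["", "## Pair-level Beta categories", ""] + [
        f"- {k}: {v}" for k, v in sorted(beta_counts.items())
    ]
    perm = analysis["permutation"]
    lines += [
        "",
        "## Group self-consistency permutation test",
        "",
        f"- observed mean coefficient: {perm['observed']:.4f}",
        f"- p = {perm['p']:.4g}",
        "",
        "## Symbolic distance effect",
        "",
        f"- mean slope: {analysis['slopes']['mean_slope']:.4f} "
        f"(t = {analysis['slopes']['t']:.2f}, n = {analysis['slopes']['n']})",
    ]
    if "similarity" in results:
        lines += [
            "",
            "## Inter-subject ranking similarity",
            "",
            f"- mean Kendall tau: {results['similarity']['tau'].mean():.4f}",
        ]
    if "rsa" in results:
        lines += ["", "## RSA", ""]
        for predictor, cl in results["rsa"]["clusters"].items():
            sig = [c for c in cl if c["p"] < config.cluster_p]
            lines.append(
                f"- {predictor}: {len(sig)} significant cluster(s) "
                + ", ".join(
                    f"[{c['time_start']:.3f}-{c['time_end']:.3f}s p={c['p']:.3g}]"
                    for c in sig
                )
            )
        lines.append(
            f"- subject-shuffle p = {results['rsa']['shuffle']['p']:.4g}"
        )
    (out / "summary.md").write_text("\n".join(lines) + "\n")
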