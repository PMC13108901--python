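"""Time-resolved representational similarity analysis (RSA).

For every subject, phase, and timepoint, an 8 x 8 neural representational
dissimilarity matrix (RDM; 1 - Pearson correlation between item sensor
patterns) is regressed simultaneously on three model RDMs:

* ``lowlevel`` — cosine dissimilarity of stimulus feature vectors (shared),
* ``size`` — absolute differences of canonical size ranks (shared),
* ``subjective`` — absolute differences of the subject's own reconstructed
  subjective ranks (subject-specific).

Learning effects are isolated by the post - pre contrast of the subjective
beta (lowlevel and size are averaged across phases), tested over time with a
sign-flip cluster permutation and validated for subject specificity by
shuffling subjective-RDM assignments across subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import RankOrder

__all__ = [
    "RDM",
    "NeuralPatterns",
    "model_rdm_from_ranks",
    "feature_rdm",
    "neural_rdm",
    "rdm_regression",
    "compute_rsa_betas",
    "learning_contrast",
    "cluster_permutation_test",
    "subject_shuffle_test",
]

PREDICTORS = ("lowlevel", "size", "subjective")


@dataclass
class RDM:
    """Symmetric zero-diagonal dissimilarity matrix over a fixed item order."""

    d: np.ndarray
    items: tuple[str, ...]
    label: str = "model"

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("RDM must be square")
        if d.shape[0] != len(self.items):
            raise ValueError("item labels do not match matrix size")
        if not np.allclose(d, d.T, equal_nan=True):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(d), 0.0, equal_nan=True):
            raise ValueError("RDM diagonal must be zero")
        self.d = d

    def vectorize(self) -> np.ndarray:
        """Upper-triangle entries, row-major — the fixed ordering everywhere."""
        iu = np.triu_indices(self.d.shape[0], k=1)
        return self.d[iu]


@dataclass
class NeuralPatterns:
    """Item x sensor x time arrays per (subject, phase), shared time axis."""

    items: tuple[str, ...]
    times: np.ndarray
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.data})

    @property
    def phases(self) -> list[str]:
        return sorted({p for _, p in self.data})

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def window_slice(self, window: tuple[float, float]) -> slice:
        lo = int(np.searchsorted(self.times, window[0], side="left"))
        hi = int(np.searchsorted(self.times, window[1], side="right"))
        if hi <= lo:
            raise ValueError(f"window {window} outside the time axis")
        return slice(lo, hi)

    def save(self, path) -> None:
        """Write an .npz container plus a JSON sidecar describing the axes."""
        path = Path(path)
        arrays = {f"{s}__{p}": arr for (s, p), arr in self.data.items()}
        np.savez_compressed(path.with_suffix(".npz"), times=self.times, **arrays)
        sidecar = {
            "items": list(self.items),
            "subjects": self.subjects,
            "phases": self.phases,
            "n_sensors": int(next(iter(self.data.values())).shape[1]),
            "n_times": len(self.times),
            "time_start": float(self.times[0]),
            "time_end": float(self.times[-1]),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "NeuralPatterns":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            times = npz["times"]
            data = {}
            for key in npz.files:
                if key == "times":
                    continue
                s, p = key.split("__")
                data[(s, p)] = npz[key]
        return cls(tuple(sidecar["items"]), times, data)


# ---------------------------------------------------------------------------
# RDM construction
# ---------------------------------------------------------------------------


def model_rdm_from_ranks(
    rank: RankOrder, items: tuple[str, ...] | None = None, label: str = "rank"
) -> RDM:
    """d(i, j) = |rank_i - rank_j| over a canonical item ordering."""
    if items is None:
        items = tuple(sorted(rank.items))
    r = rank.rank_of
    ranks = np.array([r[it] for it in items], dtype=float)
    d = np.abs(ranks[:, None] - ranks[None, :])
    return RDM(d, items, label)


def feature_rdm(features: dict[str, np.ndarray], label: str = "lowlevel") -> RDM:
    """Cosine dissimilarity 1 - cos(f_i, f_j) between item feature vectors."""
    items = tuple(sorted(features))
    mat = np.array([np.asarray(features[it], dtype=float) for it in items])
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ValueError("feature vectors must be nonzero")
    unit = mat / norms[:, None]
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(d, items, label)


def neural_rdm(patterns: np.ndarray, items: tuple[str, ...]) -> RDM:
    """1 - Pearson correlation between item sensor patterns (one timepoint).

    ``patterns`` is item x sensor. Zero-variance patterns yield NaN entries
    (flagged undefined) rather than an error.
    """
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValueError("need an item x sensor matrix with >= 2 sensors")
    sd = patterns.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(patterns)
    d = 1.0 - corr
    d[sd == 0, :] = np.nan
    d[:, sd == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(d, items, "neural")


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def rdm_regression(neural: RDM, models: list[RDM]) -> tuple[np.ndarray, bool]:
    """OLS of the vectorized neural RDM on the model RDMs, entered together.

    Predictors are z-scored across the 28 off-diagonal entries so the betas
    are comparable in magnitude; an intercept is included. Returns
    (betas, collinear_flag); with rank-deficient predictors the minimum-norm
    solution is returned and flagged.
    """
    yv = neural.vectorize()
    x = np.column_stack([_zscore(m.vectorize()) for m in models])
    design = np.column_stack([np.ones(len(yv)), x])
    mask = np.isfinite(yv)
    betas, *_ = np.linalg.lstsq(design[mask], yv[mask], rcond=None)
    collinear = np.linalg.matrix_rank(design[mask]) < design.shape[1]
    return betas[1:], bool(collinear)


def compute_rsa_betas(
    patterns: NeuralPatterns,
    lowlevel: RDM,
    size: RDM,
    subjective: dict[str, RDM],
) -> pd.DataFrame:
    """Per-timepoint regression betas for every subject and phase.

    Returns tidy rows (subject_id, phase, predictor, time, beta).
    """
    rows = []
    for (subject, phase), arr in sorted(patterns.data.items()):
        models = [lowlevel, size, subjective[subject]]
        for t_idx, t in enumerate(patterns.times):
            nrdm = neural_rdm(arr[:, :, t_idx], patterns.items)
            betas, _ = rdm_regression(nrdm, models)
            for name, beta in zip(PREDICTORS, betas):
                rows.append((subject, phase, name, float(t), float(beta)))
    return pd.DataFrame(
        rows, columns=["subject_id", "phase", "predictor", "time", "beta"]
    )


def learning_contrast(
    betas: pd.DataFrame, pre: str = "meg_pre", post: str = "meg_post"
) -> pd.DataFrame:
    """Per-subject, per-time contrast: subjective post - pre; others averaged.

    The subjective predictor isolates learning by differencing the phases;
    lowlevel and size reflect stable structure and are averaged across both.
    """
    phases = set(betas["phase"].unique())
    if not {pre, post} <= phases:
        raise ValueError(f"need both phases {pre!r} and {post!r}")
    wide = betas.pivot_table(
        index=["subject_id", "predictor", "time"],
        columns="phase",
        values="beta",
    ).reset_index()
    is_subj = wide["predictor"] == "subjective"
    wide["contrast"] = np.where(
        is_subj,
        wide[post] - wide[pre],
        (wide[post] + wide[pre]) / 2.0,
    )
    return wide[["subject_id", "predictor", "time", "contrast"]]


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def _cluster_masses(tvals: np.ndarray, threshold: float):
    """Maximal runs of same-sign suprathreshold t values with their masses."""
    supra = np.abs(tvals) > threshold
    sign = np.sign(tvals)
    clusters = []
    start = None
    for k in range(len(tvals) + 1):
        inside = k < len(tvals) and supra[k]
        if inside and start is None:
            start = k
        boundary = (
            start is not None
            and (not inside or (k > start and sign[k] != sign[start]))
        )
        if boundary:
            clusters.append((start, k, float(tvals[start:k].sum())))
            start = k if inside else None
    return clusters


def cluster_permutation_test(
    contrasts: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    cluster_p: float = 0.05,
    seed=None,
) -> list[dict]:
    """Sign-flip cluster permutation over time for a subjects x time array.

    Timepoints whose one-sample t (against 0) exceeds the two-sided
    cluster-defining threshold form contiguous same-sign clusters scored by
    the sum of t values (mass). The null is the distribution of the maximum
    absolute mass under random per-subject sign flips; add-one p values.
    """
    if contrasts.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n_sub, n_time = contrasts.shape
    threshold = stats.t.ppf(1.0 - cluster_p / 2.0, df=n_sub - 1)

    def tseries(data):
        mean = data.mean(axis=0)
        se = data.std(axis=0, ddof=1) / np.sqrt(n_sub)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(se > 0, mean / se, 0.0)

    observed = _cluster_masses(tseries(contrasts), threshold)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        masses = _cluster_masses(tseries(contrasts * flips[b][:, None]), threshold)
        null_max[b] = max((abs(m) for *_, m in masses), default=0.0)
    out = []
    for start, stop, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        out.append(
            {
                "start_index": start,
                "stop_index": stop,
                "time_start": float(times[start]),
                "time_end": float(times[stop - 1]),
                "mass": mass,
                "p": float(p),
            }
        )
    return out


def subject_shuffle_test(
    patterns: NeuralPatterns,
    lowlevel: RDM,
    size: RDM,
    subjective: dict[str, RDM],
    window: tuple[float, float],
    n_perm: int = 1000,
    seed=None,
    phase: str = "meg_post",
) -> dict:
    """Subject-specificity test: shuffle subjective-RDM assignments.

    The observed statistic is the group-mean subjective beta from regressing
    each subject's window-averaged neural RDM on (lowlevel, size, own
    subjective RDM). Null draws reassign the subjective RDMs across subjects
    at random and recompute the group mean; p is the add-one exceedance of
    the observed mean.
    """
    subjects = [s for s in patterns.subjects if (s, phase) in patterns.data]
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    sl = patterns.window_slice(window)

    window_rdms = {}
    for s in subjects:
        avg = patterns.data[(s, phase)][:, :, sl].mean(axis=2)
        window_rdms[s] = neural_rdm(avg, patterns.items)

    def group_mean(assignment: list[str]) -> float:
        betas = []
        for s, donor in zip(subjects, assignment):
            b, _ = rdm_regression(
                window_rdms[s], [lowlevel, size, subjective[donor]]
            )
            betas.append(b[2])
        return float(np.mean(betas))

    observed = group_mean(subjects)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = [subjects[i] for i in rng.permutation(len(subjects))]
        null[b] = group_mean(perm)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return {"observed": observed, "null": null, "p": float(p)}
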