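"""Numerosity-comparison session scoring.

Trial-level records of two-colour dot comparisons are scored for
accuracy, reaction-time outliers are trimmed with a sample-size-dependent
moving criterion, and a per-subject Weber fraction is estimated by
weighted least squares against the Gaussian approximate-number-system
psychometric curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import erfc

__all__ = [
    "TrialRecord",
    "SubjectScore",
    "weber_threshold",
    "predict_percent_correct",
    "trim_rt_outliers",
    "score_accuracy",
    "estimate_weber",
    "score_subject",
    "read_trials_csv",
    "write_scores_tsv",
    "trials_to_frame",
    "frame_to_trials",
]

W_LO = 0.01
W_HI = 2.0


@dataclass
class TrialRecord:
    subject_id: str
    n_yellow: int
    n_blue: int
    response: str  # 'yellow' | 'blue'
    correct: bool
    rt_ms: float

    def __post_init__(self):
        if self.n_yellow < 1 or self.n_blue < 1:
            raise ValueError("dot counts must be >= 1")
        if self.response not in ("yellow", "blue"):
            raise ValueError(f"invalid response {self.response!r}")
        if not (self.rt_ms > 0):
            raise ValueError("rt_ms must be positive")
        if not self.indeterminate:
            larger = "yellow" if self.n_yellow > self.n_blue else "blue"
            if self.correct != (self.response == larger):
                raise ValueError(
                    "correct flag inconsistent with response and dot counts"
                )

    @property
    def indeterminate(self) -> bool:
        """Tie trials carry `correct` as recorded but are flagged here."""
        return self.n_yellow == self.n_blue


@dataclass
class SubjectScore:
    subject_id: str
    accuracy_raw: int
    w: float
    n_trials_kept: int
    fit_sse: float
    flags: list = field(default_factory=list)


def weber_threshold(n_small: int, n_large: int) -> float:
    """Just-noticeable-difference ratio: increment over the smaller set."""
    if n_small < 1:
        raise ValueError("n_small must be >= 1")
    if n_small > n_large:
        raise ValueError("n_small must not exceed n_large")
    return (n_large - n_small) / n_small


def predict_percent_correct(n1: int, n2: int, w: float) -> float:
    """Expected accuracy under Gaussian numerosity representations.

    Discriminability is |n1 - n2| / (w * sqrt(n1^2 + n2^2)); accuracy is
    the upper Gaussian tail, in [0.5, 1).
    """
    if w <= 0:
        raise ValueError("w must be positive")
    if n1 < 1 or n2 < 1:
        raise ValueError("dot counts must be >= 1")
    d = abs(n1 - n2) / (w * math.sqrt(n1 * n1 + n2 * n2))
    return 1.0 - 0.5 * erfc(d / math.sqrt(2.0))


# Non-recursive moving criterion (SDs from the mean) as a function of the
# number of trials in the cell; linearly interpolated, asymptote 2.5.
_CRITERION_N = np.array(
    [4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 20, 25, 30, 35, 50, 100], float
)
_CRITERION_K = np.array(
    [1.458, 1.68, 1.841, 1.961, 2.05, 2.12, 2.173, 2.22, 2.246, 2.274,
     2.31, 2.326, 2.391, 2.41, 2.4305, 2.45, 2.48, 2.5], float
)


def moving_criterion(n: int) -> float:
    """Interpolated SD criterion for sample size n (>= 2.5 cap at n=100)."""
    return float(np.interp(n, _CRITERION_N, _CRITERION_K))


def trim_rt_outliers(trials: list[TrialRecord]) -> tuple[list[TrialRecord], int]:
    """Single-pass moving-criterion trim on reaction times.

    A trial is removed when its RT lies more than k(n) sample standard
    deviations from the session mean, with k(n) increasing in n. Sessions
    shorter than the criterion table (n < 4) or with zero RT spread are
    returned untouched (with a warning in the short case).
    """
    if not trials:
        raise ValueError("need at least one trial")
    rts = np.array([t.rt_ms for t in trials], float)
    if not np.all(np.isfinite(rts)):
        raise ValueError("non-finite RT encountered")
    n = len(rts)
    if n < int(_CRITERION_N[0]):
        warnings.warn("too few trials for the moving criterion; no trimming")
        return list(trials), 0
    sd = rts.std(ddof=1)
    if sd == 0:
        return list(trials), 0
    k = moving_criterion(n)
    keep = np.abs(rts - rts.mean()) <= k * sd
    kept = [t for t, ok in zip(trials, keep) if ok]
    return kept, int(n - keep.sum())


def score_accuracy(trials: list[TrialRecord]) -> int:
    if not trials:
        raise ValueError("no trials to score")
    return sum(1 for t in trials if t.correct)


def _binned(trials: list[TrialRecord]):
    """Unequal-count bins: (n_small, n_large) -> (count, prop correct)."""
    bins: dict[tuple[int, int], list[int]] = {}
    for t in trials:
        if t.indeterminate:
            continue
        key = (min(t.n_yellow, t.n_blue), max(t.n_yellow, t.n_blue))
        cnt = bins.setdefault(key, [0, 0])
        cnt[0] += 1
        cnt[1] += int(t.correct)
    if not bins:
        raise ValueError("all trials are ties; Weber fraction unidentifiable")
    keys = sorted(bins)
    n1 = np.array([k[0] for k in keys], float)
    n2 = np.array([k[1] for k in keys], float)
    cnt = np.array([bins[k][0] for k in keys], float)
    phat = np.array([bins[k][1] / bins[k][0] for k in keys], float)
    return n1, n2, cnt, phat


def _curve(n1, n2, w):
    d = np.abs(n1 - n2) / (w * np.sqrt(n1**2 + n2**2))
    return 1.0 - 0.5 * erfc(d / math.sqrt(2.0))


def estimate_weber(
    trials: list[TrialRecord],
    w_bounds: tuple[float, float] = (W_LO, W_HI),
) -> SubjectScore:
    """Least-squares Weber fraction from binned proportion-correct data.

    Minimizes sum over bins of count * (observed - predicted)^2 for w in
    ``w_bounds``; a coarse grid locates the basin and a bounded scalar
    search refines it, so the optimum matches exhaustive grid search.
    Boundary solutions and below-chance sessions are flagged.
    """
    if not trials:
        raise ValueError("no trials supplied")
    lo, hi = w_bounds
    n1, n2, cnt, phat = _binned(trials)
    flags = []
    overall = float(np.sum(cnt * phat) / np.sum(cnt))

    def sse(w):
        return float(np.sum(cnt * (phat - _curve(n1, n2, w)) ** 2))

    if overall < 0.5:
        w_hat, flags = hi, ["below-chance accuracy; w clamped at upper bound"]
    else:
        grid = np.linspace(lo, hi, 400)
        pred = _curve(n1[:, None], n2[:, None], grid[None, :])
        obj = np.sum(cnt[:, None] * (phat[:, None] - pred) ** 2, axis=0)
        i = int(np.argmin(obj))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(sse, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-8})
        w_hat = float(res.x)
        if w_hat - lo < 1e-4:
            w_hat = lo
            flags.append("w at lower bound")
        elif hi - w_hat < 1e-4:
            w_hat = hi
            flags.append("w at upper bound")

    subject = trials[0].subject_id
    return SubjectScore(
        subject_id=subject,
        accuracy_raw=score_accuracy(trials),
        w=w_hat,
        n_trials_kept=len(trials),
        fit_sse=sse(w_hat),
        flags=flags,
    )


def score_subject(trials: list[TrialRecord], trim: bool = True) -> SubjectScore:
    """Full per-subject scoring: raw accuracy on all trials, Weber fraction
    on the trimmed set."""
    accuracy = score_accuracy(trials)
    kept, _removed = trim_rt_outliers(trials) if trim else (list(trials), 0)
    score = estimate_weber(kept)
    score.accuracy_raw = accuracy
    return score


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ["subject_id", "trial", "n_yellow", "n_blue", "response",
                 "correct", "rt_ms"]


def trials_to_frame(trials_by_subject: dict[str, list[TrialRecord]]) -> pd.DataFrame:
    rows = []
    for sid in trials_by_subject:
        for i, t in enumerate(trials_by_subject[sid], start=1):
            rows.append((sid, i, t.n_yellow, t.n_blue, t.response,
                         int(t.correct), t.rt_ms))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> dict[str, list[TrialRecord]]:
    out: dict[str, list[TrialRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            TrialRecord(str(row.subject_id), int(row.n_yellow), int(row.n_blue),
                        str(row.response), bool(row.correct), float(row.rt_ms))
        )
    return out


def read_trials_csv(path) -> dict[str, list[TrialRecord]]:
    return frame_to_trials(pd.read_csv(path))


def write_scores_tsv(scores: list[SubjectScore], path) -> None:
    df = pd.DataFrame(
        [(s.subject_id, s.accuracy_raw, s.w, s.n_trials_kept, s.fit_sse)
         for s in scores],
        columns=["subject_id", "accuracy", "weber", "n_kept", "sse"],
    )
    df.to_csv(path, sep="\t", index=False)
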