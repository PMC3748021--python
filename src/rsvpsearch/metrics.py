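"""Decoding and retrieval metrics.

``average_precision`` follows the ranked-retrieval convention used in
relevance-feedback evaluation: the precision of a retrieved target is
``i / n`` where ``i`` is its position among the targets of the retrieved
sequence and ``n`` its absolute position; a target missing from the
retrieved sequence scores 0; AP is the mean over *all* targets in the
database.  ROC AUC is the Mann-Whitney probability with the 1/2 tie
convention.  TTI-stratified AUC scores each target-to-target-interval
category's targets against the shared distractor pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .preprocessing import TTI_GT3

__all__ = [
    "RankedRetrieval",
    "roc_auc",
    "average_precision",
    "tti_stratified_auc",
    "retrieval_fraction",
    "compare_runs",
    "RunComparison",
    "TTI_CATEGORY_NAMES",
]

TTI_CATEGORY_NAMES = {1: "1", 2: "2", 3: "3", TTI_GT3: ">3"}


@dataclass
class RankedRetrieval:
    """An ordered retrieved sequence (best first) plus the true target set."""

    ranked_ids: np.ndarray
    target_ids: frozenset
    cap: int | None = None

    def __post_init__(self) -> None:
        self.ranked_ids = np.asarray(self.ranked_ids)
        if len(np.unique(self.ranked_ids)) != len(self.ranked_ids):
            raise ValueError("retrieved sequence contains duplicate ids")
        self.target_ids = frozenset(int(i) for i in self.target_ids)
        if self.cap is not None and len(self.ranked_ids) > self.cap:
            raise ValueError(f"retrieved sequence exceeds cap {self.cap}")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC = P(score_target > score_distractor) + 1/2 P(equal)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def average_precision(ret: RankedRetrieval) -> float:
    """Mean of per-target precision scores ``i / n`` over all targets.

    ``i`` is a retrieved target's position among the targets of the
    sequence (1-based) and ``n`` its absolute position; unretrieved targets
    contribute 0.
    """
    if not ret.target_ids:
        raise ValueError("empty target set")
    total = 0.0
    i = 0
    for n, img in enumerate(ret.ranked_ids, start=1):
        if int(img) in ret.target_ids:
            i += 1
            total += i / n
    return total / len(ret.target_ids)


def tti_stratified_auc(scores: np.ndarray, labels: np.ndarray,
                       tti: np.ndarray) -> dict[str, float]:
    """AUC per target-to-target-interval category.

    Each category's target trials are scored against the full shared
    distractor pool; a category with no targets is reported as NaN rather
    than 0 (absence of evidence, not evidence of chance).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    tti = np.asarray(tti)
    distractors = scores[labels == 0]
    if distractors.size == 0:
        raise ValueError("no distractor trials")
    out: dict[str, float] = {}
    for code, name in TTI_CATEGORY_NAMES.items():
        targ = scores[(labels == 1) & (tti == code)]
        if targ.size == 0:
            out[name] = float("nan")
            continue
        s = np.concatenate([targ, distractors])
        y = np.concatenate([np.ones(targ.size), np.zeros(distractors.size)])
        out[name] = roc_auc(s, y)
    return out


def retrieval_fraction(ret: RankedRetrieval) -> float:
    """Fraction of all database targets present in the retrieved sequence."""
    if not ret.target_ids:
        raise ValueError("empty target set")
    hits = sum(1 for i in ret.ranked_ids if int(i) in ret.target_ids)
    return hits / len(ret.target_ids)


@dataclass
class RunComparison:
    """Wilcoxon signed-rank summary of two seed-paired metric series."""

    p_value: float
    median_difference: float
    n: int
    degenerate: bool = False  # all paired differences were zero


def compare_runs(a: np.ndarray, b: np.ndarray,
                 alternative: str = "two-sided") -> RunComparison:
    """Paired signed-rank comparison of two metric series (same seeds).

    Uses the exact signed-rank null distribution for small n (no ties) and
    the normal approximation otherwise.  An all-zero difference series is
    degenerate: reported with p = 1 and median difference 0 rather than an
    error.  Requires at least 5 pairs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired values")
    d = a - b
    if np.all(d == 0):
        return RunComparison(p_value=1.0, median_difference=0.0, n=len(a),
                             degenerate=True)
    dz = d[d != 0]
    m = len(dz)
    if m <= 25:
        p = _exact_signed_rank_p(dz, alternative)
    else:
        res = stats.wilcoxon(a, b, alternative=alternative, method="approx")
        p = float(res.pvalue)
    return RunComparison(p_value=p, median_difference=float(np.median(d)),
                         n=len(a))


def _exact_signed_rank_p(dz: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p by sign enumeration (handles tied ranks).

    Under the null every sign pattern of the m nonzero differences is
    equally likely; the distribution of W+ (sum of ranks of positive
    differences) is built by dynamic programming over doubled ranks
    (mid-ranks are half-integers).
    """
    ranks = stats.rankdata(np.abs(dz))
    r2 = np.rint(2 * ranks).astype(int)
    w_obs = int(r2[dz > 0].sum())
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    p_ge = float(pmf[w_obs:].sum())
    p_le = float(pmf[: w_obs + 1].sum())
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_ge, p_le))
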