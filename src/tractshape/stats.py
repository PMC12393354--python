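"""Per-subject bundle-adjacency summaries and paired method comparison.

Each subject contributes one inter-subject similarity score per tracking
method: the mean of their similarity-matrix row excluding the diagonal.
The two methods are then compared subject-by-subject with a paired t-test,
an exact Wilcoxon signed-rank test, and a paired Cohen's d standardized by
the SD of the differences, so that |t| = |d| * sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .metrics import SimilarityMatrix

__all__ = [
    "DegenerateTestError",
    "CohortResult",
    "subject_mean_ba",
    "cohort_summary",
    "paired_t",
    "wilcoxon_signed_rank",
    "cohens_d_paired",
    "paired_comparison",
]

#: Largest n for which the Wilcoxon null distribution is computed exactly.
WILCOXON_EXACT_MAX_N = 25


class DegenerateTestError(ValueError):
    """All paired differences are zero (or have zero variance)."""


@dataclass
class CohortResult:
    """Everything a cohort run produces: scores, summaries, paired tests."""

    per_subject_ba: dict
    cohort_summary: dict
    atlas_ba: dict
    tests: dict
    atlas_tests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_subject_ba": self.per_subject_ba,
            "cohort_summary": self.cohort_summary,
            "atlas_ba": self.atlas_ba,
            "tests": self.tests,
            "atlas_tests": self.atlas_tests,
        }


def subject_mean_ba(M: SimilarityMatrix) -> np.ndarray:
    """Per-subject score: mean of the subject's row excluding the diagonal."""
    S = np.asarray(M.scores, dtype=np.float64)
    n = len(S)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    return (S.sum(axis=1) - np.diag(S)) / (n - 1)


def upper_triangle_mean(M: SimilarityMatrix) -> float:
    """Cohort-level alternative to row-means: mean over unordered pairs."""
    S = np.asarray(M.scores, dtype=np.float64)
    iu = np.triu_indices(len(S), k=1)
    return float(S[iu].mean())


def cohort_summary(scores: np.ndarray) -> dict:
    """Mean, sample SD (n-1), and range of per-subject scores."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 values")
    return {
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)),
        "min": float(scores.min()),
        "max": float(scores.max()),
        "n": int(scores.size),
    }


def _paired_diffs(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    return x - y


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    d = _paired_diffs(x, y)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d: mean difference over the SD of the differences.

    With this standardization |t| = |d| * sqrt(n) for the same paired data.
    """
    d = _paired_diffs(x, y)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("paired differences have zero variance")
    return float(d.mean() / sd)


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Midranks of |d| for nonzero differences."""
    return sps.rankdata(np.abs(d))


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the sum of positive ranks.

    The null distribution over all 2^n equiprobable sign assignments is
    built by dynamic programming on the (doubled, hence integral) midranks
    — mathematically identical to full enumeration but O(n * sum(ranks)).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    total = counts.sum()  # == 2**n
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (W, two-sided p).

    Zero differences are dropped; tied absolute differences receive
    midranks; W = min(sum of positive ranks, sum of negative ranks).  The
    p-value is exact (all sign assignments) for n <= 25 and a tie-corrected
    normal approximation above.
    """
    d = _paired_diffs(x, y)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_MAX_N:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = 2.0 * float(sps.norm.sf(abs(z)))
    return W, p


def paired_comparison(x, y) -> dict:
    """Full paired test block: t, df, p_t, W, p_wilcoxon, cohens_d."""
    t, df, p_t = paired_t(x, y)
    W, p_w = wilcoxon_signed_rank(x, y)
    d = cohens_d_paired(x, y)
    return {
        "t": t,
        "df": df,
        "p_t": p_t,
        "W": W,
        "p_wilcoxon": p_w,
        "cohens_d": d,
        "n": len(np.asarray(x)),
    }
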