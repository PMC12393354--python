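"""Streamline distances and bundle shape similarity.

The core quantities:

* MDF — minimum average direct-flip distance between two streamlines
  resampled to K points: the mean pointwise Euclidean distance, minimized
  over the two traversal orders, making it invariant to streamline
  orientation (head/tail) flips.
* adjacency — two streamlines are adjacent when MDF <= theta.
* coverage(B1, B2) — fraction of streamlines in B1 adjacent to at least
  one streamline in B2.
* bundle adjacency BA(B1, B2) = 0.5 * (coverage(B1, B2) + coverage(B2, B1)),
  a symmetric shape-similarity score in [0, 1] (0 = no shared shape,
  1 = identical shape).

Pairwise BA over a cohort yields a symmetric similarity matrix per tracking
method; ``extract_bundle`` is a model-proximity segmentation that keeps
tractogram streamlines within a threshold MDF of a reference bundle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .tracking import Tractogram

__all__ = [
    "BAParams",
    "SimilarityMatrix",
    "resample",
    "mdf",
    "mdf_matrix",
    "coverage",
    "bundle_adjacency",
    "pairwise_ba_matrix",
    "extract_bundle",
]

Bundle = Sequence[np.ndarray]


@dataclass(frozen=True)
class BAParams:
    """Bundle-adjacency parameters.

    ``theta`` is the adjacency threshold in mm (strict 5 mm by default);
    ``n_resample_points`` is the common point count K used for MDF.
    ``subsample`` optionally caps each bundle at a seeded random subset, a
    cost control for large bundles (off by default so results are exact).
    """

    theta: float = 5.0
    n_resample_points: int = 20
    subsample: Optional[int] = None
    subsample_seed: int = 0

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.n_resample_points < 2:
            raise ValueError("n_resample_points must be >= 2")
        if self.subsample is not None and self.subsample < 1:
            raise ValueError("subsample must be >= 1 when set")


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise BA scores over a cohort."""

    scores: np.ndarray
    subject_ids: list[str]
    method: str
    theta: float
    empty_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = len(self.subject_ids)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square and match subject_ids")


def resample(s: np.ndarray, K: int) -> np.ndarray:
    """Resample a streamline to K points equally spaced by arc length.

    Endpoints are preserved exactly; interior points are linearly
    interpolated along the polyline.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
        raise ValueError("streamline must be an (n>=2, 3) array")
    if K < 2:
        raise ValueError("K must be >= 2")
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("cannot resample a zero-length streamline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, total, K)
    out = np.empty((K, 3))
    for d in range(3):
        out[:, d] = np.interp(target, cum, s[:, d])
    out[0] = s[0]
    out[-1] = s[-1]
    return out


def _bundle_array(bundle: Bundle, K: int) -> np.ndarray:
    """Stack a bundle into an (N, K, 3) array of resampled streamlines."""
    if len(bundle) == 0:
        return np.empty((0, K, 3))
    return np.stack([resample(s, K) for s in bundle])


def mdf(s1: np.ndarray, s2: np.ndarray, K: int = 20) -> float:
    """Minimum average direct-flip distance between two streamlines (mm)."""
    a = resample(s1, K)
    b = resample(s2, K)
    direct = float(np.mean(np.linalg.norm(a - b, axis=1)))
    flipped = float(np.mean(np.linalg.norm(a - b[::-1], axis=1)))
    return min(direct, flipped)


def mdf_matrix(A: np.ndarray, B: np.ndarray, chunk: int = 256) -> np.ndarray:
    """All-pairs MDF between two stacks of K-point streamlines.

    ``A`` is (N1, K, 3), ``B`` is (N2, K, 3); returns (N1, N2).  Work is
    chunked over rows to bound peak memory.
    """
    n1 = len(A)
    out = np.empty((n1, len(B)))
    B_flip = B[:, ::-1]
    for lo in range(0, n1, chunk):
        hi = min(lo + chunk, n1)
        diff = A[lo:hi, None] - B[None]  # (c, N2, K, 3)
        direct = np.sqrt(np.sum(diff * diff, axis=3)).mean(axis=2)
        diff = A[lo:hi, None] - B_flip[None]
        flipped = np.sqrt(np.sum(diff * diff, axis=3)).mean(axis=2)
        out[lo:hi] = np.minimum(direct, flipped)
    return out


def _prepare(bundle: Bundle, params: BAParams, salt: int) -> np.ndarray:
    """Optionally subsample (seeded), then resample a bundle to an array."""
    idx = np.arange(len(bundle))
    if params.subsample is not None and len(bundle) > params.subsample:
        rng = np.random.default_rng(np.random.SeedSequence([params.subsample_seed, salt]))
        idx = np.sort(rng.choice(len(bundle), size=params.subsample, replace=False))
    return _bundle_array([bundle[i] for i in idx], params.n_resample_points)


def coverage(B1: Bundle, B2: Bundle, params: BAParams = BAParams()) -> float:
    """Fraction of B1's streamlines adjacent (MDF <= theta) to any in B2."""
    params.validate()
    if len(B1) == 0:
        raise ValueError("coverage is undefined for an empty B1")
    if len(B2) == 0:
        return 0.0
    a = _prepare(B1, params, salt=0)
    b = _prepare(B2, params, salt=1)
    dmin = mdf_matrix(a, b).min(axis=1)
    return float(np.mean(dmin <= params.theta))


def bundle_adjacency(B1: Bundle, B2: Bundle, params: BAParams = BAParams()) -> float:
    """Symmetric bundle-adjacency score 0.5 * (cov(B1,B2) + cov(B2,B1)).

    An empty bundle on either side yields 0 with a warning: a failed
    extraction means no shared shape, and must not abort a cohort run.
    """
    params.validate()
    if len(B1) == 0 or len(B2) == 0:
        warnings.warn("bundle_adjacency of an empty bundle is 0", stacklevel=2)
        return 0.0
    a = _prepare(B1, params, salt=0)
    b = _prepare(B2, params, salt=1)
    D = mdf_matrix(a, b)
    cov12 = float(np.mean(D.min(axis=1) <= params.theta))
    cov21 = float(np.mean(D.min(axis=0) <= params.theta))
    return 0.5 * (cov12 + cov21)


def pairwise_ba_matrix(
    bundles: Sequence[Bundle],
    params: BAParams = BAParams(),
    subject_ids: Optional[Sequence[str]] = None,
    method: str = "",
) -> SimilarityMatrix:
    """Fully connected shape-similarity network over a cohort of bundles.

    Each unordered pair is computed once from a shared MDF table and
    mirrored; the diagonal is 1 by definition for nonempty bundles.  Empty
    bundles produce zero rows/columns and are flagged in the result.
    """
    params.validate()
    n = len(bundles)
    if n < 2:
        raise ValueError("need at least 2 bundles")
    if subject_ids is None:
        subject_ids = [f"sub-{i:02d}" for i in range(n)]
    subject_ids = list(subject_ids)

    arrays = [_prepare(b, params, salt=i) for i, b in enumerate(bundles)]
    scores = np.zeros((n, n))
    empty = [subject_ids[i] for i in range(n) if len(arrays[i]) == 0]
    for i in range(n):
        if len(arrays[i]) > 0:
            scores[i, i] = 1.0
        for j in range(i + 1, n):
            if len(arrays[i]) == 0 or len(arrays[j]) == 0:
                continue
            D = mdf_matrix(arrays[i], arrays[j])
            cov_ij = float(np.mean(D.min(axis=1) <= params.theta))
            cov_ji = float(np.mean(D.min(axis=0) <= params.theta))
            scores[i, j] = scores[j, i] = 0.5 * (cov_ij + cov_ji)
    return SimilarityMatrix(
        scores=scores,
        subject_ids=subject_ids,
        method=method,
        theta=params.theta,
        empty_subjects=empty,
    )


def extract_bundle(
    t: Union[Tractogram, Bundle],
    model: Bundle,
    theta_extract: float,
    params: BAParams = BAParams(),
) -> list[np.ndarray]:
    """Model-proximity segmentation of a tractogram.

    Keeps every streamline whose minimum MDF to any model streamline is at
    most ``theta_extract`` (mm).  This is a deliberately simple reference
    bundle segmentation: the same threshold is applied to both tracking
    methods' tractograms so segmentation cannot favour either one.
    """
    params.validate()
    if theta_extract <= 0:
        raise ValueError("theta_extract must be positive")
    if len(model) == 0:
        raise ValueError("model bundle must be nonempty")
    streamlines = t.streamlines if isinstance(t, Tractogram) else list(t)
    if len(streamlines) == 0:
        warnings.warn("extracting from an empty tractogram", stacklevel=2)
        return []
    K = params.n_resample_points
    A = _bundle_array(streamlines, K)
    M = _bundle_array(model, K)
    dmin = mdf_matrix(A, M).min(axis=1)
    return [streamlines[i] for i in np.flatnonzero(dmin <= theta_extract)]
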