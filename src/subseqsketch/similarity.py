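"""Similarity and distance functions between sketches.

Cosine similarity is the default score: sketches of similar sequences have
large values at the same testing-subsequence indices, so their vectors
point in nearly the same direction.  For pairwise matrices the cosine path
is a single matrix product of row-normalized sketch matrices.  A set of
alternative vector metrics (Canberra, Bray-Curtis, correlation, Hamming,
Manhattan, squared Euclidean, Jaccard, Euclidean, Minkowski p=3, Chebyshev)
is provided for benchmarking against edit similarity.

Conventions: the cosine of an all-zero sketch against anything is 0 (such a
sketch shares no testing-subsequence content with any sequence); Hamming is
reported as a similarity (fraction of equal entries); Jaccard similarity is
one minus the proportion of disagreeing entries among entries where either
vector is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import distance as ssd

from .core import IncompatibleSketchError, InvalidInputError
from .sketch import Sketch, SketchSet

#: metric name -> (kind, is_similarity); kind names follow scipy where possible
SIMILARITY_METRICS = ("cosine", "correlation", "hamming", "jaccard")
DISTANCE_METRICS = (
    "canberra",
    "braycurtis",
    "manhattan",
    "sqeuclidean",
    "euclidean",
    "minkowski",
    "chebyshev",
)
METRICS = SIMILARITY_METRICS + DISTANCE_METRICS

_MINKOWSKI_P = 3  # p=1/2 would duplicate Manhattan/Euclidean


@dataclass
class SimilarityMatrix:
    """Pairwise scores between two sketch sets under one metric."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    metric: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise InvalidInputError("matrix shape does not match id lists")


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.testing_digest != b.testing_digest:
        raise IncompatibleSketchError(
            f"sketches come from different testing lists "
            f"({a.testing_digest} vs {b.testing_digest})"
        )
    if len(a) != len(b):
        raise IncompatibleSketchError(
            f"sketch lengths differ ({len(a)} vs {len(b)})"
        )


def _as_float(a: Sketch | np.ndarray) -> np.ndarray:
    return np.asarray(a.values if isinstance(a, Sketch) else a, dtype=float)


def cosine_similarity(a: Sketch, b: Sketch) -> float:
    """dot(a,b) / (||a|| ||b||); 0 when either vector is all-zero."""
    _check_compatible(a, b)
    u, v = _as_float(a), _as_float(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _metric_value(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            return 0.0
        return float(np.dot(u, v) / (nu * nv))
    if metric == "correlation":
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return 0.0
        return float(1.0 - ssd.correlation(u, v))
    if metric == "hamming":
        return float(np.mean(u == v))
    if metric == "jaccard":
        any_nonzero = (u != 0) | (v != 0)
        if not any_nonzero.any():
            return 1.0
        return float(1.0 - np.count_nonzero((u != v) & any_nonzero) / any_nonzero.sum())
    if metric == "canberra":
        return float(ssd.canberra(u, v))
    if metric == "braycurtis":
        return float(ssd.braycurtis(u, v))
    if metric == "manhattan":
        return float(ssd.cityblock(u, v))
    if metric == "sqeuclidean":
        return float(ssd.sqeuclidean(u, v))
    if metric == "euclidean":
        return float(ssd.euclidean(u, v))
    if metric == "minkowski":
        return float(ssd.minkowski(u, v, p=_MINKOWSKI_P))
    if metric == "chebyshev":
        return float(ssd.chebyshev(u, v))
    raise InvalidInputError(
        f"unknown metric {metric!r}; choose one of: {', '.join(METRICS)}"
    )


def sketch_metric(a: Sketch, b: Sketch, metric: str = "cosine") -> float:
    """Evaluate one named metric on a pair of compatible sketches."""
    if metric not in METRICS:
        raise InvalidInputError(
            f"unknown metric {metric!r}; choose one of: {', '.join(METRICS)}"
        )
    _check_compatible(a, b)
    return _metric_value(_as_float(a), _as_float(b), metric)


def is_similarity(metric: str) -> bool:
    return metric in SIMILARITY_METRICS


def pairwise_similarity(
    A: SketchSet,
    B: SketchSet | None = None,
    metric: str = "cosine",
) -> SimilarityMatrix:
    """All-vs-all metric values between two sketch sets.

    Cosine is computed as a row-normalized matrix product; the other
    metrics go through :func:`scipy.spatial.distance.cdist`.  Both paths
    agree with the per-pair functions to within 1e-9.
    """
    if metric not in METRICS:
        raise InvalidInputError(
            f"unknown metric {metric!r}; choose one of: {', '.join(METRICS)}"
        )
    if B is None:
        B = A
    if A.testing_digest != B.testing_digest:
        raise IncompatibleSketchError(
            f"sketch sets come from different testing lists "
            f"({A.testing_digest} vs {B.testing_digest})"
        )
    X = A.matrix().astype(float)
    Y = B.matrix().astype(float)
    if metric == "cosine":
        xn = np.linalg.norm(X, axis=1, keepdims=True)
        yn = np.linalg.norm(Y, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = (X / np.where(xn == 0, 1, xn)) @ (Y / np.where(yn == 0, 1, yn)).T
    elif metric == "correlation":
        const_x = np.ptp(X, axis=1) == 0
        const_y = np.ptp(Y, axis=1) == 0
        values = 1.0 - ssd.cdist(X, Y, "correlation")
        values[const_x, :] = 0.0
        values[:, const_y] = 0.0
    elif metric == "hamming":
        values = 1.0 - ssd.cdist(X, Y, "hamming")
    elif metric == "jaccard":
        # nonzero-agreement convention on integer vectors; cdist's jaccard
        # booleanizes its input, so compute it directly in blocks
        values = np.empty((X.shape[0], Y.shape[0]))
        for i0 in range(0, X.shape[0], 64):
            Xi = X[i0 : i0 + 64, None, :]
            diff = Xi != Y[None, :, :]
            union = ((Xi != 0) | (Y[None, :, :] != 0)).sum(axis=2)
            mism = (diff & ((Xi != 0) | (Y[None, :, :] != 0))).sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                values[i0 : i0 + 64] = np.where(
                    union == 0, 1.0, 1.0 - mism / np.maximum(union, 1)
                )
    elif metric == "manhattan":
        values = ssd.cdist(X, Y, "cityblock")
    elif metric == "minkowski":
        values = ssd.cdist(X, Y, "minkowski", p=_MINKOWSKI_P)
    else:
        values = ssd.cdist(X, Y, metric)
    return SimilarityMatrix(A.ids, B.ids, values, metric)


def to_distance(M: SimilarityMatrix) -> SimilarityMatrix:
    """Convert a [0,1] similarity matrix to distances 1 - s.

    The diagonal is forced to exactly 0 when row and column ids coincide,
    as required by neighbor joining.
    """
    if not is_similarity(M.metric):
        raise InvalidInputError(
            f"metric {M.metric!r} is a distance; to_distance needs a "
            "similarity in [0,1]"
        )
    values = 1.0 - M.values
    if M.row_ids == M.col_ids:
        np.fill_diagonal(values, 0.0)
    return SimilarityMatrix(M.row_ids, M.col_ids, values, f"{M.metric}-distance")


def min_max_normalize(M: SimilarityMatrix) -> SimilarityMatrix:
    """Min-max rescale values into [0,1] (used when plotting non-cosine
    metrics on a common axis); constant matrices map to 0."""
    v = M.values
    span = np.ptp(v)
    out = np.zeros_like(v) if span == 0 else (v - v.min()) / span
    return SimilarityMatrix(M.row_ids, M.col_ids, out, M.metric, normalized=True)
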