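"""Distance-covariance based dependence scores.

Three marginal dependence measures used for feature screening:

* ``mrdc`` — multivariate-rank distance correlation: both arguments are first
  mapped onto fixed reference grids by optimal transport (:mod:`.rankgrid`)
  and the distance-correlation V-statistic is computed on the rank vectors.
  Because the ranks live in the unit hypercube, the statistic is insensitive
  to heavy tails, outliers and monotone marginal transforms.
* ``dcor`` — the classical (raw-data) distance correlation of Székely,
  Rizzo & Bakirov, the score used by DC-SIS.
* ``pearson_score`` — absolute Pearson correlation, the score used by SIS.

All estimators are the plain V-statistics (1/n², 1/n³ normalisations); no
bias correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .rankgrid import generate_grid, multivariate_rank, univariate_rank

__all__ = ["DependenceScore", "mrdcov2", "mrdc", "dcor", "pearson_score"]

#: negative distance-covariance values above this are clamped to zero
_NEG_TOL = 1e-12


@dataclass(frozen=True)
class DependenceScore:
    """A scalar dependence score in [0, 1] with its provenance."""

    value: float
    method: str  # "mrdc" | "dcor" | "pearson-abs"
    n: int
    d_x: int
    d_y: int

    def __float__(self) -> float:
        return self.value


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def _dist_matrix(X: np.ndarray) -> np.ndarray:
    X = _as_2d(X)
    if X.shape[1] == 1:
        x = X[:, 0]
        return np.abs(x[:, None] - x[None, :])
    return squareform(pdist(X))


def _double_center(D: np.ndarray) -> np.ndarray:
    row = D.mean(axis=1, keepdims=True)
    col = D.mean(axis=0, keepdims=True)
    return D - row - col + D.mean()


def dcov2_from_distances(A: np.ndarray, B: np.ndarray) -> float:
    """Distance-covariance V-statistic from two pairwise-distance matrices.

    Uses the identity S1 + S2 - 2*S3 = mean(A~ ∘ B~) with both matrices
    double-centered; centering both keeps the value exactly symmetric under
    argument swap.
    """
    if A.shape != B.shape:
        raise ValueError("distance matrices must share shape")
    val = float((_double_center(A) * _double_center(B)).mean())
    if val < 0:
        if val < -_NEG_TOL:
            raise FloatingPointError(f"distance covariance {val} below -{_NEG_TOL}")
        val = 0.0
    return val


def mrdcov2(RX: np.ndarray, RY: np.ndarray) -> float:
    """Squared multivariate-rank distance covariance of two rank samples.

    ``RX`` and ``RY`` are ``(n, d1)`` and ``(n, d2)`` arrays of rank vectors
    (rows in the unit hypercube).  Returns the V-statistic
    ``MrS1 + MrS2 - 2 MrS3`` with Euclidean norms in the respective
    dimensions; always >= 0 up to numerical tolerance.
    """
    RX, RY = _as_2d(RX), _as_2d(RY)
    if RX.shape[0] != RY.shape[0]:
        raise ValueError(f"sample sizes differ: {RX.shape[0]} vs {RY.shape[0]}")
    return dcov2_from_distances(_dist_matrix(RX), _dist_matrix(RY))


@lru_cache(maxsize=32)
def grid_self_dcov2(n: int, d: int, kind: str | None = None) -> float:
    """dcov²(G, G) of the n-point reference grid in d dimensions.

    The rank map is a bijection onto the grid, so for any ranked sample the
    self distance covariance equals this constant — it depends only on
    (n, d, grid kind), never on the data.  Screening exploits this: the MrDc
    denominator is computed once per dimension instead of once per feature.
    """
    pts = generate_grid(n, d, kind=kind).points
    A = _dist_matrix(pts)
    Ac = _double_center(A)
    return float((Ac * Ac).mean())


def _rank_rows(X: np.ndarray, grid_kind: str | None = None) -> np.ndarray:
    X = _as_2d(X)
    if X.shape[1] == 1:
        return univariate_rank(X[:, 0]).ranks
    grid = generate_grid(X.shape[0], X.shape[1], kind=grid_kind)
    return multivariate_rank(X, grid).ranks


def mrdc(X: np.ndarray, Y: np.ndarray, *, grid_kind: str | None = None) -> DependenceScore:
    """Multivariate-rank distance correlation between two samples.

    Both samples are ranked separately (ordinary ranks i/n for 1-d margins,
    Sobol'-grid optimal transport otherwise), then

        MrDc = MrDcov(X, Y) / sqrt(MrDcov(X, X) · MrDcov(Y, Y)),

    where MrDcov = sqrt(MrDcov²).  The self terms equal the grid constants
    of :func:`grid_self_dcov2`.  The value lies in [0, 1]; 1 iff the rank
    maps coincide (e.g. ``mrdc(X, X)``).
    """
    X, Y = _as_2d(X), _as_2d(Y)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError(f"sample sizes differ: {n} vs {Y.shape[0]}")
    if n < 3:
        raise ValueError("need n >= 3 samples")
    RX = _rank_rows(X, grid_kind)
    RY = _rank_rows(Y, grid_kind)
    num = mrdcov2(RX, RY)
    cx = grid_self_dcov2(n, X.shape[1], grid_kind)
    cy = grid_self_dcov2(n, Y.shape[1], grid_kind)
    den = np.sqrt(cx * cy)
    value = float(np.sqrt(num / den)) if den > 0 else 0.0
    return DependenceScore(min(value, 1.0), "mrdc", n, X.shape[1], Y.shape[1])


def dcor(X: np.ndarray, Y: np.ndarray) -> DependenceScore:
    """Classical distance correlation (V-statistic) on the raw data."""
    X, Y = _as_2d(X), _as_2d(Y)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError(f"sample sizes differ: {n} vs {Y.shape[0]}")
    if n < 3:
        raise ValueError("need n >= 3 samples")
    A, B = _dist_matrix(X), _dist_matrix(Y)
    num = dcov2_from_distances(A, B)
    den = np.sqrt(dcov2_from_distances(A, A) * dcov2_from_distances(B, B))
    if den <= 0:
        warnings.warn("degenerate (constant) input: distance correlation set to 0")
        value = 0.0
    else:
        value = float(np.sqrt(num / den))
    return DependenceScore(min(value, 1.0), "dcor", n, X.shape[1], Y.shape[1])


def pearson_score(x: np.ndarray, y: np.ndarray) -> DependenceScore:
    """Absolute Pearson correlation of two 1-d samples (the SIS score)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return DependenceScore(min(abs(r), 1.0), "pearson-abs", x.shape[0], 1, 1)
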