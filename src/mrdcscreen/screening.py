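"""Marginal screening of high-dimensional predictors against a response.

The response matrix (n x q) is partitioned into consecutive small subgroups
of columns (default 5), and every predictor — possibly a multi-platform
vector, i.e. a slice of an (n, p, d) tensor — is scored against every
subgroup with a marginal dependence measure (``mrdc``, ``dcor`` or
``pearson-abs``).  Selection then uses the max-ratio criterion: sort the
scores, and cut at the largest ratio between consecutive sorted scores,
exploiting the gap between signal scores and near-zero noise scores.

Two summarisation directions are provided for the G x p score table:

* scenario 1 — one global max-ratio cut over all G·p scores, picking
  (subgroup, predictor) pairs with individually strong association;
* scenario 2 — a max-ratio cut within each subgroup, then per-predictor
  selection counts across subgroups, picking predictors weakly associated
  with many response components (the pleiotropy signature).

Implementation notes: scores are computed in vectorised chunks; pairwise
distance matrices are built per chunk of predictors and discarded, so the
peak memory is O(chunk · n²) no matter how large p is.  For ``mrdc`` the
self-distance-covariance of any ranked sample equals a grid constant
(see :func:`.dependence.grid_self_dcov2`), so only numerators are computed
per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dependence import dcov2_from_distances, grid_self_dcov2, _dist_matrix, _double_center
from .rankgrid import generate_grid, multivariate_rank

__all__ = [
    "PredictorTensor",
    "ScoreTable",
    "SelectionSummary",
    "subgroup_response",
    "screen",
    "max_ratio_cutoff",
    "select_scenario1",
    "select_scenario2",
]


@dataclass
class PredictorTensor:
    """n samples x p predictors x d platforms, with feature names.

    For single-platform data (d = 1) this is an ordinary n x p matrix with a
    trailing singleton axis.
    """

    values: np.ndarray
    predictor_names: list[str] | None = None
    platform_names: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3:
            raise ValueError("predictor values must be (n, p) or (n, p, d)")
        self.values = v
        if self.predictor_names is None:
            self.predictor_names = [f"X{j + 1}" for j in range(self.p)]
        if len(self.predictor_names) != self.p:
            raise ValueError("predictor_names length mismatch")
        if self.platform_names is None:
            self.platform_names = [f"platform{k + 1}" for k in range(self.d)]
        if len(self.platform_names) != self.d:
            raise ValueError("platform_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def d(self) -> int:
        return self.values.shape[2]

    def slice(self, j: int) -> np.ndarray:
        """The (n, d) data of predictor j (0-based)."""
        return self.values[:, j, :]


@dataclass
class ScoreTable:
    """G response-subgroups x p predictors of dependence scores.

    The flattened position of (subgroup g, predictor j), both 1-based, is
    ``(g - 1) * p + j`` — row-major over the score matrix.
    """

    scores: np.ndarray  # (G, p)
    group_size: int
    subgroup_spans: list[tuple[int, int]]  # 0-based half-open column ranges of Y
    predictor_names: list[str]
    method: str

    @property
    def n_groups(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    def flat_scores(self) -> np.ndarray:
        return self.scores.ravel()

    def flat_position(self, g: int, j: int) -> int:
        """1-based flattened position of 1-based (subgroup, predictor)."""
        return (g - 1) * self.p + j

    def to_frame(self):
        import pandas as pd

        G, p = self.scores.shape
        g_idx = np.repeat(np.arange(1, G + 1), p)
        j_idx = np.tile(np.arange(1, p + 1), G)
        return pd.DataFrame(
            {
                "subgroup": g_idx,
                "predictor": j_idx,
                "predictor_name": np.tile(np.asarray(self.predictor_names, dtype=object), G),
                "position": (g_idx - 1) * p + j_idx,
                "score": self.scores.ravel(),
            }
        )


@dataclass
class SelectionSummary:
    """Scenario-1 and scenario-2 summaries of a score table."""

    scenario1: list[tuple[int, int]] = field(default_factory=list)  # 1-based (g, j)
    scenario1_positions: list[int] = field(default_factory=list)
    per_predictor_max: np.ndarray | None = None
    per_predictor_count: np.ndarray | None = None
    scenario2_selected: list[int] | None = None  # 1-based predictor indices

    def to_frame(self, predictor_names: list[str]):
        import pandas as pd

        sel = set(self.scenario2_selected or [])
        return pd.DataFrame(
            {
                "predictor_name": predictor_names,
                "max_score": self.per_predictor_max,
                "count": self.per_predictor_count,
                "selected_flag": [int(j + 1 in sel) for j in range(len(predictor_names))],
            }
        )


def subgroup_response(Y: np.ndarray, group_size: int) -> list[tuple[int, int]]:
    """Half-open column spans partitioning an n x q response into blocks.

    Consecutive blocks of ``group_size`` columns; the last block is smaller
    when q is not a multiple.  ``group_size > q`` yields a single block with
    a warning.
    """
    Y = np.asarray(Y)
    q = Y.shape[1] if Y.ndim == 2 else 1
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > q:
        warnings.warn(f"group_size {group_size} exceeds q={q}; using a single block")
        return [(0, q)]
    starts = list(range(0, q, group_size))
    return [(s, min(s + group_size, q)) for s in starts]


def _univariate_rank_matrix(M: np.ndarray) -> np.ndarray:
    """Column-wise classical ranks i/n (stable ties), vectorised."""
    n = M.shape[0]
    order = np.argsort(M, axis=0, kind="stable")
    ranks = np.empty_like(M, dtype=float)
    rows = np.arange(1, n + 1, dtype=float)[:, None] / n
    np.put_along_axis(ranks, order, np.broadcast_to(rows, M.shape).copy(), axis=0)
    return ranks


def _predictor_rank_slices(X: PredictorTensor, grid_kind: str | None):
    """Yield (j, rank-rows) for each predictor."""
    n, p, d = X.values.shape
    if d == 1:
        R = _univariate_rank_matrix(X.values[:, :, 0])
        for j in range(p):
            yield j, R[:, j][:, None]
    else:
        grid = generate_grid(n, d, kind=grid_kind)
        for j in range(p):
            yield j, multivariate_rank(X.slice(j), grid).ranks


def _block_data(Y: np.ndarray, span: tuple[int, int]) -> np.ndarray:
    return Y[:, span[0]:span[1]]


def _rank_block(B: np.ndarray, grid_kind: str | None) -> np.ndarray:
    if B.shape[1] == 1:
        return _univariate_rank_matrix(B)
    grid = generate_grid(B.shape[0], B.shape[1], kind=grid_kind)
    return multivariate_rank(B, grid).ranks


def screen(
    Y: np.ndarray,
    X: PredictorTensor | np.ndarray,
    method: str = "mrdc",
    group_size: int = 5,
    *,
    grid_kind: str | None = None,
    chunk: int = 256,
    cache_response_ranks: bool = True,
) -> ScoreTable:
    """Score every predictor against every response subgroup.

    Parameters
    ----------
    Y
        ``(n, q)`` response matrix (a 1-d vector is treated as q = 1).
    X
        ``(n, p, d)`` predictor tensor or an ``(n, p)`` matrix.
    method
        ``"mrdc"`` (rank-based distance correlation), ``"dcor"`` (classical
        distance correlation, DC-SIS) or ``"pearson-abs"`` (SIS; requires
        q = 1 and d = 1).
    group_size
        Response columns per subgroup (default 5).
    chunk
        Number of predictor distance matrices held in memory at once.
    cache_response_ranks
        Compute each subgroup's rank map / centred distance matrix once and
        reuse it across all p predictors (identical results either way).
    """
    if not isinstance(X, PredictorTensor):
        X = PredictorTensor(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    if X.n != n:
        raise ValueError(f"sample mismatch: Y has n={n}, X has n={X.n}")
    if not np.isfinite(Y).all():
        raise ValueError("non-finite values in response")
    if method not in ("mrdc", "dcor", "pearson-abs"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pearson-abs" and (q != 1 or X.d != 1):
        raise ValueError("pearson-abs requires a 1-d response and single-platform predictors")

    spans = subgroup_response(Y, min(group_size, q))
    G, p, d = len(spans), X.p, X.d

    if method == "pearson-abs":
        y = Y[:, 0]
        M = X.values[:, :, 0]
        yc = y - y.mean()
        Mc = M - M.mean(axis=0)
        denom = np.sqrt((yc @ yc) * (Mc * Mc).sum(axis=0))
        with np.errstate(invalid="raise"):
            r = np.abs(Mc.T @ yc) / denom
        scores = r[None, :]
        return ScoreTable(scores, group_size, spans, X.predictor_names, method)

    def response_blocks():
        # centred response-block distance matrices (G, n, n) + self dcov2 terms
        Bc = np.empty((G, n, n))
        block_self = np.empty(G)
        for g, span in enumerate(spans):
            B = _block_data(Y, span)
            w = B.shape[1]
            if method == "mrdc":
                Dg = _dist_matrix(_rank_block(B, grid_kind))
                block_self[g] = grid_self_dcov2(n, w, "uniform-1d" if w == 1 else grid_kind)
            else:
                Dg = _dist_matrix(B)
                block_self[g] = dcov2_from_distances(Dg, Dg)
            Bc[g] = _double_center(Dg)
        return Bc, block_self

    cached = response_blocks() if cache_response_ranks else None

    scores = np.empty((G, p))
    if method == "mrdc":
        pred_self = grid_self_dcov2(n, d, "uniform-1d" if d == 1 else grid_kind)
        for j0, A in _chunked_distance_matrices(X, chunk, ranked=True, grid_kind=grid_kind):
            Bc, block_self = cached if cached is not None else response_blocks()
            den = np.sqrt(pred_self * block_self)  # (G,)
            num = np.einsum("jab,gab->gj", A, Bc) / (n * n)
            np.clip(num, 0.0, None, out=num)
            scores[:, j0:j0 + A.shape[0]] = np.sqrt(num / den[:, None])
    else:  # dcor
        for j0, A in _chunked_distance_matrices(X, chunk, ranked=False, grid_kind=grid_kind):
            Bc, block_self = cached if cached is not None else response_blocks()
            m = A.shape[0]
            # ||A~||^2/n^2 = mean(A^2) - 2 mean(rowmeans^2) + (mean A)^2
            row = A.mean(axis=2)
            self_j = np.einsum("jab,jab->j", A, A) / (n * n) \
                - 2.0 * (row * row).mean(axis=1) + row.mean(axis=1) ** 2
            np.clip(self_j, 0.0, None, out=self_j)
            num = np.einsum("jab,gab->gj", A, Bc) / (n * n)
            np.clip(num, 0.0, None, out=num)
            den = np.sqrt(self_j[None, :] * block_self[:, None])  # (G, m)
            with np.errstate(divide="ignore", invalid="ignore"):
                val = np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
            scores[:, j0:j0 + m] = val
    np.clip(scores, 0.0, 1.0, out=scores)
    return ScoreTable(scores, group_size, spans, X.predictor_names, method)


def _chunked_distance_matrices(X: PredictorTensor, chunk: int, *, ranked: bool,
                               grid_kind: str | None):
    """Yield (start index, (m, n, n) distance matrices) per predictor chunk.

    Distance matrices are built per chunk and discarded — never all p at
    once.  With ``ranked`` the distances are those of the optimal-transport
    rank rows (1-d margins use classical ranks).
    """
    n, p, d = X.values.shape
    if ranked and d == 1:
        R = _univariate_rank_matrix(X.values[:, :, 0])
        for j0 in range(0, p, chunk):
            r = R[:, j0:j0 + chunk].T  # (m, n)
            yield j0, np.abs(r[:, :, None] - r[:, None, :])
    elif d == 1:
        M = X.values[:, :, 0]
        for j0 in range(0, p, chunk):
            v = M[:, j0:j0 + chunk].T
            yield j0, np.abs(v[:, :, None] - v[:, None, :])
    else:
        grid = generate_grid(n, d, kind=grid_kind) if ranked else None
        for j0 in range(0, p, chunk):
            m = min(chunk, p - j0)
            A = np.empty((m, n, n))
            for k in range(m):
                data = X.slice(j0 + k)
                if ranked:
                    data = multivariate_rank(data, grid).ranks
                A[k] = _dist_matrix(data)
            yield j0, A


def max_ratio_cutoff(scores: np.ndarray, *, search_frac: float = 0.5,
                     denom_floor: float = 1e-12) -> int:
    """Selection size from the max-ratio criterion on descending scores.

    Given scores sorted in descending order w_(1) >= ... >= w_(J), returns
    s0 = argmax_j w_(j) / w_(j+1): noise scores sit near zero, so the
    largest consecutive ratio marks the signal/noise gap.  The search is
    restricted to the top ``search_frac`` fraction of positions (ratios deep
    in the near-zero tail explode spuriously) and stops where the
    denominator falls below ``denom_floor``.  Ties pick the smallest j.
    """
    w = np.asarray(scores, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("need at least 2 sorted scores")
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("scores must be sorted in descending order")
    J = int(min(w.size - 1, np.ceil(w.size * search_frac)))
    num, den = w[:J], w[1:J + 1]
    valid = den >= denom_floor
    if not valid.any():
        warnings.warn("all consecutive scores below the denominator floor; selecting 1")
        return 1
    ratios = np.where(valid, num / np.where(valid, den, 1.0), -np.inf)
    s0 = int(np.argmax(ratios)) + 1
    if np.all(np.abs(ratios[valid] - ratios[valid][0]) < 1e-12) and valid.sum() > 1:
        warnings.warn("no separable gap in the score sequence; selecting 1")
        return 1
    return s0


def select_scenario1(table: ScoreTable, **cut_kwargs) -> SelectionSummary:
    """Global max-ratio cut over all G·p scores (strong single associations)."""
    flat = table.flat_scores()
    order = np.lexsort((np.arange(flat.size), -flat))
    s0 = max_ratio_cutoff(flat[order], **cut_kwargs)
    top = order[:s0]
    p = table.p
    pairs = [(int(pos // p) + 1, int(pos % p) + 1) for pos in top]
    summary = SelectionSummary(
        scenario1=pairs,
        scenario1_positions=[int(pos) + 1 for pos in top],
    )
    return summary


def select_scenario2(table: ScoreTable, *, top_k: int | None = None,
                     **cut_kwargs) -> SelectionSummary:
    """Per-subgroup max-ratio cuts, then per-predictor counts across subgroups.

    A predictor weakly linked to many response components accumulates a high
    count even though no single score stands out — the pleiotropy signature.
    The default final call applies the max-ratio criterion to the sorted
    counts; ``top_k`` overrides it.
    """
    G, p = table.scores.shape
    counts = np.zeros(p, dtype=int)
    for g in range(G):
        row = table.scores[g]
        order = np.lexsort((np.arange(p), -row))
        s0 = max_ratio_cutoff(row[order], **cut_kwargs)
        counts[order[:s0]] += 1
    per_max = table.scores.max(axis=0)
    order = np.lexsort((np.arange(p), -counts.astype(float)))
    if top_k is not None:
        sel = order[:top_k]
    elif p >= 2 and counts[order[0]] > 0:
        sorted_counts = counts[order].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k = max_ratio_cutoff(sorted_counts, **cut_kwargs)
        sel = order[:k]
    else:
        sel = order[:0]
    return SelectionSummary(
        per_predictor_max=per_max,
        per_predictor_count=counts,
        scenario2_selected=[int(j) + 1 for j in sel],
    )
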