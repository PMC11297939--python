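"""Screening-performance metrics across simulation replicates.

Three standard criteria for marginal screening procedures:

* S — the minimum model size: the smallest number of top-ranked scores
  needed to capture every true (subgroup, predictor) score.  Reported as
  25th/50th/95th percentiles across replicates (linear interpolation, so
  fractional values are possible).
* P_s — per-truth success rate: the fraction of replicates in which a given
  true score ranks within a predetermined cutoff.
* P_a — simultaneous success rate: the fraction of replicates in which all
  true scores rank within the cutoff, i.e. S <= cutoff.  Always bounded
  above by the smallest P_s.

The conventional cutoffs are s1 = [n / log n] (floor), s2 = 2 s1 and
s3 = 3 s1 (37, 74, 111 at n = 200).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .screening import ScoreTable

__all__ = [
    "ReplicateMetrics",
    "cutoff_s",
    "truth_ranks",
    "min_model_size",
    "success_rates",
    "s_percentiles",
    "summarize",
]


@dataclass
class ReplicateMetrics:
    """Ranks of the true scores within one replicate's screening output."""

    truth_positions: list[int]  # 1-based flattened positions
    truth_ranks: np.ndarray  # descending-score rank of each truth position
    S: int  # max(truth_ranks): minimum model size
    total: int  # total number of scores ranked


def cutoff_s(n: int, multiplier: int = 1) -> int:
    """The predetermined cutoff multiplier * floor(n / ln n)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if multiplier < 1:
        raise ValueError("multiplier must be a positive integer")
    return multiplier * int(np.floor(n / np.log(n)))


def _flat_scores(table) -> np.ndarray:
    if isinstance(table, ScoreTable):
        return table.flat_scores()
    return np.asarray(table, dtype=float).ravel()


def truth_ranks(table, truth_positions) -> ReplicateMetrics:
    """Descending-score ranks of the truth positions among all scores.

    Scores are ranked from largest to smallest; ties are broken by flattened
    position (deterministic).  ``truth_positions`` are 1-based flattened
    indices under the (g - 1) * p + j convention.
    """
    flat = _flat_scores(table)
    pos = np.asarray(truth_positions, dtype=np.intp)
    if pos.size == 0:
        raise ValueError("empty truth set")
    if pos.min() < 1 or pos.max() > flat.size:
        raise ValueError("truth position out of bounds")
    order = np.lexsort((np.arange(flat.size), -flat))
    rank_of = np.empty(flat.size, dtype=np.intp)
    rank_of[order] = np.arange(1, flat.size + 1)
    ranks = rank_of[pos - 1]
    return ReplicateMetrics(
        truth_positions=[int(t) for t in pos],
        truth_ranks=ranks,
        S=int(ranks.max()),
        total=flat.size,
    )


def min_model_size(table, truth_positions) -> int:
    """Smallest top-score set containing every truth position."""
    return truth_ranks(table, truth_positions).S


def success_rates(replicates: list[ReplicateMetrics], cutoffs: list[int]):
    """P_s per truth position and P_a per cutoff across replicates.

    Returns ``(P_s, P_a)`` where ``P_s`` is a (len(cutoffs), n_truth) array
    and ``P_a`` a (len(cutoffs),) array.  P_a <= min_t P_s for every cutoff.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    ranks = np.vstack([r.truth_ranks for r in replicates])  # (R, T)
    cut = np.asarray(cutoffs, dtype=float)[:, None, None]  # (C, 1, 1)
    hits = ranks[None, :, :] <= cut  # (C, R, T)
    P_s = hits.mean(axis=1)
    P_a = hits.all(axis=2).mean(axis=1)
    return P_s, P_a


def s_percentiles(replicates: list[ReplicateMetrics],
                  q=(25, 50, 95)) -> np.ndarray:
    """Interpolated percentiles of the minimum model size across replicates."""
    if not replicates:
        raise ValueError("need at least one replicate")
    S = np.array([r.S for r in replicates], dtype=float)
    return np.percentile(S, q)  # linear interpolation (type-7)


def summarize(replicates: list[ReplicateMetrics], n: int, method: str = ""):
    """Per-method report: S percentiles plus P_s / P_a at s1, s2, s3."""
    import pandas as pd

    cuts = [cutoff_s(n, m) for m in (1, 2, 3)]
    P_s, P_a = success_rates(replicates, cuts)
    pct = s_percentiles(replicates)
    rows = []
    for i, (mult, c) in enumerate(zip((1, 2, 3), cuts)):
        row = {
            "method": method,
            "S_percentile": (25, 50, 95)[i],
            "S": pct[i],
            "cutoff": f"s{mult}={c}",
        }
        for t, posrank in enumerate(P_s[i]):
            row[f"P_truth{t + 1}"] = posrank
        row["P_a"] = P_a[i]
        rows.append(row)
    return pd.DataFrame(rows)
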