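"""Reference grids on the unit hypercube and empirical multivariate ranks.

The multivariate rank of a d-dimensional sample is defined through optimal
transport: the n observed points are matched one-to-one onto n fixed
"uniform-like" points in [0, 1]^d so that the total squared displacement is
minimised (equivalently, the total inner product is maximised).  For d = 1
this reduces to ordinary ranks i/n obtained by sorting; for d > 1 the target
points are taken from a low-discrepancy (quasi-Monte Carlo) sequence and the
matching is solved as a linear assignment problem.

Because the target grid is a fixed, deterministic point set, the rank map is
reproducible bit-for-bit across machines, and the multiset of rank vectors is
always exactly the grid itself — a property downstream dependence measures
exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import qmc

__all__ = ["ReferenceGrid", "RankedSample", "generate_grid", "univariate_rank", "multivariate_rank"]


@dataclass(frozen=True)
class ReferenceGrid:
    """A discrete approximation of the uniform distribution on (0, 1]^d.

    Attributes
    ----------
    points
        ``(n, d)`` array of grid coordinates, all in ``(0, 1]`` and pairwise
        distinct.
    kind
        ``"uniform-1d"`` for the exact 1-d lattice ``{i/n}`` or ``"sobol"``
        for the unscrambled Sobol' sequence with the origin skipped.
    """

    points: np.ndarray
    kind: str

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        if self.points.ndim != 2:
            raise ValueError("grid points must be a 2-d array")

    def to_tsv(self, path) -> None:
        """Dump the grid points as TSV (debugging aid)."""
        header = "\t".join(f"dim{k + 1}" for k in range(self.d))
        np.savetxt(path, self.points, delimiter="\t", header=header, comments="")


@dataclass
class RankedSample:
    """An observed sample together with its optimal-transport rank map.

    ``assignment[i]`` is the index of the grid point that sample row ``i``
    was transported to; ``ranks`` is therefore a row permutation of
    ``grid.points``.
    """

    data: np.ndarray
    grid: ReferenceGrid
    assignment: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.intp)
        n = self.grid.n
        if sorted(self.assignment.tolist()) != list(range(n)):
            raise ValueError("assignment must be a permutation of 0..n-1")
        self.ranks = self.grid.points[self.assignment]


def generate_grid(n: int, d: int, *, kind: str | None = None, scramble: bool = False,
                  skip_origin: bool = True, seed: int | None = None) -> ReferenceGrid:
    """Generate the n-point reference grid in (0, 1]^d.

    For ``d == 1`` the grid is the exact lattice ``{i/n : i = 1..n}``.  For
    ``d > 1`` it is the unscrambled Sobol' sequence (Joe–Kuo direction
    numbers, as implemented in :mod:`scipy.stats.qmc`) with the all-zeros
    origin point dropped, so that every coordinate is strictly positive.
    Scrambling is off by default: a fixed point set makes every downstream
    statistic exactly reproducible across machines.

    Parameters
    ----------
    n, d
        Number of grid points and dimension; ``n >= 2``, ``d >= 1``.
    kind
        Force ``"uniform-1d"`` or ``"sobol"``; defaults to uniform-1d when
        ``d == 1`` and Sobol' otherwise.
    scramble, seed
        Optional Owen scrambling of the Sobol' points (off by default).
    skip_origin
        Drop the leading all-zeros Sobol' point (default).  Points containing
        a zero coordinate are always discarded so the grid lies in (0, 1]^d.
    """
    if n < 2:
        raise ValueError(f"need at least 2 grid points, got n={n}")
    if d < 1:
        raise ValueError(f"dimension must be positive, got d={d}")
    if kind is None:
        kind = "uniform-1d" if d == 1 else "sobol"
    if kind == "uniform-1d":
        if d != 1:
            raise ValueError("uniform-1d grids are one-dimensional")
        pts = (np.arange(1, n + 1, dtype=float) / n)[:, None]
        return ReferenceGrid(pts, "uniform-1d")
    if kind != "sobol":
        raise ValueError(f"unknown grid kind {kind!r}")

    engine = qmc.Sobol(d, scramble=scramble, seed=seed)
    collected: list[np.ndarray] = []
    remaining = n + (1 if skip_origin and not scramble else 0)
    first_block = True
    while remaining > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # power-of-two balance note
            block = engine.random(max(remaining, 64))
        if first_block and skip_origin and not scramble:
            block = block[1:]
            first_block = False
        block = block[(block > 0).all(axis=1)]  # keep strictly inside (0, 1]
        collected.append(block)
        remaining = n - sum(len(b) for b in collected)
    pts = np.concatenate(collected)[:n]
    return ReferenceGrid(pts, "sobol")


def univariate_rank(x: np.ndarray) -> RankedSample:
    """Classical ranks i/n, expressed as a transport onto the 1-d grid.

    ``ranks[i]`` is the position of ``x[i]`` in ascending order divided by n;
    ties are broken stably by original index.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite value at index {bad[0]}")
    order = np.argsort(x, kind="stable")
    assignment = np.empty(n, dtype=np.intp)
    assignment[order] = np.arange(n)
    grid = generate_grid(n, 1, kind="uniform-1d")
    return RankedSample(x[:, None], grid, assignment)


def multivariate_rank(X: np.ndarray, grid: ReferenceGrid) -> RankedSample:
    """Optimal-transport rank of an ``(n, d)`` sample onto a reference grid.

    Solves the linear assignment problem maximising the total inner product
    sum_i <X_i, h_sigma(i)> (equivalently minimising the total squared
    transport cost) with the Hungarian-type solver of
    :func:`scipy.optimize.linear_sum_assignment`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape != (grid.n, grid.d):
        raise ValueError(f"sample shape {X.shape} does not match grid ({grid.n}, {grid.d})")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
    cost = -(X @ grid.points.T)
    _, assignment = linear_sum_assignment(cost)
    return RankedSample(X, grid, assignment)
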