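"""Synthetic multi-omics screening benchmarks with known truth.

Four generator families emulate the regimes a marginal screening procedure
faces with real multi-platform genomic data: ultrahigh-dimensional,
heavy-tailed (multivariate-t with 1–3 degrees of freedom), serially
correlated predictors (AR(1) scale structure, rho = 0.8 by default), and a
response that is mostly noise.

* study 1 — univariate response, linear + square links, t1 margins.
* study 2 — univariate response, log / square / absolute-value links.
* study 3 — three predictor platforms (t2, t1, t3), 10k-scale response with
  only its first 12 coordinates carrying signal through one platform each of
  two predictors (signal-to-noise ratio ~1.2% at q = 10,000).
* study 4 — single signal response coordinate among q - 1 noise coordinates,
  four true predictors (one through a square link), q varied to trace how
  performance degrades as the response gets noisier.

Every random draw (coefficients, platform choices, noise) is recorded in the
returned truth metadata, so evaluation never re-derives the truth from data.
All generators are bit-reproducible from (config, seed) via
``numpy.random.default_rng``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .screening import PredictorTensor, subgroup_response

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sample_mvt_ar1",
    "gen_study1",
    "gen_study2",
    "gen_study3",
    "gen_study4",
    "generate",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic replicate.

    Defaults follow the benchmark design: n = 200 samples, AR(1) parameter
    rho = 0.8, coefficient ranges Uniform(2, 5) for the univariate-response
    studies, Uniform(4, 5) for study 3 and Uniform(1, 2) for study 4.
    """

    study: str = "study1"
    n: int = 200
    p: int = 10_000
    q: int = 1
    rho: float = 0.8
    dfs: tuple[int, ...] = (1,)
    beta_range: tuple[float, float] | None = None
    seed: int = 0
    per_dim_platforms: bool = False  # study 3: redraw platform ids per response dim

    def __post_init__(self):
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if any(df < 1 for df in self.dfs):
            raise ValueError("degrees of freedom must be >= 1")
        if self.beta_range is not None and self.beta_range[0] >= self.beta_range[1]:
            raise ValueError("beta_range must be (low, high) with low < high")


@dataclass
class SimulatedDataset:
    """Generated data plus complete truth bookkeeping."""

    X: PredictorTensor
    Y: np.ndarray  # (n, q)
    config: SimulationConfig
    truth_predictors: list[int]  # 1-based predictor indices
    truth_response_dims: list[int]  # 1-based response column indices
    truth_platforms: dict[int, list[int]] = field(default_factory=dict)  # predictor -> ids
    betas: np.ndarray | None = None

    def truth_positions(self, group_size: int) -> list[int]:
        """1-based flattened (subgroup, predictor) positions of all truth scores.

        A (subgroup, predictor) pair counts as truth when the subgroup
        contains at least one signal response dimension; position is
        (g - 1) * p + j under the row-major flattening convention.
        """
        spans = subgroup_response(self.Y, min(group_size, self.Y.shape[1]))
        p = self.X.p
        truth_dims = set(self.truth_response_dims)
        positions = []
        for g, (lo, hi) in enumerate(spans, start=1):
            if truth_dims.intersection(range(lo + 1, hi + 1)):
                positions.extend((g - 1) * p + j for j in self.truth_predictors)
        return positions

    def truth_json(self) -> str:
        return json.dumps(
            {
                "study": self.config.study,
                "config": {k: v for k, v in asdict(self.config).items()},
                "truth_predictors": self.truth_predictors,
                "truth_response_dims": self.truth_response_dims,
                "truth_platforms": {str(k): v for k, v in self.truth_platforms.items()},
                "betas": None if self.betas is None else list(map(float, self.betas)),
            },
            indent=1,
        )


def _gaussian_ar1(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """n rows from N(0, Sigma) with Sigma_jk = rho^|j-k|, never forming Sigma.

    Sequential construction Z_j = rho Z_{j-1} + sqrt(1 - rho^2) eps_j,
    vectorised across rows with an IIR filter.
    """
    eps = rng.standard_normal((n, p))
    eps[:, 1:] *= np.sqrt(1.0 - rho * rho)
    return lfilter([1.0], [1.0, -rho], eps, axis=1)


def sample_mvt_ar1(n: int, p: int, df: float, rho: float,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """i.i.d. rows from a multivariate t with AR(1) scale matrix.

    Each row is Z / sqrt(W / df) with Z ~ N(0, Sigma_AR1(rho)) and
    W ~ chi^2_df.  For df = 1 the marginals are Cauchy: moments do not
    exist, and Sigma is the scale matrix of the Gaussian core rather than a
    covariance.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Z = _gaussian_ar1(n, p, rho, rng)
    W = rng.chisquare(df, size=n)
    return Z / np.sqrt(W / df)[:, None]


def _betas(rng, k, beta_range):
    lo, hi = beta_range
    return rng.uniform(lo, hi, size=k)


def gen_study1(config: SimulationConfig) -> SimulatedDataset:
    """Univariate response with simple links: y = b1 X1 + b2 X6 + b3 X12^2 + b4 X22 + e."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    X = sample_mvt_ar1(n, p, config.dfs[0], config.rho, rng)
    beta = _betas(rng, 4, config.beta_range or (2.0, 5.0))
    eps = rng.standard_t(1, size=n)
    y = beta[0] * X[:, 0] + beta[1] * X[:, 5] + beta[2] * X[:, 11] ** 2 \
        + beta[3] * X[:, 21] + eps
    return SimulatedDataset(
        PredictorTensor(X), y[:, None], config,
        truth_predictors=[1, 6, 12, 22], truth_response_dims=[1], betas=beta,
    )


def gen_study2(config: SimulationConfig) -> SimulatedDataset:
    """Univariate response with nonlinear links: log, square and absolute value.

    y = b1 X1 + b2 log|X6| + b3 X12^2 + b4 |X22| + e.  The log link is
    applied to |X6| because the t1 margin is real-valued.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    X = sample_mvt_ar1(n, p, config.dfs[0], config.rho, rng)
    beta = _betas(rng, 4, config.beta_range or (2.0, 5.0))
    eps = rng.standard_t(1, size=n)
    y = beta[0] * X[:, 0] + beta[1] * np.log(np.abs(X[:, 5])) \
        + beta[2] * X[:, 11] ** 2 + beta[3] * np.abs(X[:, 21]) + eps
    return SimulatedDataset(
        PredictorTensor(X), y[:, None], config,
        truth_predictors=[1, 6, 12, 22], truth_response_dims=[1], betas=beta,
    )


def _three_platform_tensor(config: SimulationConfig, rng) -> PredictorTensor:
    dfs = config.dfs if len(config.dfs) == 3 else (2, 1, 3)
    slabs = [sample_mvt_ar1(config.n, config.p, df, config.rho, rng) for df in dfs]
    values = np.stack(slabs, axis=2)
    names = [f"df{df}" for df in dfs]
    return PredictorTensor(values, platform_names=names)


def gen_study3(config: SimulationConfig) -> SimulatedDataset:
    """Three platforms (t2, t1, t3); response dims 1..12 linked to predictors 2, 4.

    Y_k = b1 X_{2, id1} + b2 X_{4, id2} + e for k = 1..12 with
    b ~ Uniform(4, 5) and platform ids drawn from {1, 2, 3}; remaining
    response dims are t1 noise.  By default one (id1, id2) pair is shared by
    all 12 signal dimensions; ``per_dim_platforms`` redraws them per
    dimension.
    """
    if config.q < 12:
        raise ValueError("study 3 requires q >= 12 (the first 12 response dims carry signal)")
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n, config.p, config.q
    X = _three_platform_tensor(config, rng)
    beta_range = config.beta_range or (4.0, 5.0)
    Y = rng.standard_t(1, size=(n, q))
    n_signal = 12
    platforms: dict[int, list[int]] = {2: [], 4: []}
    if config.per_dim_platforms:
        betas = _betas(rng, 2 * n_signal, beta_range).reshape(n_signal, 2)
        for k in range(n_signal):
            id1, id2 = rng.integers(1, 4, size=2)
            platforms[2].append(int(id1))
            platforms[4].append(int(id2))
            Y[:, k] += betas[k, 0] * X.values[:, 1, id1 - 1] \
                + betas[k, 1] * X.values[:, 3, id2 - 1]
        beta_out = betas.ravel()
    else:
        beta = _betas(rng, 2, beta_range)
        id1, id2 = rng.integers(1, 4, size=2)
        platforms[2] = [int(id1)]
        platforms[4] = [int(id2)]
        signal = beta[0] * X.values[:, 1, id1 - 1] + beta[1] * X.values[:, 3, id2 - 1]
        Y[:, :n_signal] += signal[:, None]
        beta_out = beta
    return SimulatedDataset(
        X, Y, config,
        truth_predictors=[2, 4],
        truth_response_dims=list(range(1, n_signal + 1)),
        truth_platforms=platforms,
        betas=beta_out,
    )


def gen_study4(config: SimulationConfig) -> SimulatedDataset:
    """Three platforms; only Y_1 carries signal from predictors 2, 4, 101, 102.

    Y_1 = b1 X_{2,id1} + b2 X_{4,id2} + b3 X_{101,id3} + b4 X_{102,id4}^2 + e
    with b ~ Uniform(1, 2); Y_2..Y_q are t1 noise.
    """
    if config.q < 2:
        raise ValueError("study 4 requires q >= 2")
    if config.p < 102:
        raise ValueError("study 4 requires p >= 102 (truth at predictors 101, 102)")
    rng = np.random.default_rng(config.seed)
    n, q = config.n, config.q
    X = _three_platform_tensor(config, rng)
    beta = _betas(rng, 4, config.beta_range or (1.0, 2.0))
    ids = rng.integers(1, 4, size=4)
    Y = rng.standard_t(1, size=(n, q))
    Y[:, 0] += beta[0] * X.values[:, 1, ids[0] - 1] + beta[1] * X.values[:, 3, ids[1] - 1] \
        + beta[2] * X.values[:, 100, ids[2] - 1] + beta[3] * X.values[:, 101, ids[3] - 1] ** 2
    return SimulatedDataset(
        X, Y, config,
        truth_predictors=[2, 4, 101, 102],
        truth_response_dims=[1],
        truth_platforms={2: [int(ids[0])], 4: [int(ids[1])],
                         101: [int(ids[2])], 102: [int(ids[3])]},
        betas=beta,
    )


_GENERATORS = {
    "study1": gen_study1,
    "study2": gen_study2,
    "study3": gen_study3,
    "study4": gen_study4,
}


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Dispatch to the generator named by ``config.study``."""
    try:
        gen = _GENERATORS[config.study]
    except KeyError:
        raise ValueError(f"unknown study {config.study!r}") from None
    return gen(config)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Write X (one TSV per platform), Y (TSV) and truth metadata (JSON)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"S{i + 1}" for i in range(ds.X.n)]
    for k, name in enumerate(ds.X.platform_names):
        df = pd.DataFrame(ds.X.values[:, :, k], index=sample_ids,
                          columns=ds.X.predictor_names)
        df.to_csv(out / f"X_{name}.tsv", sep="\t", index_label="sample_id")
    ydf = pd.DataFrame(ds.Y, index=sample_ids,
                       columns=[f"Y{j + 1}" for j in range(ds.Y.shape[1])])
    ydf.to_csv(out / "Y.tsv", sep="\t", index_label="sample_id")
    (out / "truth.json").write_text(ds.truth_json())
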