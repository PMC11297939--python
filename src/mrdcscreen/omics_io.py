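"""Delimited omics matrices: reading, platform filters and tensor assembly.

Platform matrices arrive as TSV/CSV with a header row and an ID column, in
either orientation (samples in rows or features in rows); everything is
normalised to samples-in-rows.  The preprocessing filters are the generic
forms of the usual expression-matrix hygiene steps:

* prevalence filter — keep features exceeding a value threshold in a
  minimum fraction of samples (e.g. expression > 1 in 70% of samples for
  RNA-seq, > 10 in 80% for miRNA);
* pooled-quantile filter — drop features whose maximum never reaches the
  25% quantile of all pooled nonzero values (methylation);
* exact-duplicate removal — collapse features with identical value vectors
  across all samples (copy-number segments mapped to several gene names).

``match_platforms`` intersects feature names and sample ids across platforms
and stacks the matched slices into the (n, p, d) predictor tensor consumed
by :func:`mrdcscreen.screening.screen`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import PredictorTensor

__all__ = [
    "PlatformMatrix",
    "read_matrix",
    "write_matrix",
    "filter_prevalence",
    "filter_methylation_quantile",
    "dedupe_identical_features",
    "match_platforms",
]

log = logging.getLogger("mrdcscreen")


@dataclass
class PlatformMatrix:
    """A samples-in-rows numeric matrix with ids and a platform tag."""

    values: np.ndarray  # (n, m)
    sample_ids: list[str]
    feature_names: list[str]
    platform: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("platform matrix must be 2-d")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_names) != m:
            raise ValueError("id/name lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def _keep(self, mask: np.ndarray, why: str) -> "PlatformMatrix":
        dropped = [f for f, k in zip(self.feature_names, mask) if not k]
        if dropped:
            log.info("%s: dropping %d/%d features (%s)", self.platform or "matrix",
                     len(dropped), self.m, why)
            log.debug("dropped: %s", ", ".join(dropped[:50]))
        return replace(self, values=self.values[:, mask],
                       feature_names=[f for f, k in zip(self.feature_names, mask) if k])


def read_matrix(path: str | Path, orientation: str = "samples-in-rows",
                *, sep: str | None = None, na_policy: str = "drop-feature",
                platform: str = "") -> PlatformMatrix:
    """Read a delimited matrix into samples-in-rows form.

    Parameters
    ----------
    orientation
        ``"samples-in-rows"`` or ``"features-in-rows"`` (transposed on read).
    sep
        Field separator; inferred from the extension by default
        (``.csv`` -> comma, otherwise tab).
    na_policy
        ``"drop-feature"`` removes any feature column containing missing
        values (logged); ``"error"`` raises.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column ids")
    if orientation == "features-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    na_cols = df.columns[df.isna().any(axis=0)]
    if len(na_cols):
        if na_policy == "error":
            raise ValueError(f"{path}: missing values in features {list(na_cols)[:10]}")
        log.info("%s: dropping %d features with missing values", path.name, len(na_cols))
        df = df.drop(columns=na_cols)
    mat = PlatformMatrix(df.to_numpy(), [str(i) for i in df.index],
                         [str(c) for c in df.columns], platform or path.stem)
    log.info("%s: read %d samples x %d features", path.name, mat.n, mat.m)
    return mat


def write_matrix(M: PlatformMatrix, path: str | Path, *, sep: str = "\t") -> None:
    df = pd.DataFrame(M.values, index=M.sample_ids, columns=M.feature_names)
    df.to_csv(path, sep=sep, index_label="sample_id")


def filter_prevalence(M: PlatformMatrix, min_value: float,
                      min_fraction: float) -> PlatformMatrix:
    """Keep features with value > min_value in at least ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    need = int(np.ceil(min_fraction * M.n))
    counts = (M.values > min_value).sum(axis=0)
    return M._keep(counts >= need, f"value > {min_value} in < {min_fraction:.0%} of samples")


def filter_methylation_quantile(M: PlatformMatrix, *, quantile: float = 0.25) -> PlatformMatrix:
    """Drop features whose maximum is below the pooled nonzero-value quantile.

    Zeros are removed from the pooled value list, the quantile (default 25%,
    linear interpolation) is taken over what remains, and features whose
    per-feature maximum is strictly below it are dropped.
    """
    pooled = M.values[M.values != 0]
    if pooled.size == 0:
        raise ValueError("all-zero matrix: pooled quantile undefined")
    thr = float(np.quantile(pooled, quantile))
    keep = M.values.max(axis=0) >= thr
    return M._keep(keep, f"max below pooled {quantile:.0%} quantile {thr:.4g}")


def dedupe_identical_features(M: PlatformMatrix) -> PlatformMatrix:
    """Among features with exactly identical value vectors, keep the first."""
    _, first_idx = np.unique(M.values.T, axis=0, return_index=True)
    keep = np.zeros(M.m, dtype=bool)
    keep[first_idx] = True
    return M._keep(keep, "identical value vector of an earlier feature")


def match_platforms(platforms: list[PlatformMatrix]) -> PredictorTensor:
    """Stack >= 2 platforms into an (n, p, d) tensor over shared genes/samples.

    Feature names are intersected across platforms (order taken from the
    first platform), sample ids likewise; rows are aligned by id before
    stacking, so input row order is irrelevant.
    """
    if len(platforms) < 2:
        raise ValueError("need at least two platforms to match")
    feats = [f for f in platforms[0].feature_names
             if all(f in set(m.feature_names) for m in platforms[1:])]
    samples = [s for s in platforms[0].sample_ids
               if all(s in set(m.sample_ids) for m in platforms[1:])]
    if not feats:
        raise ValueError("no features shared across platforms")
    if not samples:
        raise ValueError("no samples shared across platforms")
    slabs = []
    for m in platforms:
        df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_names)
        slabs.append(df.loc[samples, feats].to_numpy())
    tensor = np.stack(slabs, axis=2)
    log.info("matched %d platforms: %d samples x %d features x %d",
             len(platforms), len(samples), len(feats), len(platforms))
    return PredictorTensor(tensor, predictor_names=feats,
                           platform_names=[m.platform or f"platform{i + 1}"
                                           for i, m in enumerate(platforms)])
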