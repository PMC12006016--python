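"""Probe-to-gene summarization and quantile normalization.

Microarray intensities arrive as a probes x samples matrix on the log2
scale.  Probes are collapsed to one row per gene (median by default) and the
gene-level matrix is quantile-normalized so every sample shares the same
empirical intensity distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["summarize_probes", "quantile_normalize", "log2_transform"]


def summarize_probes(
    probe_matrix: pd.DataFrame,
    probe_map: pd.Series | dict,
    method: str = "median",
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Parameters
    ----------
    probe_matrix : DataFrame
        Probe-level intensities, probe ids on the index.
    probe_map : Series or dict
        Many-to-one mapping probe id -> gene id; every probe in the matrix
        must be mapped.
    method : {"median", "mean"}
        Per-sample summary statistic over each gene's probes.
    """
    if probe_matrix.empty:
        raise ValueError("probe matrix is empty")
    if method not in ("median", "mean"):
        raise ValueError(f"unknown summary method: {method!r}")
    probe_map = pd.Series(probe_map)
    missing = probe_matrix.index.difference(probe_map.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes without a gene mapping: "
            f"{sorted(missing)[:10]}"
        )
    genes = probe_matrix.index.map(probe_map)
    out = probe_matrix.groupby(genes, sort=True).agg(method)
    out.index.name = "gene_id"
    return out[probe_matrix.columns]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the vector of row means of the column-sorted data; each
    column's values are replaced by the reference value at their rank.  Ties
    within a column get the mean of the tied reference quantiles.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    ref = np.sort(X, axis=0).mean(axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 of a linear-scale matrix; errors on non-positive values."""
    X = matrix.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("log2 transform requires strictly positive values")
    return pd.DataFrame(np.log2(X), index=matrix.index, columns=matrix.columns)
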