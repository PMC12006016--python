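"""Trajectory clustering and shape-archetype classification.

Fitted gene trajectories are Z-scored across the age grid, clustered with
agglomerative hierarchical clustering on the Kendall rank-correlation
distance d = 1 - tau, cut into k fine clusters (default 24), and each fine
cluster's mean trajectory is classified into one of six shape archetypes
(decreasing, U, increasing, inverted-U, stable, late rise) by a
deterministic rule cascade that replaces manual curation of cluster shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau, spearmanr

from .simulate import archetype_curve

__all__ = [
    "zscore_trajectories",
    "kendall_tau",
    "tau_distance_matrix",
    "hierarchical_cluster",
    "ShapeThresholds",
    "classify_shape",
    "ClusterAssignment",
    "cluster_trajectories",
]


def zscore_trajectories(traj: pd.DataFrame) -> pd.DataFrame:
    """Row-wise standardization using the population (1/n) SD.

    Flat rows are an error: a gene that passed the fold-change filter
    cannot have a constant fitted trajectory, so a zero-variance row
    signals a pipeline bug upstream.
    """
    X = traj.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = sd < 1e-12
    if flat.any():
        raise ValueError(
            f"zero-variance trajectories: {list(traj.index[flat][:10])}"
        )
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(Z, index=traj.index, columns=traj.columns)


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau undefined for an all-tied vector")
    tau = kendalltau(x, y).statistic
    return float(tau)


def tau_distance_matrix(Z: pd.DataFrame) -> np.ndarray:
    """Pairwise d = 1 - tau over rows; symmetric with zero diagonal."""
    X = Z.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - kendalltau(X[i], X[j]).statistic
    return D


def hierarchical_cluster(D: np.ndarray, k: int = 24, method: str = "average") -> np.ndarray:
    """Cut an agglomerative tree on a precomputed distance matrix into k
    clusters; labels are 1..k.  Deterministic given D."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items n={n}")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    Zlink = linkage(squareform(D, checks=False), method=method)
    return fcluster(Zlink, t=k, criterion="maxclust")


@dataclass(frozen=True)
class ShapeThresholds:
    """Tunable thresholds of the shape-classification cascade."""

    stable_rel_amplitude: float = 0.25  # amplitude below this x reference => STABLE
    monotone_abs_spearman: float = 0.9
    extremum_depth: float = 0.5  # endpoints must sit this fraction of amplitude above an interior min
    late_rise_frac: float = 0.25


_SHAPED = ("DECREASING", "U", "INCREASING", "INVERTED_U", "LATE_RISE")


def _template_curves(grid: np.ndarray) -> dict[str, np.ndarray]:
    rng = (float(grid[0]), float(grid[-1]))
    return {a: archetype_curve(a, grid, rng) for a in _SHAPED}


def classify_shape(
    mean_z,
    grid,
    ref_amplitude: float | None = None,
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> str:
    """Assign a trajectory to one of the six shape archetypes.

    Rule cascade (first match wins):

    1. peak-to-trough amplitude below ``stable_rel_amplitude`` times
       ``ref_amplitude`` (when a reference is supplied) -> STABLE;
    2. |Spearman(z, age)| >= 0.9 -> INCREASING/DECREASING by slope sign;
    3. an interior minimum with both endpoints at least half the amplitude
       above it -> U; the mirrored condition -> INVERTED_U;
    4. no net change over the first two thirds and a late net rise of at
       least a quarter of the amplitude -> LATE_RISE;
    5. otherwise the nearest of the five shaped canonical curves by
       Kendall tau.
    """
    z = np.asarray(mean_z, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if z.size < 5:
        raise ValueError("need >= 5 grid points to classify a shape")
    amp = z.max() - z.min()
    if ref_amplitude is not None and amp < thresholds.stable_rel_amplitude * ref_amplitude:
        return "STABLE"
    if amp < 1e-12:
        return "STABLE"

    rho = spearmanr(z, grid).statistic
    if abs(rho) >= thresholds.monotone_abs_spearman:
        return "INCREASING" if rho > 0 else "DECREASING"

    imin, imax = int(np.argmin(z)), int(np.argmax(z))
    depth = thresholds.extremum_depth * amp
    if 0 < imin < z.size - 1 and min(z[0], z[-1]) >= z[imin] + depth:
        return "U"
    if 0 < imax < z.size - 1 and max(z[0], z[-1]) <= z[imax] - depth:
        return "INVERTED_U"

    cut = int(np.floor(z.size * 2 / 3))
    if z[cut - 1] - z[0] <= 0 and z[-1] - z[cut - 1] >= thresholds.late_rise_frac * amp:
        return "LATE_RISE"

    best, best_tau = None, -np.inf
    for label, curve in _template_curves(grid).items():
        tau = kendalltau(z, curve).statistic
        if np.isnan(tau):
            continue
        if tau > best_tau:
            best, best_tau = label, tau
    return best if best is not None else "STABLE"


@dataclass
class ClusterAssignment:
    """Fine clusters and archetype labels for a set of trajectories."""

    labels: pd.DataFrame  # per gene: cluster (int), archetype (str)
    cluster_means: pd.DataFrame  # fine cluster x grid mean Z trajectories
    cluster_archetypes: dict[int, str] = field(default_factory=dict)
    linkage_method: str = "average"
    k: int = 24


def cluster_trajectories(
    trajectories: pd.DataFrame,
    k: int = 24,
    method: str = "average",
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> ClusterAssignment:
    """Full clustering stage: Z-score, Kendall distance, average-linkage
    tree cut at k, then archetype classification of cluster means.

    The stable-shape reference amplitude is the largest peak-to-trough
    amplitude among the cluster mean trajectories, so clusters whose mean
    flattens out (signal cancelling within the cluster or genuinely flat
    members) fall into STABLE.
    """
    if trajectories.empty:
        raise ValueError("no trajectories to cluster")
    k = min(k, len(trajectories))
    Z = zscore_trajectories(trajectories)
    D = tau_distance_matrix(Z)
    labels = hierarchical_cluster(D, k=k, method=method)
    grid = np.array([float(c.split("_", 1)[1]) for c in trajectories.columns])

    means = {}
    for c in sorted(set(labels)):
        means[c] = Z.to_numpy()[labels == c].mean(axis=0)
    mean_df = pd.DataFrame.from_dict(means, orient="index", columns=trajectories.columns)
    ref_amp = max(m.max() - m.min() for m in means.values())
    archetypes = {
        c: classify_shape(m, grid, ref_amplitude=ref_amp, thresholds=thresholds)
        for c, m in means.items()
    }
    per_gene = pd.DataFrame(
        {
            "cluster": labels,
            "archetype": [archetypes[c] for c in labels],
        },
        index=trajectories.index,
    )
    return ClusterAssignment(
        labels=per_gene,
        cluster_means=mean_df,
        cluster_archetypes=archetypes,
        linkage_method=method,
        k=k,
    )
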