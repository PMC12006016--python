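"""Temporal differential expression with spline models and moderated F tests.

Per gene, expression is modelled as

    y = b0 + f(age) + sex + season + subject + noise

where f(age) is a natural cubic spline with 3 degrees of freedom and the
subject term is a random intercept.  The random intercept is handled in two
stages, the strategy popularized for repeated-measures microarray designs:

1. a compound-symmetry (intra-subject) correlation ``rho`` is estimated per
   gene by REML and pooled across genes into a consensus value (trimmed mean
   on the atanh scale);
2. each gene is then fit by generalized least squares under the common
   block covariance ``V = (1 - rho) I + rho`` (within subject).

Residual variances are shrunk across genes by empirical Bayes (a scaled
inverse chi-square prior with moments matched to the observed log-variance
distribution), and the three spline coefficients are tested jointly with a
moderated F statistic on (3, d0 + d_g) degrees of freedom.  A gene is
declared differentially expressed over time when its BH-adjusted p-value is
below ``alpha`` and the peak-to-trough fold change of its fitted marginal
trajectory is at least ``fc_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "NaturalSplineBasis",
    "build_spline_basis",
    "build_design_matrix",
    "ConsensusCorrelation",
    "estimate_consensus_correlation",
    "GeneFits",
    "fit_gene_models",
    "ModerationParams",
    "moderate_variances",
    "moderated_f_test",
    "bh_adjust",
    "fold_change_over_time",
    "DEResults",
    "run_de",
    "interaction_test",
]


# ---------------------------------------------------------------------------
# spline basis


@dataclass(frozen=True)
class NaturalSplineBasis:
    """Natural cubic spline basis (linear beyond the boundary knots).

    ``df`` basis columns are generated from ``df + 1`` knots: boundary knots
    at the min/max observed age and interior knots at evenly spaced age
    quantiles (33.3%/66.7% for the default df = 3).  The construction is the
    standard truncated-power natural spline: with knots ``k_1 < ... < k_K``,

        d_j(x) = [(x - k_j)_+^3 - (x - k_K)_+^3] / (k_K - k_j)
        N_1(x) = x,   N_{j+1}(x) = d_j(x) - d_{K-1}(x)   (j = 1..K-2)

    which is cubic between knots, has continuous second derivatives, and has
    zero second derivative outside the boundary knots.
    """

    knots: tuple[float, ...]

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    @property
    def boundary(self) -> tuple[float, float]:
        return (self.knots[0], self.knots[-1])

    def __call__(self, ages) -> np.ndarray:
        x = np.asarray(ages, dtype=float)
        k = np.asarray(self.knots)
        K = len(k)

        def d(j):
            return (
                np.clip(x - k[j], 0, None) ** 3 - np.clip(x - k[-1], 0, None) ** 3
            ) / (k[-1] - k[j])

        cols = [x] + [d(j) - d(K - 2) for j in range(K - 2)]
        return np.column_stack(cols)


def build_spline_basis(ages, df: int = 3) -> NaturalSplineBasis:
    """Place knots for a natural cubic spline basis on the observed ages."""
    ages = np.asarray(ages, dtype=float)
    distinct = np.unique(ages)
    if len(distinct) < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct ages for a {df}-df natural "
            f"spline, got {len(distinct)}"
        )
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(distinct, qs)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate age distribution: coincident knots")
    return NaturalSplineBasis(tuple(float(v) for v in knots))


def build_design_matrix(
    samples: pd.DataFrame, basis: NaturalSplineBasis
) -> pd.DataFrame:
    """Fixed-effect design: intercept, spline(age), sex and season dummies.

    Single-level covariates are dropped with a warning (no contrast exists).
    """
    n = len(samples)
    cols = {"intercept": np.ones(n)}
    S = basis(samples["age_months"].to_numpy())
    for j in range(S.shape[1]):
        cols[f"age_spline{j + 1}"] = S[:, j]
    for cov in ("sex", "season"):
        levels = sorted(samples[cov].unique())
        if len(levels) < 2:
            logger.warning("covariate %r has a single level; dropped", cov)
            continue
        for lev in levels[1:]:
            cols[f"{cov}_{lev}"] = (samples[cov] == lev).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    return X


def spline_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if c.startswith("age_spline")]


# ---------------------------------------------------------------------------
# compound-symmetry GLS machinery


def _block_codes(blocks) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(np.asarray(blocks))
    sizes = np.bincount(codes)
    return codes, sizes


def _whiten(M: np.ndarray, codes: np.ndarray, sizes: np.ndarray, rho: float) -> np.ndarray:
    """Transform rows of M (samples x k) so the block covariance becomes I.

    For a block of size m, V = (1-rho) I + rho J has eigenvalue
    1 + (m-1) rho along the block mean and 1 - rho on deviations, so
    W y = (y - ybar) / sqrt(1-rho) + ybar / sqrt(1 + (m-1) rho).
    """
    m = sizes[codes].astype(float)[:, None]
    sums = np.zeros((len(sizes), M.shape[1]))
    np.add.at(sums, codes, M)
    means = sums[codes] / m
    return (M - means) / np.sqrt(1.0 - rho) + means / np.sqrt(1.0 + (m - 1.0) * rho)


def _logdet_v(sizes: np.ndarray, rho: float) -> float:
    return float(
        np.sum(np.log1p((sizes - 1) * rho) + (sizes - 1) * np.log1p(-rho))
    )


@dataclass
class ConsensusCorrelation:
    """Pooled intra-subject correlation and the per-gene REML estimates."""

    rho: float
    per_gene: np.ndarray
    n_dropped: int = 0


def estimate_consensus_correlation(
    Y: np.ndarray | pd.DataFrame,
    X: np.ndarray | pd.DataFrame,
    blocks,
    grid_size: int = 121,
    trim: float = 0.1,
) -> ConsensusCorrelation:
    """Per-gene REML estimate of the compound-symmetry correlation, pooled.

    The REML criterion is profiled over the residual scale and evaluated on
    a grid of ``rho`` values spanning (just above) the identifiability bound
    ``-1/(m_max - 1)`` to 0.99; each gene's maximizer is recorded and the
    consensus is the tanh of the 10%-trimmed mean of atanh(rho_g).  Genes
    with (numerically) zero residual variance are dropped from the pool.
    """
    Yv = np.asarray(Y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    codes, sizes = _block_codes(blocks)
    if (sizes >= 2).sum() < 2:
        raise ValueError(
            "random intercept unidentifiable: need >= 2 subjects with "
            "repeated measures"
        )
    n, p = Xv.shape
    lo = -1.0 / (sizes.max() - 1) + 1e-3
    grid = np.linspace(lo, 0.99, grid_size)

    crit = np.full((grid_size, Yv.shape[0]), -np.inf)
    YT = Yv.T  # samples x genes
    for gi, rho in enumerate(grid):
        Xw = _whiten(Xv, codes, sizes, rho)
        Yw = _whiten(YT, codes, sizes, rho)
        Q, R = np.linalg.qr(Xw)
        resid = Yw - Q @ (Q.T @ Yw)
        rss = np.einsum("ij,ij->j", resid, resid)
        ld_xx = 2.0 * np.sum(np.log(np.abs(np.diag(R))))
        crit[gi] = -(n - p) * np.log(np.maximum(rss, 1e-300)) - _logdet_v(
            sizes, rho
        ) - ld_xx

    per_gene = grid[np.argmax(crit, axis=0)]
    var_y = Yv.var(axis=1)
    ok = var_y > 1e-12
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("consensus correlation: dropped %d zero-variance genes", n_dropped)
    if not ok.any():
        raise ValueError("all genes have zero variance")
    z = np.arctanh(np.clip(per_gene[ok], -0.999, 0.999))
    rho = float(np.tanh(stats.trim_mean(z, trim)))
    return ConsensusCorrelation(rho=rho, per_gene=per_gene, n_dropped=n_dropped)


@dataclass
class GeneFits:
    """Per-gene GLS fits under the consensus block correlation."""

    coef: pd.DataFrame  # genes x design columns
    s2: np.ndarray  # residual variance per gene
    df_resid: int
    rss: np.ndarray
    rho: float
    design_columns: list[str] = field(default_factory=list)


def fit_gene_models(
    Y: pd.DataFrame, X: pd.DataFrame, rho: float, blocks
) -> GeneFits:
    """GLS fit of every gene under V = (1-rho) I + rho (within subject).

    With rho = 0 this is exactly ordinary least squares.
    """
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    codes, sizes = _block_codes(blocks)
    n, p = Xv.shape
    Xw = _whiten(Xv, codes, sizes, rho)
    Yw = _whiten(Y.to_numpy(dtype=float).T, codes, sizes, rho)
    coef, _, _, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    resid = Yw - Xw @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    dg = n - p
    return GeneFits(
        coef=pd.DataFrame(coef.T, index=Y.index, columns=X.columns),
        s2=rss / dg,
        df_resid=dg,
        rss=rss,
        rho=rho,
        design_columns=list(X.columns),
    )


def _reduced_rss(Y: pd.DataFrame, X: pd.DataFrame, drop_cols, rho: float, blocks):
    X0 = X.drop(columns=list(drop_cols))
    return fit_gene_models(Y, X0, rho, blocks).rss


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class ModerationParams:
    """Scaled inverse chi-square prior for residual variances.

    ``d0`` may be ``inf`` (no dispersion in the observed log-variances
    beyond sampling noise); the posterior variance is the precision-weighted
    blend (d0 s0^2 + d_g s_g^2) / (d0 + d_g).
    """

    d0: float
    s0_sq: float
    s2_post: np.ndarray


def moderate_variances(s2, d) -> ModerationParams:
    """Moment-match a scaled-F prior to the per-gene residual variances.

    The estimator works on z = log(s^2): E[z] and Var[z] under the
    hierarchical model are digamma/trigamma expressions in (d0, s0^2), and
    the excess of the observed Var[z] over the sampling term trigamma(d/2)
    identifies d0.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    if np.any(s2 < 0):
        raise ValueError("negative variances")
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    if np.any(d <= 0):
        raise ValueError("residual df must be positive")
    s2c = np.maximum(s2, 1e-300)
    e = np.log(s2c) - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        s2_post = np.full_like(s2, s0_sq)
    s2_post = np.maximum(s2_post, 1e-12)
    return ModerationParams(d0=float(d0), s0_sq=s0_sq, s2_post=s2_post)


def moderated_f_test(
    rss_full: np.ndarray,
    rss_reduced: np.ndarray,
    q: int,
    mod: ModerationParams,
    df_resid: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated partial F for q tested coefficients.

    F = ((RSS_reduced - RSS_full) / q) / s2_post, referred to an
    F(q, d0 + d_g) distribution; with infinite prior df the limit is
    chi-square(q)/q.
    """
    num = np.maximum(rss_reduced - rss_full, 0.0) / q
    F = num / mod.s2_post
    if np.isfinite(mod.d0):
        p = stats.f.sf(F, q, mod.d0 + df_resid)
    else:
        p = stats.chi2.sf(q * F, q)
    return F, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_over_time(trajectory) -> float:
    """Peak-to-trough fold change 2^(max - min) of a fitted log2 trajectory."""
    t = np.asarray(trajectory, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory grid")
    return float(2.0 ** (t.max() - t.min()))


# ---------------------------------------------------------------------------
# top-level analyses


@dataclass
class DEResults:
    """Output of :func:`run_de`.

    ``table`` has one row per gene: F, p, p_adj, fc_time, de_flag.
    ``trajectories`` holds the fitted marginal log2 trajectory of every gene
    on the age grid (sex/season effects averaged out).
    """

    table: pd.DataFrame
    trajectories: pd.DataFrame
    age_grid: np.ndarray
    rho: float
    d0: float
    s0_sq: float
    basis: NaturalSplineBasis
    fc_threshold: float
    alpha: float

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["de_flag"]]


def _check_alignment(expression: pd.DataFrame, samples: pd.DataFrame) -> None:
    missing = expression.columns.difference(samples.index)
    if len(missing):
        raise ValueError(f"samples missing metadata: {sorted(missing)[:10]}")


def _marginal_trajectories(
    fits: GeneFits, X: pd.DataFrame, basis: NaturalSplineBasis, grid: np.ndarray
) -> pd.DataFrame:
    """Fitted log2 value per gene at each grid age, non-age covariates at
    their sample means (effect-averaged marginal curve)."""
    ref = X.mean(axis=0)
    Xg = pd.DataFrame(
        np.tile(ref.to_numpy(), (len(grid), 1)), columns=X.columns
    )
    S = basis(grid)
    Xg["intercept"] = 1.0
    for j in range(S.shape[1]):
        Xg[f"age_spline{j + 1}"] = S[:, j]
    vals = fits.coef.to_numpy() @ Xg.to_numpy().T
    return pd.DataFrame(
        vals, index=fits.coef.index, columns=[f"age_{a:g}" for a in grid]
    )


def run_de(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    df: int = 3,
    fc_threshold: float = 1.10,
    alpha: float = 0.05,
    grid_step: float = 0.5,
    rho: float | None = None,
) -> DEResults:
    """Temporal differential expression for every gene.

    Parameters
    ----------
    expression : DataFrame
        Genes x samples log2 matrix.
    samples : DataFrame
        Metadata indexed by sample id with columns ``subject_id``,
        ``age_months``, ``sex``, ``season``.
    df : int
        Spline degrees of freedom (3 captures monotone, U and late-rise
        shapes without overfitting quarterly sampling).
    fc_threshold : float
        Minimum peak-to-trough fold change of the fitted trajectory.
    alpha : float
        BH-adjusted significance level.
    grid_step : float
        Age-grid resolution (months) for fitted trajectories.
    rho : float, optional
        Intra-subject correlation; estimated from the data when omitted.
    """
    _check_alignment(expression, samples)
    meta = samples.loc[expression.columns]
    ages = meta["age_months"].to_numpy()
    basis = build_spline_basis(ages, df=df)
    X = build_design_matrix(meta, basis)
    blocks = meta["subject_id"].to_numpy()

    if rho is None:
        cons = estimate_consensus_correlation(
            expression.to_numpy(), X.to_numpy(), blocks
        )
        rho = cons.rho
    fits = fit_gene_models(expression, X, rho, blocks)
    sp_cols = spline_columns(X)
    rss0 = _reduced_rss(expression, X, sp_cols, rho, blocks)
    mod = moderate_variances(fits.s2, fits.df_resid)
    F, p = moderated_f_test(fits.rss, rss0, len(sp_cols), mod, fits.df_resid)
    p_adj = bh_adjust(p)

    grid = np.arange(ages.min(), ages.max() + grid_step / 2, grid_step)
    traj = _marginal_trajectories(fits, X, basis, grid)
    fc = 2.0 ** (traj.to_numpy().max(axis=1) - traj.to_numpy().min(axis=1))
    table = pd.DataFrame(
        {
            "F": F,
            "p": p,
            "p_adj": p_adj,
            "fc_time": fc,
            "de_flag": (p_adj < alpha) & (fc >= fc_threshold),
        },
        index=expression.index,
    )
    return DEResults(
        table=table,
        trajectories=traj,
        age_grid=grid,
        rho=rho,
        d0=mod.d0,
        s0_sq=mod.s0_sq,
        basis=basis,
        fc_threshold=fc_threshold,
        alpha=alpha,
    )


def interaction_test(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    factor: str,
    df: int = 3,
    rho: float | None = None,
) -> pd.DataFrame:
    """Test whether age trajectories differ across levels of a factor.

    Adds spline(age) x factor interaction columns (3 per non-reference
    level) to the base design and tests them jointly with a moderated F.
    The factor may be constant within subject (e.g. sex, HLA genotype);
    it enters as a fixed effect, so this is handled.  Returns a per-gene
    table with F, p and BH-adjusted p (one family per interaction test).
    """
    _check_alignment(expression, samples)
    meta = samples.loc[expression.columns]
    levels = sorted(meta[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level; no contrast")
    for lev in levels:
        n_ages = meta.loc[meta[factor] == lev, "age_months"].nunique()
        if n_ages < 4:
            raise ValueError(
                f"factor level {lev!r} observed at only {n_ages} distinct ages"
            )
    ages = meta["age_months"].to_numpy()
    basis = build_spline_basis(ages, df=df)
    X = build_design_matrix(meta, basis)
    sp_cols = spline_columns(X)
    X = X.copy()
    # main effect of the factor (sex is already in the base design)
    for lev in levels[1:]:
        name = f"{factor}_{lev}"
        if name not in X.columns:
            X[name] = (meta[factor] == lev).to_numpy(dtype=float)
    inter_cols = []
    for lev in levels[1:]:
        dummy = (meta[factor] == lev).to_numpy(dtype=float)
        for c in sp_cols:
            name = f"{c}:{factor}_{lev}"
            X[name] = X[c].to_numpy() * dummy
            inter_cols.append(name)
    blocks = meta["subject_id"].to_numpy()
    if rho is None:
        X_base = X.drop(columns=inter_cols)
        cons = estimate_consensus_correlation(
            expression.to_numpy(), X_base.to_numpy(), blocks
        )
        rho = cons.rho
    fits = fit_gene_models(expression, X, rho, blocks)
    rss0 = _reduced_rss(expression, X, inter_cols, rho, blocks)
    mod = moderate_variances(fits.s2, fits.df_resid)
    F, p = moderated_f_test(fits.rss, rss0, len(inter_cols), mod, fits.df_resid)
    return pd.DataFrame(
        {"F": F, "p": p, "p_adj": bh_adjust(p)}, index=expression.index
    )
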