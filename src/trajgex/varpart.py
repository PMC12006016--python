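"""Per-gene decomposition of expression variance into named fractions.

Each gene is fit with a linear mixed model containing independent random
intercepts for the categorical covariates (individual, season, sex, HLA
genotype) and a fixed 3-df natural-spline age effect:

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

Variance components are estimated by REML.  The age contribution is the
sample variance of the fitted fixed spline component; the reported
fractions are each component divided by the total (all components plus the
age term plus residual), so they are non-negative and sum to one.

Modelling every categorical as a random intercept — even two-level sex —
keeps all components on the variance scale and is the convention for
variance-partition analyses of expression data.

The REML objective is evaluated through Henderson's mixed-model equations:
with W = [X Z] and the small crossproducts W'W, W'y, y'y precomputed, each
likelihood evaluation only involves matrices of size (p + q) where q is the
total number of random-effect levels (tens), so thousands of genes fit in
seconds.  The criterion, profiled over the residual scale and written in
terms of the relative variances gamma_k = sigma_k^2 / sigma_e^2, is

    (n - p) log S(gamma) + sum_k q_k log gamma_k
        + log|Z'Z + Gamma^{-1}| + log|X' V~^{-1} X|

with V~ = I + Z Gamma Z' and S the generalized residual sum of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .de import build_spline_basis

logger = logging.getLogger(__name__)

__all__ = ["variance_fractions", "VariancePartitionModel"]

_CATEGORICALS = {"individual": "subject_id", "season": "season", "sex": "sex", "hla": "hla"}


def _dummies(values: np.ndarray) -> np.ndarray:
    levels, codes = np.unique(values, return_inverse=True)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), codes] = 1.0
    return Z


@dataclass
class VariancePartitionModel:
    """Precomputed design for the variance-components REML fits."""

    X: np.ndarray  # fixed effects: intercept + age spline
    Z: np.ndarray  # concatenated random-effect indicator blocks
    block_slices: dict[str, slice]
    n: int

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, df: int = 3) -> "VariancePartitionModel":
        ages = samples["age_months"].to_numpy()
        basis = build_spline_basis(ages, df=df)
        X = np.column_stack([np.ones(len(samples)), basis(ages)])
        blocks, slices, start = [], {}, 0
        for name, col in _CATEGORICALS.items():
            if col not in samples.columns:
                raise ValueError(f"sample table lacks required column {col!r}")
            vals = samples[col].to_numpy()
            if len(np.unique(vals)) < 2:
                logger.warning("covariate %r has one level; term dropped", name)
                continue
            Zk = _dummies(vals)
            blocks.append(Zk)
            slices[name] = slice(start, start + Zk.shape[1])
            start += Zk.shape[1]
        if not blocks:
            raise ValueError("no usable categorical covariates")
        return cls(X=X, Z=np.hstack(blocks), block_slices=slices, n=len(samples))

    def reml_fit(self, y: np.ndarray, tol: float = 1e-8, maxiter: int = 200):
        """REML variance components for one response vector.

        Returns (components dict incl. 'residual', age_variance) or None on
        optimizer failure.
        """
        X, Z = self.X, self.Z
        n, p = X.shape
        XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
        Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)
        names = list(self.block_slices)
        qk = np.array([self.block_slices[k].stop - self.block_slices[k].start for k in names])

        def crit(eta: np.ndarray) -> float:
            gamma = np.exp(eta)
            ginv = np.concatenate(
                [np.full(q, 1.0 / g) for q, g in zip(qk, gamma)]
            )
            A = ZtZ + np.diag(ginv)
            try:
                cA = cho_factor(A, lower=True)
            except np.linalg.LinAlgError:
                return 1e12
            ldA = 2.0 * np.sum(np.log(np.diag(cA[0])))
            AinvZty = cho_solve(cA, Zty)
            AinvZtX = cho_solve(cA, XtZ.T)
            XtViX = XtX - XtZ @ AinvZtX
            XtViy = Xty - XtZ @ AinvZty
            ytViy = yty - Zty @ AinvZty
            try:
                cB = cho_factor(XtViX, lower=True)
            except np.linalg.LinAlgError:
                return 1e12
            ldB = 2.0 * np.sum(np.log(np.diag(cB[0])))
            S = ytViy - XtViy @ cho_solve(cB, XtViy)
            if S <= 0:
                return 1e12
            return float(
                (n - p) * np.log(S) + np.sum(qk * eta) + ldA + ldB
            )

        res = minimize(
            crit,
            x0=np.zeros(len(names)),
            method="L-BFGS-B",
            bounds=[(-20.0, 10.0)] * len(names),
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-6},
        )
        if not res.success and res.status not in (0, 1, 2):
            return None
        gamma = np.exp(res.x)
        # recover sigma_e^2 and the GLS fixed-effect solution at the optimum
        ginv = np.concatenate([np.full(q, 1.0 / g) for q, g in zip(qk, gamma)])
        A = ZtZ + np.diag(ginv)
        cA = cho_factor(A, lower=True)
        XtViX = XtX - XtZ @ cho_solve(cA, XtZ.T)
        XtViy = Xty - XtZ @ cho_solve(cA, Zty)
        ytViy = yty - Zty @ cho_solve(cA, Zty)
        beta = np.linalg.solve(XtViX, XtViy)
        S = ytViy - XtViy @ beta
        sigma_e2 = max(float(S) / (n - p), 1e-12)
        comps = {name: float(g * sigma_e2) for name, g in zip(names, gamma)}
        comps["residual"] = sigma_e2
        age_fit = X[:, 1:] @ beta[1:]
        age_var = float(np.var(age_fit, ddof=1))
        return comps, age_var


def variance_fractions(
    expression: pd.DataFrame, samples: pd.DataFrame, df: int = 3
) -> pd.DataFrame:
    """Fraction of each gene's variance explained by individual, season,
    age, sex and HLA genotype, plus residual.

    Returns a genes x fractions DataFrame whose rows sum to 1; genes whose
    REML fit fails are reported as all-NaN rows and counted in the log.
    """
    missing = expression.columns.difference(samples.index)
    if len(missing):
        raise ValueError(f"samples missing metadata: {sorted(missing)[:10]}")
    meta = samples.loc[expression.columns]
    model = VariancePartitionModel.from_samples(meta, df=df)
    terms = list(model.block_slices) + ["age", "residual"]
    out = np.full((expression.shape[0], len(terms)), np.nan)
    n_failed = 0
    Y = expression.to_numpy(dtype=float)
    for i in range(Y.shape[0]):
        fit = model.reml_fit(Y[i])
        if fit is None:
            n_failed += 1
            continue
        comps, age_var = fit
        total = sum(comps.values()) + age_var
        row = {k: v / total for k, v in comps.items()}
        row["age"] = age_var / total
        out[i] = [row[t] for t in terms]
    if n_failed:
        logger.warning("variance partition: %d genes failed to converge", n_failed)
    return pd.DataFrame(out, index=expression.index, columns=terms)
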