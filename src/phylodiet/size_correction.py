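"""Body-size correction of a trait by regression, with or without phylogeny.

The phylogenetic route fits a generalized least squares regression whose
error covariance is the Brownian-motion matrix of the tree, so that species
do not enter as independent points; the residuals from that fit are the
size-corrected trait carried into all downstream comparative analyses.
Residuals are raw (y - y_hat), not studentized, because they are reused as a
trait in their own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tree import PhyloTree, vcv_matrix

__all__ = ["RegressionFit", "phylo_residuals", "ols_residuals"]


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    residuals: pd.Series
    method: str  # "phylogenetic_gls" | "ols"
    r_squared: float


def _align(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = list(x.index)
    if set(labels) != set(y.index):
        raise ValueError(
            "x and y must be indexed by the same labels; difference: "
            f"{sorted(set(labels) ^ set(y.index))}"
        )
    return x.to_numpy(float), y.loc[labels].to_numpy(float), labels


def phylo_residuals(tree: PhyloTree, x: pd.Series, y: pd.Series) -> RegressionFit:
    """Phylogenetic (GLS) regression of y on x under Brownian covariance.

    Coefficients solve (X' C^-1 X) beta = X' C^-1 y with C the phylogenetic
    covariance of ``tree``; residuals are y - X beta.  The r_squared is
    computed in the C^-1 metric and is diagnostic only.
    """
    xv, yv, labels = _align(x, y)
    C = vcv_matrix(tree).reorder(labels).values
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "phylogenetic covariance matrix is singular or near-singular "
            f"(condition number {cond:.3g}); check for duplicated tips or "
            "zero-length terminal branches"
        )
    X = sm.add_constant(xv)
    fit = sm.GLS(yv, X, sigma=C).fit()
    resid = yv - X @ fit.params
    Cinv = np.linalg.inv(C)
    yc = yv - (np.ones(len(yv)) @ Cinv @ yv) / (np.ones(len(yv)) @ Cinv @ np.ones(len(yv)))
    sse = resid @ Cinv @ resid
    sst = yc @ Cinv @ yc
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        residuals=pd.Series(resid, index=labels, name="phylo_residual"),
        method="phylogenetic_gls",
        r_squared=float(1.0 - sse / sst) if sst > 0 else float("nan"),
    )


def ols_residuals(x: pd.Series, y: pd.Series) -> RegressionFit:
    """Ordinary least-squares regression of y on x; residuals are y - y_hat."""
    xv, yv, labels = _align(x, y)
    if len(xv) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; regression undefined")
    X = sm.add_constant(xv)
    fit = sm.OLS(yv, X).fit()
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        residuals=pd.Series(fit.resid, index=labels, name="ols_residual"),
        method="ols",
        r_squared=float(fit.rsquared),
    )
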