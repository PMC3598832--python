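"""Phylogenetic signal statistics for continuous traits.

Two complementary measures are provided.  Blomberg's K compares the observed
ratio of tip variance to phylogenetically corrected variance against its
Brownian-motion expectation on the same tree (K = 1 under Brownian motion);
significance comes from permuting trait values across tips.  Pagel's lambda
rescales the off-diagonal phylogenetic covariances by a factor estimated by
maximum likelihood, with likelihood-ratio tests against lambda = 0 (star
phylogeny, no signal) and lambda = 1 (Brownian motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pic import compute_pics
from .tree import PhyloTree, vcv_matrix

__all__ = [
    "SignalK",
    "SignalLambda",
    "blomberg_K",
    "K_permutation_test",
    "pagel_lambda",
    "DEFAULT_PERMUTATION_SEED",
]

DEFAULT_PERMUTATION_SEED = 20130225


@dataclass
class SignalK:
    K: float
    observed_pic_variance: float
    p_value: float  # upper-tail permutation p on K itself
    p_value_pic_variance: float  # lower-tail permutation p on PIC variance
    n_permutations: int
    seed: int


@dataclass
class SignalLambda:
    lambda_hat: float
    lnL_hat: float
    lnL_at_0: float
    lnL_at_1: float
    p_vs_0: float
    p_vs_1: float


def _prepare(tree: PhyloTree, trait: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = tree.tip_labels
    if set(trait.index) != set(labels):
        raise ValueError(
            "trait labels do not match tree tips; difference: "
            f"{sorted(set(trait.index) ^ set(labels))}"
        )
    y = trait.loc[labels].to_numpy(float)
    C = vcv_matrix(tree).values
    return y, C


def _K_stat(y: np.ndarray, Cinv: np.ndarray, denom: float) -> float:
    n = len(y)
    one = np.ones(n)
    a = (one @ Cinv @ y) / (one @ Cinv @ one)
    e = y - a
    mse0 = float(e @ e)
    mse = float(e @ Cinv @ e)
    if mse == 0:
        raise ValueError("phylogenetic mean square is zero")
    return (mse0 / mse) / denom


def _K_denominator(C: np.ndarray, Cinv: np.ndarray) -> float:
    n = C.shape[0]
    one = np.ones(n)
    return (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)


def blomberg_K(tree: PhyloTree, trait: pd.Series) -> float:
    """Blomberg's K for a continuous trait on a tree.

    K = [(y-a)'(y-a) / (y-a)' C^-1 (y-a)] / [(tr C - n/(1'C^-1 1)) / (n-1)]
    with a the GLS estimate of the root state.  Invariant to affine
    transformation of the trait; equals 1 exactly on a star phylogeny.
    """
    y, C = _prepare(tree, trait)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant across tips; signal undefined")
    Cinv = np.linalg.inv(C)
    return float(_K_stat(y, Cinv, _K_denominator(C, Cinv)))


def K_permutation_test(
    tree: PhyloTree,
    trait: pd.Series,
    n_perm: int = 1000,
    seed: int = DEFAULT_PERMUTATION_SEED,
) -> SignalK:
    """Tip-permutation test of Blomberg's K.

    The null distribution shuffles trait values across tips ``n_perm`` times.
    Two p-values are reported: the upper-tail test on K itself (significant
    signal when the observed K exceeds the randomizations) and the standard
    lower-tail test on the variance of standardized contrasts (low observed
    contrast variance indicates signal).  Both use the +1 correction so p is
    never exactly zero.
    """
    y, C = _prepare(tree, trait)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant across tips; signal undefined")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; permutation p will be coarse")
    Cinv = np.linalg.inv(C)
    denom = _K_denominator(C, Cinv)
    K_obs = _K_stat(y, Cinv, denom)

    u = compute_pics(tree, trait).std_contrast
    pic_var_obs = float(u @ u) / (len(u) - 1)

    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    n = len(y)
    one = np.ones(n)
    sum_inv = one @ Cinv @ one

    # standardized contrasts are linear in the tip values: u = B y, so build
    # the operator from unit vectors once and vectorize over permutations
    B = np.column_stack(
        [
            compute_pics(tree, pd.Series(np.eye(n)[i], index=labels)).std_contrast
            for i in range(n)
        ]
    )
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Y = y[perms].T  # n x n_perm
    a = (one @ Cinv @ Y) / sum_inv
    E = Y - a
    Kp = (np.einsum("ij,ij->j", E, E) / np.einsum("ij,ij->j", E, Cinv @ E)) / denom
    U = B @ Y
    pic_vars = np.einsum("ij,ij->j", U, U) / (U.shape[0] - 1)
    k_exceed = int(np.sum(Kp >= K_obs))
    picvar_below = int(np.sum(pic_vars <= pic_var_obs))
    return SignalK(
        K=float(K_obs),
        observed_pic_variance=pic_var_obs,
        p_value=(k_exceed + 1) / (n_perm + 1),
        p_value_pic_variance=(picvar_below + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )


# -------------------------------------------------------------------------------
# Pagel's lambda
# -------------------------------------------------------------------------------


def _lambda_C(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def lambda_max(C: np.ndarray) -> float:
    """Largest lambda keeping every tip variance >= every shared covariance."""
    off = C[~np.eye(C.shape[0], dtype=bool)]
    m = off.max()
    if m <= 0:
        return 1.0
    return float(np.min(np.diag(C)) / m)


def _profile_lnL(y: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Log-likelihood of the MVN(a*1, s2*C(lambda)) model, profiled over a, s2."""
    n = len(y)
    Cl = _lambda_C(C, lam)
    sign, logdet = np.linalg.slogdet(Cl)
    if sign <= 0:
        return -np.inf
    Cinv = np.linalg.inv(Cl)
    one = np.ones(n)
    a = (one @ Cinv @ y) / (one @ Cinv @ one)
    e = y - a
    s2 = float(e @ Cinv @ e) / n
    if s2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * s2) + logdet + n))


def pagel_lambda(tree: PhyloTree, trait: pd.Series) -> SignalLambda:
    """Maximum-likelihood estimate of Pagel's lambda with LRTs vs 0 and 1.

    lambda multiplies the off-diagonal entries of the Brownian covariance;
    the profile likelihood is maximized over [0, lambda_max] where lambda_max
    keeps the matrix positive definite (this allows lambda > 1 on trees where
    tip variances exceed all shared covariances).  The likelihood-ratio tests
    compare 2*(lnL_hat - lnL_fixed) to chi-square with 1 df.
    """
    y, C = _prepare(tree, trait)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant across tips; signal undefined")
    lmax = lambda_max(C)

    obj = lambda lam: -_profile_lnL(y, C, lam)  # noqa: E731
    res = optimize.minimize_scalar(
        obj, bounds=(0.0, lmax), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"lambda optimization failed on [0, {lmax:.4f}]: {res.message}"
        )
    lam_hat = float(res.x)
    lnL_hat = -float(res.fun)
    # the bounded optimizer can sit fractionally inside the bracket ends
    for cand in (0.0, lmax):
        cl = _profile_lnL(y, C, cand)
        if cl > lnL_hat:
            lam_hat, lnL_hat = cand, cl
    lnL0 = _profile_lnL(y, C, 0.0)
    lnL1 = _profile_lnL(y, C, min(1.0, lmax))
    p0 = float(stats.chi2.sf(max(0.0, 2 * (lnL_hat - lnL0)), 1))
    p1 = float(stats.chi2.sf(max(0.0, 2 * (lnL_hat - lnL1)), 1))
    return SignalLambda(
        lambda_hat=lam_hat, lnL_hat=lnL_hat, lnL_at_0=float(lnL0),
        lnL_at_1=float(lnL1), p_vs_0=p0, p_vs_1=p1,
    )
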