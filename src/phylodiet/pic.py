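"""Phylogenetically independent contrasts and through-origin correlation.

Contrasts are computed by the classic pruning recursion: at each internal
node with child values (x1, v1), (x2, v2) the raw contrast is x1 - x2, its
variance is v1 + v2, the node value is the variance-weighted average of the
children, and the node's parent-facing branch is lengthened by v1*v2/(v1+v2).
Standardized contrasts are contrast / sqrt(v1 + v2).

Because contrast signs are arbitrary (they depend on child order), paired
contrasts are compared through the origin: correlation, reduced major axis
slope, and the t test all omit the intercept, with degrees of freedom
n_contrasts - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tree import PhyloTree, TreeError, clade_tipsets

__all__ = [
    "ContrastSet",
    "OriginFit",
    "compute_pics",
    "origin_correlation",
    "positivize",
    "standardization_diagnostic",
]


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait, in postorder.

    ``tipsets[i]`` identifies contrast i by the descendant tip set of its
    node, so two ContrastSets from the same tree align element-wise.
    """

    tipsets: list[frozenset[str]]
    contrast: np.ndarray
    std_contrast: np.ndarray
    contrast_sd: np.ndarray
    node_value: np.ndarray
    adjusted_parent_bl: np.ndarray  # nan for the root

    def __len__(self) -> int:
        return len(self.tipsets)

    def flipped(self, signs: np.ndarray) -> "ContrastSet":
        return ContrastSet(
            self.tipsets,
            self.contrast * signs,
            self.std_contrast * signs,
            self.contrast_sd,
            self.node_value,
            self.adjusted_parent_bl,
        )


@dataclass
class OriginFit:
    """Through-origin association between two contrast sets."""

    r: float
    r_squared: float
    rma_slope: float
    p_value: float
    n_contrasts: int


def compute_pics(tree: PhyloTree, trait: pd.Series) -> ContrastSet:
    """Independent contrasts of ``trait`` (indexed by tip label) on ``tree``."""
    tree.require_bifurcating("independent contrasts")
    if not tree.has_branch_lengths():
        raise TreeError("independent contrasts require branch lengths")
    if set(trait.index) != set(tree.tip_labels):
        raise ValueError(
            "trait labels do not match tree tips; difference: "
            f"{sorted(set(trait.index) ^ set(tree.tip_labels))}"
        )
    tipset_of = clade_tipsets(tree)

    values: dict = {}
    variances: dict = {}
    rows = []
    for node in tree.postorder():
        if node.is_tip:
            values[node] = float(trait[node.label])
            variances[node] = float(node.length)
            continue
        c1, c2 = node.children
        x1, v1 = values.pop(c1), variances.pop(c1)
        x2, v2 = values.pop(c2), variances.pop(c2)
        if v1 <= 0 or v2 <= 0:
            raise TreeError(
                "contrast standardization impossible: zero-length branch "
                f"below node with tips {sorted(tipset_of[node])[:4]} "
                "(no epsilon padding is applied; fix the input branch lengths)"
            )
        pooled = v1 + v2
        contrast = x1 - x2
        sd = np.sqrt(pooled)
        node_val = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        extra = v1 * v2 / pooled
        base = float(node.length) if node is not tree.root else np.nan
        values[node] = node_val
        variances[node] = (base if node is not tree.root else 0.0) + extra
        rows.append(
            (tipset_of[node], contrast, contrast / sd, sd, node_val,
             base + extra if node is not tree.root else np.nan)
        )
    return ContrastSet(
        tipsets=[r[0] for r in rows],
        contrast=np.array([r[1] for r in rows]),
        std_contrast=np.array([r[2] for r in rows]),
        contrast_sd=np.array([r[3] for r in rows]),
        node_value=np.array([r[4] for r in rows]),
        adjusted_parent_bl=np.array([r[5] for r in rows]),
    )


def _check_paired(ux: ContrastSet, uy: ContrastSet) -> None:
    if ux.tipsets != uy.tipsets:
        raise ValueError("contrast sets come from different trees or node orders")


def origin_correlation(ux: ContrastSet, uy: ContrastSet) -> OriginFit:
    """Through-origin Pearson r and RMA slope of uy on ux.

    r = sum(ux*uy) / sqrt(sum(ux^2) sum(uy^2)); the RMA slope is
    sign(r) * sqrt(sum(uy^2)/sum(ux^2)); p comes from t = r sqrt(df)/sqrt(1-r^2)
    with df = n - 1 (through-origin convention).
    """
    _check_paired(ux, uy)
    a, b = ux.std_contrast, uy.std_contrast
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    sxx, syy, sxy = float(a @ a), float(b @ b), float(a @ b)
    if sxx == 0 or syy == 0:
        raise ValueError("zero sum of squares; correlation undefined")
    r = sxy / np.sqrt(sxx * syy)
    df = n - 1
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(abs(t), df)
    slope = float(np.sign(r) if r != 0 else 1.0) * np.sqrt(syy / sxx)
    return OriginFit(
        r=float(r), r_squared=float(r * r), rma_slope=float(slope),
        p_value=float(p), n_contrasts=n,
    )


def positivize(ux: ContrastSet, uy: ContrastSet) -> tuple[ContrastSet, ContrastSet]:
    """Flip each contrast pair so the x contrast is >= 0 (y follows).

    Through-origin r and |RMA slope| are invariant; after positivizing, the
    count of negative y contrasts equals the count of opposite-sign pairs.
    """
    _check_paired(ux, uy)
    signs = np.where(ux.std_contrast < 0, -1.0, 1.0)
    return ux.flipped(signs), uy.flipped(signs)


def standardization_diagnostic(contrasts: ContrastSet) -> dict:
    """Correlation of |standardized contrast| against contrast SD.

    A significant correlation indicates that the branch lengths do not
    adequately standardize the contrasts; ``adequate`` is True when the
    two-sided p exceeds 0.05.  With fewer than 3 contrasts the p-value is
    flagged unreliable.
    """
    absu = np.abs(contrasts.std_contrast)
    sd = contrasts.contrast_sd
    n = len(absu)
    if n < 2:
        raise ValueError("need at least 2 contrasts")
    r, p = stats.pearsonr(absu, sd)
    reliable = n >= 3
    return {
        "r": float(r),
        "p_value": float(p),
        "n": n,
        "adequate": bool(p > 0.05),
        "p_reliable": reliable,
    }
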