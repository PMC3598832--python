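"""End-to-end orchestration of the comparative pipeline.

Order of stages: validation -> derived transforms -> phylogenetic size
correction -> phylogenetic signal -> independent contrasts with RMA ->
branch-length sensitivity -> phylogenetically naive RMA -> ancestral state
reconstruction (single tree and, when a tree set is supplied, trace over
trees).  All randomness flows from a single seed; optional stages degrade
gracefully and are flagged in the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import rma_fit
from .asr import (
    CharacterData,
    count_origins,
    ml_marginal_asr,
    mp_reconstruct,
    trace_over_trees,
)
from .pic import (
    compute_pics,
    origin_correlation,
    positivize,
    standardization_diagnostic,
)
from .signal import DEFAULT_PERMUTATION_SEED, K_permutation_test, pagel_lambda
from .size_correction import ols_residuals, phylo_residuals
from .traits import TraitTable, derive, duplicate_tip_traits
from .tree import (
    BRANCH_LENGTH_SCHEMES,
    PhyloTree,
    TreeSet,
    transform_branch_lengths,
    write_newick,
)

__all__ = ["AnalysisReport", "run_full_analysis"]


@dataclass
class AnalysisReport:
    """Full pipeline output; ``sections`` is JSON-serialisable."""

    sections: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.sections, indent=indent, sort_keys=True)

    def validate(self) -> None:
        """Structural self-check of the report layout."""
        required = {"provenance", "derived", "signal", "pic", "naive", "asr"}
        missing = required - set(self.sections)
        if missing:
            raise ValueError(f"report missing sections: {sorted(missing)}")

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "report.json"
        path.write_text(self.to_json())
        pic = self.sections.get("pic", {})
        if "contrast_table" in pic:
            pd.DataFrame(pic["contrast_table"]).to_csv(
                outdir / "contrasts.tsv", sep="\t", index=False
            )
        derived = self.sections.get("derived")
        if derived:
            pd.DataFrame(derived).to_csv(
                outdir / "derived_traits.tsv", sep="\t", index=False
            )
        return path


def _fit_dict(fit) -> dict:
    return {
        "r": fit.r,
        "r_squared": fit.r_squared,
        "rma_slope": fit.rma_slope,
        "p_value": fit.p_value,
        "n_contrasts": fit.n_contrasts,
    }


def _tipset_key(ts: frozenset) -> str:
    return "|".join(sorted(ts))


def _pic_fit(tree: PhyloTree, x: pd.Series, y: pd.Series) -> dict:
    ux = compute_pics(tree, x)
    uy = compute_pics(tree, y)
    fit = origin_correlation(ux, uy)
    pux, puy = positivize(ux, uy)
    n_opposite = int(np.sum(puy.std_contrast < 0))
    return {
        "fit": _fit_dict(fit),
        "n_opposite_sign": n_opposite,
        "diagnostic_x": standardization_diagnostic(ux),
        "diagnostic_y": standardization_diagnostic(uy),
        "contrast_table": [
            {
                "tipset": _tipset_key(ts),
                "ux": float(a),
                "uy": float(b),
                "sd_x": float(s),
            }
            for ts, a, b, s in zip(
                pux.tipsets, pux.std_contrast, puy.std_contrast, pux.contrast_sd
            )
        ],
    }


def _signal_dict(tree, trait, n_perm, seed) -> dict:
    k = K_permutation_test(tree, trait, n_perm=n_perm, seed=seed)
    lam = pagel_lambda(tree, trait)
    return {
        "K": k.K,
        "observed_pic_variance": k.observed_pic_variance,
        "p_K": k.p_value,
        "p_pic_variance": k.p_value_pic_variance,
        "n_perm": k.n_permutations,
        "seed": k.seed,
        "lambda_hat": lam.lambda_hat,
        "lnL": lam.lnL_hat,
        "p_vs_0": lam.p_vs_0,
        "p_vs_1": lam.p_vs_1,
    }


def run_full_analysis(
    tree: PhyloTree,
    traits: TraitTable,
    chars: CharacterData | None = None,
    treeset: TreeSet | None = None,
    tip_map: dict[str, str] | None = None,
    arcsine_sqrt: bool = True,
    n_perm: int = 1000,
    seed: int = DEFAULT_PERMUTATION_SEED,
    recompute_residuals: bool = False,
    derived_state: str = "complex",
    trace_method: str = "mp",
) -> AnalysisReport:
    """Run every pipeline stage and assemble an :class:`AnalysisReport`.

    ``tip_map`` maps tree tips to trait-table species when they differ (tips
    duplicating a species are allowed).  By default the branch-length
    sensitivity fits reuse the residuals from the molecular tree; set
    ``recompute_residuals`` to re-estimate them under each scheme.
    """
    if tip_map is None:
        tip_map = {t: t for t in tree.tip_labels}
    missing = set(tree.tip_labels) - set(tip_map)
    if missing:
        raise ValueError(f"tips without a trait mapping: {sorted(missing)}")

    aligned = duplicate_tip_traits(traits, tip_map)
    derived = derive(aligned, arcsine_sqrt=arcsine_sqrt)
    log_sl = derived["log_sl"]
    log_il = derived["log_il"]
    asin_diet = derived["asin_diet"]

    report = AnalysisReport()
    newick = write_newick(tree)
    digest = hashlib.sha256(
        (newick + traits.data.to_csv(index=False)).encode()
    ).hexdigest()
    report.sections["provenance"] = {
        "version": __version__,
        "input_hash": digest,
        "n_tips": tree.n_tips,
        "n_species": len(traits),
        "seed": seed,
        "arcsine_sqrt": arcsine_sqrt,
        "tree_newick": newick,
    }
    report.sections["derived"] = (
        derived.reset_index().to_dict(orient="list")
    )

    # --- phylogenetic size correction -------------------------------------
    gls = phylo_residuals(tree, log_sl, log_il)
    resid = gls.residuals
    report.sections["size_correction"] = {
        "method": gls.method,
        "intercept": gls.intercept,
        "slope": gls.slope,
        "r_squared": gls.r_squared,
        "residuals": {k: float(v) for k, v in resid.items()},
    }

    # --- phylogenetic signal ----------------------------------------------
    report.sections["signal"] = {
        "intestinal_length_residuals": _signal_dict(tree, resid, n_perm, seed),
        "asin_diet": _signal_dict(tree, asin_diet, n_perm, seed),
    }

    # --- independent contrasts on the input tree --------------------------
    report.sections["pic"] = _pic_fit(tree, resid, asin_diet)

    # --- branch-length sensitivity ----------------------------------------
    sensitivity = {}
    for scheme in BRANCH_LENGTH_SCHEMES:
        alt = transform_branch_lengths(tree, scheme)
        alt_resid = (
            phylo_residuals(alt, log_sl, log_il).residuals
            if recompute_residuals
            else resid
        )
        entry = _pic_fit(alt, alt_resid, asin_diet)
        entry.pop("contrast_table")
        sensitivity[scheme] = entry
    report.sections["sensitivity"] = sensitivity

    # --- phylogenetically naive fit ---------------------------------------
    ols = ols_residuals(log_sl, log_il)
    naive = rma_fit(ols.residuals.to_numpy(), asin_diet.to_numpy())
    report.sections["naive"] = {
        "r_squared": naive.r_squared,
        "rma_slope": naive.slope,
        "p_value": naive.p_value,
        "n": naive.n,
    }

    # --- ancestral state reconstruction ------------------------------------
    if chars is not None:
        mp = mp_reconstruct(tree, chars)
        ml = ml_marginal_asr(tree, chars)
        asr: dict = {
            "alphabet": list(chars.alphabet),
            "mp_tree_length": mp.tree_length,
            "mp_sets": {
                _tipset_key(ts): sorted(states)
                for ts, states in mp.mpr_sets.items()
            },
            "ml_q_hat": ml.q_hat,
            "ml_lnL": ml.lnL,
            "ml_assignments": {
                _tipset_key(ts): state for ts, state in ml.assignments.items()
            },
        }
        if len(chars.alphabet) > 2:
            binary = chars.binarize(
                ancestral="two_loop", derived_label=derived_state
            ) if "two_loop" in chars.alphabet else None
        else:
            binary = chars
        if binary is not None:
            gains, losses = count_origins(tree, binary, derived_state)
            asr["origins"] = {"gains": gains, "losses": losses}
        if treeset is not None:
            trace = trace_over_trees(treeset, chars, tree, method=trace_method)
            asr["trace"] = {
                "method": trace_method,
                "n_trees": trace.n_trees,
                "nodes": {
                    _tipset_key(ts): info for ts, info in trace.nodes.items()
                },
            }
        else:
            asr["trace"] = None
        report.sections["asr"] = asr
    else:
        report.sections["asr"] = None

    report.validate()
    return report
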