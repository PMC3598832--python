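"""Packaged study fixtures: the 28-species trait table, the ingroup topology,
and the intestinal-configuration coding.

The trait table transcribes the published summary of terapontid morphology
and diet (per-species means of standard length and intestinal length in mm,
volumetric percent animal prey, and trophic classification).  The topology is
a transcription of the published maximum-likelihood ingroup tree for the same
28 species; it carries 29 tips because one species (Hannia greenwayi) is
represented by two sequences placed apart in the tree.  Published branch
lengths are not reproduced in the source text, so the fixture tree defaults
to unit branch lengths; supply the archived chronogram (Dryad
doi:10.5061/dryad.h30t5) to reproduce the branch-length-dependent results.

Adult intestinal configurations are coded as a seven-state categorical
character (two_loop, six_loop, pingalla_type, scortum_type, syncomistes_type,
aheneus_type, helotes_type); a binary complex-vs-two_loop collapse is
available via :meth:`CharacterData.binarize`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .asr import DEFAULT_STATES, CharacterData
from .traits import TraitTable, read_traits
from .tree import PhyloTree, parse_newick, transform_branch_lengths

__all__ = [
    "load_traits",
    "load_tree",
    "load_characters",
    "tip_species_map",
    "SEQUENCE_PARTITIONS",
    "POSTERIOR_SETTINGS",
]

# provenance of the molecular dataset underlying the fixture topology
SEQUENCE_PARTITIONS = {"cytb": 1141, "RAG1": 3896, "RAG2": 905}

# settings of the Bayesian tree-set analysis the trace summaries emulate
POSTERIOR_SETTINGS = {
    "generations": 50_000_000,
    "sample_every": 100_000,
    "burnin_fraction": 0.10,
}


def retained_posterior_trees(
    generations: int, sample_every: int, burnin_fraction: float
) -> int:
    """Number of trees kept after sampling and burn-in removal."""
    sampled = generations // sample_every
    return int(sampled - round(burnin_fraction * sampled))


def _data_path(name: str):
    return resources.files("phylodiet.data").joinpath(name)


def load_traits() -> TraitTable:
    """The 28-species trait table."""
    with resources.as_file(_data_path("terapontid_traits.csv")) as p:
        return read_traits(str(p))


def load_tree(branch_lengths: str = "unity") -> PhyloTree:
    """The 29-tip ingroup topology.

    ``branch_lengths`` selects a branch-length scheme (default "unity",
    because the source prints no branch lengths); any scheme accepted by
    :func:`transform_branch_lengths` may be used.
    """
    text = _data_path("terapontid_tree.nwk").read_text().strip()
    tree = parse_newick(text)
    return transform_branch_lengths(tree, branch_lengths)


def tip_species_map(tree: PhyloTree | None = None) -> dict[str, str]:
    """Map tree tips to trait-table species (the two H. greenwayi sequences
    share one species row)."""
    if tree is None:
        tree = load_tree()
    mapping = {}
    for tip in tree.tip_labels:
        if tip.startswith("Hannia_greenwayi"):
            mapping[tip] = "Hannia_greenwayi"
        else:
            mapping[tip] = tip
    return mapping


def load_characters(binary: bool = False) -> CharacterData:
    """The adult intestinal-configuration coding aligned to the tree tips."""
    traits = load_traits()
    series = pd.Series(
        traits.data["config_state"].to_numpy(), index=traits.data["species"]
    )
    tipmap = tip_species_map()
    states = {tip: str(series[sp]) for tip, sp in tipmap.items()}
    chars = CharacterData(states=states, alphabet=DEFAULT_STATES)
    if binary:
        chars = chars.binarize(ancestral="two_loop", derived_label="complex")
    return chars
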