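import numpy as np
import pandas as pd
import pytest

from phylodiet import parse_newick
from phylodiet.simulate import SimConfig, simulate_tree, scale_to_unit_height


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return parse_newick("((A:0.3,B:0.3):0.7,((C:0.5,D:0.5):0.2,E:0.7):0.3);")


def star_tree(n: int, depth: float = 1.0):
    """Star phylogeny resolved into a bifurcating caterpillar with zero-length
    internals, so every pair of tips shares zero covariance."""
    labels = [f"t{i}" for i in range(n)]
    nwk = labels[0] + f":{depth}"
    for lbl in labels[1:-1]:
        nwk = f"({nwk},{lbl}:{depth}):0"
    nwk = f"({nwk},{labels[-1]}:{depth});"
    return parse_newick(nwk)


def random_tree(n_tips: int, seed: int, unit_height: bool = False):
    tree = simulate_tree(SimConfig(n_tips=n_tips, seed=seed))
    return scale_to_unit_height(tree) if unit_height else tree


def random_trait(tree, seed: int) -> pd.Series:
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    return pd.Series(rng.normal(size=len(labels)), index=labels)
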