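import math

import numpy as np
import pytest

from phylodiet import (
    PhyloTree,
    clade_tipsets,
    parse_newick,
    read_treeset,
    transform_branch_lengths,
    vcv_matrix,
    write_newick,
)
from phylodiet.tree import TreeError

from conftest import random_tree, star_tree


class TestParsing:
    def test_three_tip_structure(self, three_tip_tree):
        assert three_tip_tree.n_tips == 3
        assert len(three_tip_tree.root.children) == 2
        assert sorted(three_tip_tree.tip_labels) == ["A", "B", "C"]

    def test_single_tip_accepted_but_unusable_for_contrasts(self):
        tree = parse_newick("(A:1);")
        assert tree.n_tips == 1
        import pandas as pd

        from phylodiet import compute_pics

        with pytest.raises(ValueError):
            compute_pics(tree, pd.Series([1.0], index=["B"]))

    def test_malformed_newick_raises(self):
        with pytest.raises(TreeError, match="malformed"):
            parse_newick("((A:1,B:1:1,C);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeError):
            PhyloTree(parse_newick("((A:1,A:1):1,C:2);").root)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeError, match="finite"):
            parse_newick("((A:1,B:-1):1,C:2);")

    @pytest.mark.parametrize("seed", range(5))
    def test_parse_write_roundtrip(self, seed):
        tree = random_tree(8, seed)
        text = write_newick(tree)
        again = parse_newick(text)
        assert write_newick(again) == text
        assert again.tip_labels == tree.tip_labels

    def test_fixture_topology_has_28_internal_nodes(self):
        from phylodiet import fixtures as fx

        tree = fx.load_tree()
        assert tree.n_tips == 29
        assert sum(1 for _ in tree.internals()) == 28
        assert tree.is_bifurcating


class TestVcv:
    def test_hand_path_sums(self, three_tip_tree):
        C = vcv_matrix(three_tip_tree)
        i = {l: k for k, l in enumerate(C.labels)}
        V = C.values
        assert np.allclose(np.diag(V), 2.0)
        assert V[i["A"], i["B"]] == 1.0
        assert V[i["A"], i["C"]] == 0.0 and V[i["B"], i["C"]] == 0.0

    def test_star_tree_is_scaled_identity(self):
        tree = star_tree(6, depth=2.5)
        V = vcv_matrix(tree).values
        assert np.allclose(V, 2.5 * np.eye(6))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_mrca_paths(self, seed):
        """Each entry equals the enumerated root-to-MRCA path length."""
        tree = random_tree(8, seed)
        C = vcv_matrix(tree)
        # oracle: path enumeration per tip pair
        parents = {}
        depth = {tree.root: 0.0}
        for node in tree.preorder():
            for c in node.children:
                parents[c] = node
                depth[c] = depth[node] + c.length
        tips = {t.label: t for t in tree.tips()}

        def ancestors(node):
            out = [node]
            while node in parents:
                node = parents[node]
                out.append(node)
            return out

        for a in C.labels:
            for b in C.labels:
                anc_a = ancestors(tips[a])
                anc_b = set(ancestors(tips[b]))
                mrca = next(x for x in anc_a if x in anc_b)
                i, j = C.labels.index(a), C.labels.index(b)
                assert C.values[i, j] == pytest.approx(depth[mrca])

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_semidefinite(self, seed):
        V = vcv_matrix(random_tree(10, seed)).values
        eig = np.linalg.eigvalsh(V)
        assert eig.min() > -1e-10

    def test_missing_branch_length_errors(self):
        with pytest.raises(TreeError):
            vcv_matrix(parse_newick("((A:1,B),C:2);"))


class TestBranchLengthSchemes:
    def test_unity_sets_every_length_to_one(self, five_tip_tree):
        t = transform_branch_lengths(five_tip_tree, "unity")
        lengths = [n.length for n in t.preorder() if n is not t.root]
        assert all(l == 1.0 for l in lengths)

    def test_grafen_heights_on_three_tips(self):
        t = transform_branch_lengths(parse_newick("((A,B),C);"),
                                     "grafen_tips_minus_one")
        # root height 2, cherry height 1
        lengths = {}
        for node in t.preorder():
            if node.is_tip:
                lengths[node.label] = node.length
            elif node is not t.root:
                lengths["cherry"] = node.length
        assert lengths == {"cherry": 1.0, "A": 1.0, "B": 1.0, "C": 2.0}

    def test_nee_log_heights_on_three_tips(self):
        t = transform_branch_lengths(parse_newick("((A,B),C);"), "nee_log_tips")
        depths = t.tip_depths()
        assert depths["C"] == pytest.approx(math.log(3))
        assert depths["A"] == pytest.approx(math.log(3))
        cherry = next(n for n in t.internals() if n is not t.root)
        assert cherry.length == pytest.approx(math.log(3) - math.log(2))

    @pytest.mark.parametrize("scheme", [
        "pagel_unit_internodes", "grafen_tips_minus_one", "nee_log_tips",
    ])
    @pytest.mark.parametrize("seed", range(3))
    def test_height_schemes_are_ultrametric(self, scheme, seed):
        tree = random_tree(12, seed)
        t = transform_branch_lengths(tree, scheme)
        depths = list(t.tip_depths().values())
        assert max(depths) - min(depths) < 1e-9

    def test_unity_vcv_diagonal_counts_internodes(self, five_tip_tree):
        t = transform_branch_lengths(five_tip_tree, "unity")
        C = vcv_matrix(t)
        # depth of each tip in internode counts
        expect = {"A": 2, "B": 2, "C": 3, "D": 3, "E": 2}
        for lbl, d in expect.items():
            assert C.values[C.labels.index(lbl), C.labels.index(lbl)] == d


class TestCladeTipsets:
    def test_three_tips(self):
        tree = parse_newick("((A,B),C);")
        sets = set(clade_tipsets(tree).values())
        assert sets == {frozenset("AB"), frozenset("ABC")}

    def test_identical_topologies_give_identical_mappings(self):
        a = clade_tipsets(parse_newick("((A:1,B:2):1,C:1);"))
        b = clade_tipsets(parse_newick("((A:9,B:1):4,C:2);"))
        assert set(a.values()) == set(b.values())

    def test_fixture_has_28_clades(self):
        from phylodiet import fixtures as fx

        assert len(clade_tipsets(fx.load_tree())) == 28


class TestTreeSet:
    def test_repeated_newick(self, tmp_path):
        nwk = "((A:1,B:1):1,C:2);"
        p = tmp_path / "trees.nwk"
        p.write_text((nwk + "\n") * 3)
        ts = read_treeset(str(p))
        assert len(ts) == 3
        assert all(t.n_tips == 3 for t in ts)

    def test_nexus_translate_block(self, tmp_path):
        nexus = (
            "#NEXUS\nBEGIN TAXA;\nDIMENSIONS NTAX=3;\n"
            "TAXLABELS Alpha Beta Gamma;\nEND;\n"
            "BEGIN TREES;\nTRANSLATE 1 Alpha, 2 Beta, 3 Gamma;\n"
            "TREE one = ((1:1,2:1):1,3:2);\nEND;\n"
        )
        p = tmp_path / "trees.nex"
        p.write_text(nexus)
        ts = read_treeset(str(p), format="nexus")
        assert sorted(ts.trees[0].tip_labels) == ["Alpha", "Beta", "Gamma"]

    def test_mismatched_labels_rejected(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n((A:1,B:1):1,D:2);\n")
        with pytest.raises(TreeError, match="tree 1"):
            read_treeset(str(p))

    def test_synthetic_posterior_size(self):
        from phylodiet.simulate import SimConfig, simulate_study

        _, ts, _, _ = simulate_study(SimConfig(n_tips=8, n_posterior=450, seed=3))
        assert len(ts) == 450
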