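import itertools
import math

import numpy as np
import pytest

from phylodiet import (
    CharacterData,
    count_origins,
    mk1_fit,
    ml_marginal_asr,
    mp_reconstruct,
    parse_newick,
    trace_over_trees,
)
from phylodiet.asr import LOG_UNIT_RULE, mk1_lnL, mk1_transition_matrix
from phylodiet.tree import TreeSet, clade_tipsets

from conftest import random_tree


def enumerate_parsimony(tree, chars):
    """Brute-force minimum steps and MPR sets over all internal labelings."""
    internals = [n for n in tree.internals()]
    tips = {t.label: chars.index_of(chars.states[t.label]) for t in tree.tips()}
    k = len(chars.alphabet)
    best = math.inf
    best_labelings = []
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(map(id, internals), combo))

        def state(node):
            return tips[node.label] if node.is_tip else assign[id(node)]

        steps = sum(
            state(node) != state(child)
            for node in tree.internals()
            for child in node.children
        )
        if steps < best:
            best, best_labelings = steps, [combo]
        elif steps == best:
            best_labelings.append(combo)
    tipset_of = clade_tipsets(tree)
    mpr = {}
    for i, node in enumerate(internals):
        mpr[tipset_of[node]] = frozenset(
            chars.alphabet[combo[i]] for combo in best_labelings
        )
    return best, mpr


def enumerate_mk_marginals(tree, chars, q):
    """Brute-force marginal state likelihoods by summing over all labelings."""
    internals = list(tree.internals())
    tips = {t.label: chars.index_of(chars.states[t.label]) for t in tree.tips()}
    k = len(chars.alphabet)
    tipset_of = clade_tipsets(tree)
    total = 0.0
    marg = {tipset_of[n]: np.zeros(k) for n in internals}
    for combo in itertools.product(range(k), repeat=len(internals)):
        assign = dict(zip(map(id, internals), combo))

        def state(node):
            return tips[node.label] if node.is_tip else assign[id(node)]

        prob = 1.0 / k  # uniform root prior
        for node in tree.internals():
            for child in node.children:
                P = mk1_transition_matrix(k, q, child.length)
                prob *= P[state(node), state(child)]
        total += prob
        for i, node in enumerate(internals):
            marg[tipset_of[node]][combo[i]] += prob
    return total, {ts: v / total for ts, v in marg.items()}


def random_character(tree, k, seed):
    rng = np.random.default_rng(seed)
    alphabet = tuple(str(i) for i in range(k))
    states = {t: alphabet[int(rng.integers(k))] for t in tree.tip_labels}
    return CharacterData(states=states, alphabet=alphabet)


class TestParsimony:
    def test_uniform_tips_need_no_steps(self):
        tree = random_tree(7, 1)
        chars = CharacterData(
            states={t: "a" for t in tree.tip_labels}, alphabet=("a", "b")
        )
        mp = mp_reconstruct(tree, chars)
        assert mp.tree_length == 0
        assert all(s == frozenset(["a"]) for s in mp.mpr_sets.values())

    def test_classic_equivocal_root(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        chars = CharacterData(
            states={"A": "1", "B": "1", "C": "0", "D": "0"}, alphabet=("0", "1")
        )
        mp = mp_reconstruct(tree, chars)
        assert mp.tree_length == 1
        assert mp.mpr_sets[frozenset("ABCD")] == frozenset(["0", "1"])

    def test_unscored_tip_errors(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        chars = CharacterData(states={"A": "0", "B": "1"}, alphabet=("0", "1"))
        with pytest.raises(ValueError, match="without a scored state"):
            mp_reconstruct(tree, chars)

    def test_matches_enumeration_on_500_random_cases(self):
        """Tree length and every MPR set agree with exhaustive enumeration
        over all internal labelings for trees up to 6 tips, up to 3 states."""
        rng = np.random.default_rng(123)
        for case in range(500):
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 4))
            tree = random_tree(n, 10_000 + case)
            chars = random_character(tree, k, 20_000 + case)
            mp = mp_reconstruct(tree, chars)
            steps, mpr = enumerate_parsimony(tree, chars)
            assert mp.tree_length == steps
            assert mp.mpr_sets == mpr


class TestCountOrigins:
    def test_single_derived_tip(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        chars = CharacterData(
            states={"A": "derived", "B": "anc", "C": "anc"},
            alphabet=("anc", "derived"),
        )
        assert count_origins(tree, chars, "derived") == (1, 0)

    def test_fixture_three_gains_one_loss(self):
        from phylodiet import fixtures as fx

        tree = fx.load_tree()
        chars = fx.load_characters(binary=True)
        gains, losses = count_origins(tree, chars, "complex")
        assert (gains, losses) == (3, 1)

    def test_loss_sits_on_the_reverted_lineage(self):
        """In the packaged reconstruction, the single loss is the reversion
        on the Hephaestus epirrhinos branch."""
        from phylodiet import fixtures as fx
        from phylodiet.asr import resolve_mp_labeling

        tree = fx.load_tree()
        chars = fx.load_characters(binary=True)
        mp = mp_reconstruct(tree, chars)
        labeling = resolve_mp_labeling(tree, chars, mp, root_prefer="two_loop")
        tipset_of = clade_tipsets(tree)
        for node in tree.preorder():
            if node.is_tip and node.label == "Hephaestus_epirrhinos":
                parent_state = labeling[tipset_of[node.parent]]
                assert parent_state == "complex"
                assert chars.states[node.label] == "two_loop"

    def test_nonbinary_rejected(self):
        tree = random_tree(5, 3)
        chars = random_character(tree, 3, 4)
        with pytest.raises(ValueError, match="binary"):
            count_origins(tree, chars, "0")

    def test_gains_plus_losses_equal_tree_length(self):
        rng = np.random.default_rng(77)
        for case in range(100):
            n = int(rng.integers(3, 7))
            tree = random_tree(n, 30_000 + case)
            chars = random_character(tree, 2, 40_000 + case)
            mp = mp_reconstruct(tree, chars)
            gains, losses = count_origins(tree, chars, "1", mp=mp)
            assert gains + losses == mp.tree_length


class TestMk1:
    def test_transition_matrix_limits(self):
        P0 = mk1_transition_matrix(4, 1.0, 0.0)
        assert np.allclose(P0, np.eye(4))
        Pinf = mk1_transition_matrix(4, 1.0, 1e9)
        assert np.allclose(Pinf, 0.25)

    def test_rows_sum_to_one(self):
        P = mk1_transition_matrix(5, 0.3, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0)

    @pytest.mark.parametrize("q", [0.05, 0.5, 2.0])
    def test_lnL_matches_bruteforce_sum(self, q):
        """Pruning likelihood equals the sum over all internal labelings of
        products of transition probabilities (4 tips, k=2)."""
        tree = parse_newick("((A:0.4,B:0.6):0.3,(C:0.2,D:0.9):0.5);")
        chars = CharacterData(
            states={"A": "0", "B": "1", "C": "0", "D": "0"}, alphabet=("0", "1")
        )
        total, _ = enumerate_mk_marginals(tree, chars, q)
        assert mk1_lnL(tree, chars, q) == pytest.approx(math.log(total), abs=1e-12)

    def test_fit_flags_boundary_for_invariant_character(self):
        tree = random_tree(6, 9)
        chars = CharacterData(
            states={t: "a" for t in tree.tip_labels}, alphabet=("a", "b")
        )
        q, lnL, boundary = mk1_fit(tree, chars)
        assert boundary
        assert q < 1e-4

    def test_lnL_invariant_to_root_placement(self):
        """The symmetric model is reversible, so rerooting the same unrooted
        tree leaves the likelihood unchanged."""
        a = parse_newick("((A:0.4,B:0.6):0.3,(C:0.2,D:0.9):0.5);")
        # same unrooted tree rooted along the A edge
        b = parse_newick("(A:0.1,(B:0.6,(C:0.2,D:0.9):0.8):0.3);")
        chars = CharacterData(
            states={"A": "0", "B": "1", "C": "1", "D": "0"}, alphabet=("0", "1")
        )
        for q in (0.1, 0.9):
            assert mk1_lnL(a, chars, q) == pytest.approx(
                mk1_lnL(b, chars, q), abs=1e-9
            )


class TestMarginalAsr:
    def test_identical_cherry_at_low_rate(self):
        tree = parse_newick("(A:0.01,B:0.01);")
        chars = CharacterData(states={"A": "1", "B": "1"}, alphabet=("0", "1"))
        res = ml_marginal_asr(tree, chars, q=0.01)
        p = res.proportional_likelihoods[frozenset("AB")]
        assert p[chars.index_of("1")] > 0.999

    def test_symmetric_conflict_is_equivocal(self):
        tree = parse_newick("(A:1,B:1);")
        chars = CharacterData(states={"A": "0", "B": "1"}, alphabet=("0", "1"))
        res = ml_marginal_asr(tree, chars, q=0.5)
        p = res.proportional_likelihoods[frozenset("AB")]
        assert p == pytest.approx([0.5, 0.5])
        assert res.assignments[frozenset("AB")] is None

    @pytest.mark.parametrize("seed", range(20))
    def test_marginals_match_enumeration(self, seed):
        """Rerooting-identity marginals equal brute-force enumeration over
        all labelings on trees up to 5 tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        k = int(rng.integers(2, 4))
        tree = random_tree(n, 50_000 + seed)
        chars = random_character(tree, k, 60_000 + seed)
        q = float(rng.uniform(0.05, 2.0))
        res = ml_marginal_asr(tree, chars, q=q)
        _, marg = enumerate_mk_marginals(tree, chars, q)
        for ts, expected in marg.items():
            np.testing.assert_allclose(
                res.proportional_likelihoods[ts], expected, atol=1e-9
            )

    def test_proportional_likelihoods_sum_to_one(self):
        tree = random_tree(10, 70)
        chars = random_character(tree, 3, 71)
        res = ml_marginal_asr(tree, chars)
        for p in res.proportional_likelihoods.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_log_unit_rule_matches_seven_point_four(self):
        assert round(math.exp(LOG_UNIT_RULE), 1) == 7.4


class TestTraceOverTrees:
    def test_identical_trees_give_indicator_frequencies(self):
        tree = random_tree(6, 80)
        chars = random_character(tree, 2, 81)
        ts = TreeSet(trees=[tree.copy() for _ in range(5)], source="test")
        summary = trace_over_trees(ts, chars, tree, method="mp")
        single = mp_reconstruct(tree, chars)
        for tipset, info in summary.nodes.items():
            assert info["n"] == 5
            states = single.mpr_sets[tipset]
            if len(states) == 1:
                assert info["freq"][next(iter(states))] == 1.0
            else:
                assert info["freq"]["equivocal"] == 1.0

    def test_partial_clade_presence(self):
        a = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        b = parse_newick("(((A:1,C:1):1,B:2):1,D:3);")
        chars = CharacterData(
            states={"A": "1", "B": "1", "C": "0", "D": "0"}, alphabet=("0", "1")
        )
        ts = TreeSet(trees=[a, a, b, b], source="test")
        summary = trace_over_trees(ts, chars, a, method="mp")
        assert summary.nodes[frozenset("AB")]["n"] == 2
        assert summary.nodes[frozenset("ABC")]["n"] == 4

    def test_ml_trace_runs_and_normalizes(self):
        tree = random_tree(6, 90, unit_height=True)
        chars = random_character(tree, 2, 91)
        ts = TreeSet(trees=[tree.copy() for _ in range(3)], source="test")
        summary = trace_over_trees(ts, chars, tree, method="ml")
        for info in summary.nodes.values():
            if info["n"]:
                assert sum(info["freq"].values()) == pytest.approx(1.0)

    def test_stability_across_seeds(self):
        """Trace frequencies over two independently jittered posteriors of the
        packaged topology differ by less than 0.1 at every matched node."""
        from phylodiet import fixtures as fx
        from phylodiet.simulate import SimConfig, nni_jitter

        tree = fx.load_tree()
        chars = fx.load_characters(binary=True)
        summaries = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            trees = [nni_jitter(tree, 2, rng) for _ in range(150)]
            ts = TreeSet(trees=trees, source=f"jitter-{seed}")
            summaries.append(trace_over_trees(ts, chars, tree, method="mp"))
        for tipset in summaries[0].nodes:
            a, b = summaries[0].nodes[tipset], summaries[1].nodes[tipset]
            if a["n"] >= 20 and b["n"] >= 20:
                for state in list(chars.alphabet) + ["equivocal"]:
                    assert abs(a["freq"][state] - b["freq"][state]) < 0.1
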