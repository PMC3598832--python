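"""Ancestral state reconstruction of discrete characters.

Two reconstruction routes are provided and are designed to be compared:

* unordered maximum parsimony (Sankoff dynamic programming with unit change
  costs), reporting per-node MPR sets — the states attainable in at least one
  most-parsimonious labeling — with nodes whose set is not a singleton
  flagged equivocal; and
* maximum likelihood under the one-parameter symmetric k-state Markov model
  (Mk1, equal rates between all state pairs), with the single rate fitted by
  bounded search and per-node marginal likelihoods obtained by combining
  subtree and complementary partial likelihoods (the rerooting identity).

ML states are assigned at a node only when the best state's log-likelihood
exceeds every alternative by at least 2 natural-log units (~7.4-fold more
probable); otherwise the node is equivocal.  Reconstruction over a set of
alternative trees is summarized per reference node by matching clades on
their descendant tip sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .tree import Node, PhyloTree, TreeError, TreeSet, clade_tipsets

__all__ = [
    "CharacterData",
    "MPResult",
    "MLAsrResult",
    "TraceSummary",
    "mp_reconstruct",
    "count_origins",
    "mk1_fit",
    "mk1_transition_matrix",
    "ml_marginal_asr",
    "trace_over_trees",
    "LOG_UNIT_RULE",
]

# assignment rule for ML reconstructions: best state must beat every
# alternative by this many natural-log units (e^2 ~ 7.4-fold)
LOG_UNIT_RULE = 2.0

DEFAULT_STATES = (
    "two_loop",
    "six_loop",
    "pingalla_type",
    "scortum_type",
    "syncomistes_type",
    "aheneus_type",
    "helotes_type",
)


@dataclass
class CharacterData:
    """One observed discrete state per tip, over an ordered state alphabet."""

    states: dict[str, str]  # tip label -> state
    alphabet: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alphabet) < 2:
            raise ValueError("need at least 2 states in the alphabet")
        bad = {t: s for t, s in self.states.items() if s not in self.alphabet}
        if bad:
            raise ValueError(f"states outside the alphabet: {bad}")

    @classmethod
    def from_series(
        cls, series: pd.Series, alphabet: tuple[str, ...] | None = None
    ) -> "CharacterData":
        states = {str(k): str(v) for k, v in series.items()}
        if alphabet is None:
            alphabet = tuple(sorted(set(states.values())))
        return cls(states=states, alphabet=alphabet)

    def binarize(
        self, ancestral: str = "two_loop", derived_label: str = "complex"
    ) -> "CharacterData":
        """Collapse to a binary ancestral-vs-derived coding."""
        return CharacterData(
            states={
                t: (ancestral if s == ancestral else derived_label)
                for t, s in self.states.items()
            },
            alphabet=(ancestral, derived_label),
        )

    def index_of(self, state: str) -> int:
        return self.alphabet.index(state)


@dataclass
class MPResult:
    """Most-parsimonious reconstruction: per-node MPR state sets."""

    tree_length: int
    mpr_sets: dict[frozenset[str], frozenset[str]]  # clade tipset -> states

    def equivocal_nodes(self) -> list[frozenset[str]]:
        return [k for k, v in self.mpr_sets.items() if len(v) > 1]


@dataclass
class MLAsrResult:
    """Marginal ML reconstruction under Mk1."""

    q_hat: float
    lnL: float
    alphabet: tuple[str, ...]
    proportional_likelihoods: dict[frozenset[str], np.ndarray]
    assignments: dict[frozenset[str], str | None]  # None = equivocal
    rate_at_boundary: bool = False


@dataclass
class TraceSummary:
    """Per-reference-node state frequencies over a set of trees."""

    alphabet: tuple[str, ...]
    n_trees: int
    # tipset -> {"n": trees containing clade, "freq": {state|equivocal: frac}}
    nodes: dict[frozenset[str], dict] = field(default_factory=dict)


def _tip_state_indices(tree: PhyloTree, chars: CharacterData) -> dict[str, int]:
    missing = [t for t in tree.tip_labels if t not in chars.states]
    if missing:
        raise ValueError(f"tips without a scored state: {sorted(missing)}")
    return {t: chars.index_of(chars.states[t]) for t in tree.tip_labels}


# -------------------------------------------------------------------------------
# Maximum parsimony
# -------------------------------------------------------------------------------


def mp_reconstruct(tree: PhyloTree, chars: CharacterData) -> MPResult:
    """Unordered-parsimony reconstruction with MPR sets.

    Down-pass: Sankoff costs down[v][s] = minimum changes in the subtree of v
    given state s at v, with unit cost for any state change.  Up-pass:
    up[v][s] = minimum changes in the rest of the tree given state s at v.
    State s belongs to the MPR set of v iff down[v][s] + up[v][s] equals the
    tree length, i.e. some most-parsimonious full labeling puts s at v.
    """
    tree.require_bifurcating("parsimony reconstruction")
    k = len(chars.alphabet)
    tip_idx = _tip_state_indices(tree, chars)
    INF = 10**9

    down: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            cost = np.full(k, INF)
            cost[tip_idx[node.label]] = 0
            down[node] = cost
        else:
            total = np.zeros(k)
            for c in down[node.children[0]], down[node.children[1]]:
                # min over child state t of down[c][t] + [t != s]
                best = c.min()
                total = total + np.minimum(c, best + 1)
            down[node] = total

    tree_length = int(down[tree.root].min())

    up: dict[Node, np.ndarray] = {tree.root: np.zeros(k)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            if child.is_tip:
                continue
            sibs = [c for c in node.children if c is not child]
            # cost of the rest of the tree given parent state t
            rest = up[node].copy()
            for s in sibs:
                d = down[s]
                rest = rest + np.minimum(d, d.min() + 1)
            # up[child][s] = min_t rest[t] + [t != s]
            best = rest.min()
            up[child] = np.minimum(rest, best + 1)

    tipset_of = clade_tipsets(tree)
    mpr: dict[frozenset[str], frozenset[str]] = {}
    for node in tree.internals():
        score = down[node] + up[node]
        states = frozenset(
            chars.alphabet[i] for i in range(k) if score[i] == tree_length
        )
        mpr[tipset_of[node]] = states
    return MPResult(tree_length=tree_length, mpr_sets=mpr)


def resolve_mp_labeling(
    tree: PhyloTree, chars: CharacterData, mp: MPResult, root_prefer: str | None = None
) -> dict[frozenset[str], str]:
    """One most-parsimonious labeling, resolving equivocal nodes toward the
    parent's resolved state (accelerated-transformation flavour).

    At the root, ties break toward ``root_prefer`` when given and attainable,
    else toward the first state in alphabet order.  The returned labeling is
    guaranteed to achieve the minimum tree length.
    """
    tree.require_bifurcating("parsimony resolution")
    k = len(chars.alphabet)
    tip_idx = _tip_state_indices(tree, chars)
    INF = 10**9
    down: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            cost = np.full(k, INF)
            cost[tip_idx[node.label]] = 0
            down[node] = cost
        else:
            total = np.zeros(k)
            for c in (down[node.children[0]], down[node.children[1]]):
                total = total + np.minimum(c, c.min() + 1)
            down[node] = total

    tipset_of = clade_tipsets(tree)
    choice: dict[Node, int] = {}
    labeling: dict[frozenset[str], str] = {}
    for node in tree.preorder():
        if node.is_tip:
            choice[node] = tip_idx[node.label]
            continue
        cost = down[node]
        if node is tree.root:
            best = cost.min()
            candidates = [i for i in range(k) if cost[i] == best]
            pick = candidates[0]
            if root_prefer is not None:
                ri = chars.index_of(root_prefer)
                if ri in candidates:
                    pick = ri
        else:
            parent_state = choice[node.parent]
            # optimal child state given the parent: down[v][s] + [s != parent]
            scores = cost + (np.arange(k) != parent_state)
            best = scores.min()
            candidates = [i for i in range(k) if scores[i] == best]
            pick = parent_state if parent_state in candidates else candidates[0]
        choice[node] = pick
        labeling[tipset_of[node]] = chars.alphabet[pick]
    return labeling


def count_origins(
    tree: PhyloTree,
    chars: CharacterData,
    derived_state: str,
    mp: MPResult | None = None,
) -> tuple[int, int]:
    """Count independent gains and losses of ``derived_state`` on a binary
    character, on a parent-preferring most-parsimonious labeling.

    Returns (gains, losses): gains are edges where the ancestral state gives
    way to the derived state, losses the reverse.  For a binary character
    gains + losses equals the parsimony tree length.
    """
    if len(chars.alphabet) != 2:
        raise ValueError("origin counting requires a binary character")
    if derived_state not in chars.alphabet:
        raise ValueError(f"unknown derived state {derived_state!r}")
    ancestral = next(s for s in chars.alphabet if s != derived_state)
    if mp is None:
        mp = mp_reconstruct(tree, chars)
    labeling = resolve_mp_labeling(tree, chars, mp, root_prefer=ancestral)
    tipset_of = clade_tipsets(tree)

    def state_of(node: Node) -> str:
        if node.is_tip:
            return chars.states[node.label]
        return labeling[tipset_of[node]]

    gains = losses = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = state_of(node.parent)
        child_state = state_of(node)
        if parent_state == ancestral and child_state == derived_state:
            gains += 1
        elif parent_state == derived_state and child_state == ancestral:
            losses += 1
    return gains, losses


# -------------------------------------------------------------------------------
# Mk1 maximum likelihood
# -------------------------------------------------------------------------------


def mk1_transition_matrix(k: int, q: float, t: float) -> np.ndarray:
    """Closed-form k-state symmetric (Mk1) transition probabilities.

    P_ii(t) = 1/k + (k-1)/k * exp(-k q t); P_ij(t) = 1/k * (1 - exp(-k q t)).
    At t = 0 this is the identity; as q t grows all entries tend to 1/k.
    """
    e = np.exp(-k * q * t)
    off = (1.0 - e) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def _mk1_partials(
    tree: PhyloTree, chars: CharacterData, q: float
) -> dict[Node, np.ndarray]:
    """Downward conditional likelihoods D[v][s] = P(tips below v | v = s)."""
    k = len(chars.alphabet)
    tip_idx = _tip_state_indices(tree, chars)
    D: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            vec = np.zeros(k)
            vec[tip_idx[node.label]] = 1.0
            D[node] = vec
        else:
            part = np.ones(k)
            for child in node.children:
                P = mk1_transition_matrix(k, q, child.length)
                part = part * (P @ D[child])
            D[node] = part
    return D


def mk1_lnL(tree: PhyloTree, chars: CharacterData, q: float) -> float:
    """Pruning log-likelihood of the character under Mk1 with rate q
    (uniform 1/k root prior)."""
    if not tree.has_branch_lengths():
        raise TreeError("Mk1 likelihood requires branch lengths")
    k = len(chars.alphabet)
    D = _mk1_partials(tree, chars, q)
    like = float(np.sum(D[tree.root]) / k)
    if like <= 0:
        return -np.inf
    return float(np.log(like))


def mk1_fit(
    tree: PhyloTree, chars: CharacterData, q_bounds: tuple[float, float] | None = None
) -> tuple[float, float, bool]:
    """Fit the single Mk1 rate by bounded 1-D maximum likelihood.

    Returns (q_hat, lnL, at_boundary); at_boundary flags a rate estimate
    pinned to an edge of the search bracket (e.g. an invariant character
    drives q toward 0).
    """
    depth = tree.max_depth()
    if depth <= 0:
        raise TreeError("tree has zero depth; cannot fit a rate")
    if q_bounds is None:
        q_bounds = (1e-8 / depth, 1e3 / depth)
    lo, hi = q_bounds
    res = optimize.minimize_scalar(
        lambda lq: -mk1_lnL(tree, chars, float(np.exp(lq))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q_hat = float(np.exp(res.x))
    lnL = -float(res.fun)
    at_boundary = bool(
        res.x - np.log(lo) < 1e-6 or np.log(hi) - res.x < 1e-6
    )
    return q_hat, lnL, at_boundary


def ml_marginal_asr(
    tree: PhyloTree,
    chars: CharacterData,
    q: float | None = None,
    log_unit_rule: float = LOG_UNIT_RULE,
) -> MLAsrResult:
    """Marginal ML ancestral states under Mk1.

    For each internal node the marginal likelihood of each state combines the
    downward partials of its subtree with the complementary likelihood of the
    rest of the tree (computed by a preorder sweep; equivalent to rerooting
    at the node).  Normalized to proportional likelihoods summing to 1.  A
    state is assigned only if its log-likelihood beats every alternative by
    ``log_unit_rule`` natural-log units; otherwise the node is equivocal.
    """
    rate_at_boundary = False
    if q is None:
        q, _, rate_at_boundary = mk1_fit(tree, chars)
    k = len(chars.alphabet)
    D = _mk1_partials(tree, chars, q)
    prior = np.full(k, 1.0 / k)

    # U[v][s]: likelihood of everything outside v's subtree, given v = s,
    # including the root prior
    U: dict[Node, np.ndarray] = {tree.root: prior.copy()}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            rest = U[node].copy()
            for sib in node.children:
                if sib is child:
                    continue
                Ps = mk1_transition_matrix(k, q, sib.length)
                rest = rest * (Ps @ D[sib])
            Pc = mk1_transition_matrix(k, q, child.length)
            U[child] = Pc.T @ rest

    tipset_of = clade_tipsets(tree)
    prop: dict[frozenset[str], np.ndarray] = {}
    assign: dict[frozenset[str], str | None] = {}
    lnL = float(np.log(np.sum(D[tree.root] * prior)))
    for node in tree.internals():
        marg = D[node] * U[node]
        total = marg.sum()
        if total <= 0:
            raise RuntimeError("zero marginal likelihood at an internal node")
        p = marg / total
        key = tipset_of[node]
        prop[key] = p
        with np.errstate(divide="ignore"):
            logs = np.log(p)
        order = np.argsort(logs)[::-1]
        if logs[order[0]] - logs[order[1]] >= log_unit_rule:
            assign[key] = chars.alphabet[order[0]]
        else:
            assign[key] = None
    return MLAsrResult(
        q_hat=float(q),
        lnL=lnL,
        alphabet=chars.alphabet,
        proportional_likelihoods=prop,
        assignments=assign,
        rate_at_boundary=rate_at_boundary,
    )


# -------------------------------------------------------------------------------
# Trace over trees
# -------------------------------------------------------------------------------


def trace_over_trees(
    trees: TreeSet,
    chars: CharacterData,
    reference: PhyloTree,
    method: str = "mp",
) -> TraceSummary:
    """Summarize per-node reconstructions across a set of alternative trees.

    Each internal node of the reference tree is identified by its descendant
    tip set; a tree contributes to that node only if it contains a clade with
    exactly the same tip set.  Over contributing trees, the frequency of each
    uniquely best state (singleton MPR set for parsimony; 2-log-unit winner
    for ML) and the frequency of equivocal reconstructions are reported.
    """
    if method not in ("mp", "ml"):
        raise ValueError("method must be 'mp' or 'ml'")
    ref_nodes = list(clade_tipsets(reference).values())
    counts: dict[frozenset[str], dict[str, int]] = {
        ts: {"n": 0, "equivocal": 0, **{s: 0 for s in chars.alphabet}}
        for ts in ref_nodes
    }
    for tree in trees:
        if method == "mp":
            result = mp_reconstruct(tree, chars)
            best: dict[frozenset[str], str | None] = {
                ts: (next(iter(states)) if len(states) == 1 else None)
                for ts, states in result.mpr_sets.items()
            }
        else:
            result = ml_marginal_asr(tree, chars)
            best = result.assignments
        for ts in ref_nodes:
            if ts not in best:
                continue
            counts[ts]["n"] += 1
            state = best[ts]
            if state is None:
                counts[ts]["equivocal"] += 1
            else:
                counts[ts][state] += 1

    summary = TraceSummary(alphabet=chars.alphabet, n_trees=len(trees))
    for ts, c in counts.items():
        n = c["n"]
        freq = {}
        if n > 0:
            for key in list(chars.alphabet) + ["equivocal"]:
                freq[key] = c[key] / n
        summary.nodes[ts] = {"n": n, "freq": freq}
    return summary
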