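"""Binary-trait parsimony on a rooted phylogeny.

Leaves carry partial AATase/TATase annotations; internal nodes and
unannotated leaves are free.  Small parsimony with unit change cost (Sankoff
dynamic programming, equivalent to Fitch on two states) gives the minimum
number of specificity switches, optionally with the root state constrained —
the comparison of AAT-rooted vs TAT-rooted minimum counts is what supports
an ancestral-AATase hypothesis.  Co-optimal labelings can be enumerated
(small trees) or summarised by the exact union of candidate switch branches
(any tree size), and a leave-one-out parsimony predictor gives a simple
phylogeny-only function-prediction baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .errors import ConfigurationError, InputError
from .io_formats import Phylogeny

STATES: tuple[str, str] = ("AAT", "TAT")
_INF = float("inf")


@dataclass(frozen=True)
class AnnotatedPhylogeny:
    """Rooted tree plus a partial leaf -> {AAT, TAT} state map."""

    phylogeny: Phylogeny
    leaf_states: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = set(self.phylogeny.leaf_labels())
        unknown = set(self.leaf_states) - labels
        if unknown:
            raise InputError(f"annotated leaves not in tree: {sorted(unknown)}")
        bad = {l: s for l, s in self.leaf_states.items() if s not in STATES}
        if bad:
            raise InputError(f"states outside alphabet {STATES}: {bad}")

    def annotated_leaves(self) -> list[str]:
        return sorted(self.leaf_states)

    def masked(self, leaf: str) -> "AnnotatedPhylogeny":
        """Copy with one leaf's annotation removed (for leave-one-out)."""
        return AnnotatedPhylogeny(
            self.phylogeny, {l: s for l, s in self.leaf_states.items() if l != leaf}
        )


@dataclass(frozen=True)
class ParsimonyResult:
    min_changes: int
    root_constraint: str | None
    optimal_root_states: frozenset[str]
    n_optimal_labelings: int
    candidate_switch_edges: frozenset[tuple[str, str]] = frozenset()
    switch_edge_sets: tuple[frozenset[tuple[str, str]], ...] = ()


def _edge_id(child: dendropy.Node) -> tuple[str, str]:
    """Stable name for the edge above ``child``: (parent clade key, child clade key)."""
    def clade_key(node: dendropy.Node) -> str:
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        return leaves[0] if len(leaves) == 1 else f"mrca({leaves[0]},{leaves[-1]},n={len(leaves)})"

    return (clade_key(child.parent_node), clade_key(child))


def _leaf_cost(leaf: dendropy.Node, leaf_states: Mapping[str, str]) -> dict[str, float]:
    state = leaf_states.get(leaf.taxon.label)
    if state is None:
        return {s: 0.0 for s in STATES}  # unannotated: free variable
    return {s: (0.0 if s == state else _INF) for s in STATES}


def _sankoff_costs(
    annotated: AnnotatedPhylogeny,
) -> dict[dendropy.Node, dict[str, float]]:
    """Bottom-up Sankoff cost vectors (unit substitution cost)."""
    costs: dict[dendropy.Node, dict[str, float]] = {}
    for node in annotated.phylogeny.tree.postorder_node_iter():
        if node.is_leaf():
            costs[node] = _leaf_cost(node, annotated.leaf_states)
        else:
            costs[node] = {
                s: sum(
                    min(costs[ch][t] + (0 if t == s else 1) for t in STATES)
                    for ch in node.child_nodes()
                )
                for s in STATES
            }
    return costs


def _count_labelings(
    annotated: AnnotatedPhylogeny,
    costs: dict[dendropy.Node, dict[str, float]],
) -> dict[dendropy.Node, dict[str, int]]:
    """Number of optimal labelings of each subtree given its root state."""
    counts: dict[dendropy.Node, dict[str, int]] = {}
    for node in annotated.phylogeny.tree.postorder_node_iter():
        if node.is_leaf():
            counts[node] = {s: (1 if costs[node][s] == 0 else 0) for s in STATES}
        else:
            counts[node] = {}
            for s in STATES:
                total = 1
                for ch in node.child_nodes():
                    best = min(costs[ch][t] + (0 if t == s else 1) for t in STATES)
                    total *= sum(
                        counts[ch][t]
                        for t in STATES
                        if costs[ch][t] + (0 if t == s else 1) == best
                    )
                counts[node][s] = total
    return counts


def min_changes(
    annotated: AnnotatedPhylogeny, root_constraint: str | None = None
) -> ParsimonyResult:
    """Minimum number of state switches over all labelings consistent with the
    leaf annotations, optionally with the root state fixed."""
    if not annotated.leaf_states:
        raise InputError("no annotated leaves")
    if root_constraint is not None and root_constraint not in STATES:
        raise InputError(f"root constraint {root_constraint!r} not in {STATES}")
    costs = _sankoff_costs(annotated)
    root = annotated.phylogeny.root
    root_costs = costs[root]
    if root_constraint is None:
        best = min(root_costs.values())
        opt_roots = frozenset(s for s in STATES if root_costs[s] == best)
    else:
        best = root_costs[root_constraint]
        if not np.isfinite(best):
            raise InputError(
                f"root constraint {root_constraint!r} incompatible with annotations"
            )
        opt_roots = frozenset({root_constraint})
    counts = _count_labelings(annotated, costs)
    n_opt = sum(counts[root][s] for s in opt_roots)
    candidates = _candidate_switch_edges(annotated, costs, int(best), root_constraint)
    return ParsimonyResult(
        min_changes=int(best),
        root_constraint=root_constraint,
        optimal_root_states=opt_roots,
        n_optimal_labelings=n_opt,
        candidate_switch_edges=candidates,
    )


def _min_with_edge_forced(
    costs: dict[dendropy.Node, dict[str, float]],
    root: dendropy.Node,
    forced_child: dendropy.Node,
    root_constraint: str | None,
) -> float:
    """Minimum changes when the edge above ``forced_child`` must switch state.

    Only nodes on the ancestor chain of the forced edge need recomputation;
    every other subtree keeps its ordinary Sankoff cost.
    """
    chain: list[dendropy.Node] = []
    node = forced_child.parent_node
    while node is not None:
        chain.append(node)
        node = node.parent_node
    forced_cost: dict[str, float] = {}
    below = forced_child
    for i, anc in enumerate(chain):
        new: dict[str, float] = {}
        for s in STATES:
            total = 0.0
            for ch in anc.child_nodes():
                if ch is below:
                    if i == 0:
                        # the forced edge itself: child state must differ
                        c = min(costs[ch][t] + 1 for t in STATES if t != s)
                    else:
                        c = min(forced_cost[t] + (0 if t == s else 1) for t in STATES)
                else:
                    c = min(costs[ch][t] + (0 if t == s else 1) for t in STATES)
                total += c
            new[s] = total
        forced_cost = new
        below = anc
    if root_constraint is None:
        return min(forced_cost.values())
    return forced_cost[root_constraint]


def _candidate_switch_edges(
    annotated: AnnotatedPhylogeny,
    costs: dict[dendropy.Node, dict[str, float]],
    optimum: int,
    root_constraint: str | None,
) -> frozenset[tuple[str, str]]:
    """Edges that carry a switch in at least one minimum-change labeling,
    found exactly by re-optimizing with each edge forced to switch."""
    root = annotated.phylogeny.root
    out: set[tuple[str, str]] = set()
    for node in annotated.phylogeny.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if _min_with_edge_forced(costs, root, node, root_constraint) == optimum:
            out.add(_edge_id(node))
    return frozenset(out)


def enumerate_switch_edges(
    annotated: AnnotatedPhylogeny,
    result: ParsimonyResult,
    limit: int = 100_000,
) -> tuple[frozenset[tuple[str, str]], ...]:
    """All distinct switch-edge sets across minimum-change labelings.

    Enumerates optimal labelings by backtracking over co-optimal Sankoff
    pointers; refuses (ConfigurationError) when more than ``limit`` optimal
    labelings exist — use ``result.candidate_switch_edges`` for the union on
    large trees.
    """
    if result.n_optimal_labelings > limit:
        raise ConfigurationError(
            f"{result.n_optimal_labelings} optimal labelings exceed limit={limit}; "
            "use candidate_switch_edges instead"
        )
    costs = _sankoff_costs(annotated)
    root = annotated.phylogeny.root

    def assignments(node: dendropy.Node, state: str):
        """Yield dicts node->state for optimal labelings of node's subtree
        rooted in ``state``."""
        if node.is_leaf():
            if costs[node][state] == 0:
                yield {node: state}
            return
        child_options = []
        for ch in node.child_nodes():
            best = min(costs[ch][t] + (0 if t == state else 1) for t in STATES)
            opts = [
                t for t in STATES if costs[ch][t] + (0 if t == state else 1) == best
            ]
            child_options.append((ch, opts))

        def rec(i: int, acc: dict):
            if i == len(child_options):
                yield dict(acc)
                return
            ch, opts = child_options[i]
            for t in opts:
                for sub in assignments(ch, t):
                    merged = {**acc, **sub}
                    yield from rec(i + 1, merged)

        for full in rec(0, {node: state}):
            yield full

    edge_sets: set[frozenset[tuple[str, str]]] = set()
    roots = (
        [result.root_constraint] if result.root_constraint else sorted(result.optimal_root_states)
    )
    for rs in roots:
        if costs[root][rs] != result.min_changes:
            continue
        for labeling in assignments(root, rs):
            switches = frozenset(
                _edge_id(node)
                for node in annotated.phylogeny.tree.preorder_node_iter()
                if node.parent_node is not None
                and labeling[node] != labeling[node.parent_node]
            )
            assert len(switches) == result.min_changes
            edge_sets.add(switches)
    return tuple(sorted(edge_sets, key=sorted))


def parsimony_predict(annotated: AnnotatedPhylogeny, query_leaf: str) -> frozenset[str]:
    """States the query leaf takes across all minimum-change labelings.

    A singleton is a confident call; both states means the phylogeny cannot
    decide.  If the query is annotated its annotation is masked first.
    """
    if query_leaf not in annotated.phylogeny.leaf_labels():
        raise InputError(f"query leaf {query_leaf!r} not in tree")
    masked = annotated.masked(query_leaf)
    if not masked.leaf_states:
        raise InputError("no annotated leaves remain after masking the query")
    base = min_changes(masked).min_changes
    possible = set()
    for state in STATES:
        constrained = AnnotatedPhylogeny(
            masked.phylogeny, {**dict(masked.leaf_states), query_leaf: state}
        )
        if min_changes(constrained).min_changes == base:
            possible.add(state)
    return frozenset(possible)


def loo_accuracy(annotated: AnnotatedPhylogeny, undecided_credit: float = 0.0) -> float:
    """Leave-one-out accuracy of the parsimony predictor over annotated leaves.

    Each annotated leaf is masked and predicted from the rest; a prediction
    counts as correct only when it is the singleton of the true state.
    ``undecided_credit`` (default 0, conservative) is awarded when the
    predictor returns both states.
    """
    leaves = annotated.annotated_leaves()
    if len(leaves) < 2:
        raise InputError("leave-one-out needs >= 2 annotated leaves")
    if not 0.0 <= undecided_credit <= 1.0:
        raise ConfigurationError("undecided_credit must be in [0, 1]")
    total = 0.0
    for leaf in leaves:
        predicted = parsimony_predict(annotated, leaf)
        truth = annotated.leaf_states[leaf]
        if predicted == frozenset({truth}):
            total += 1.0
        elif len(predicted) == 2:
            total += undecided_credit
    return total / len(leaves)
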