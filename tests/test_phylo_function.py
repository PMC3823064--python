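import itertools

import numpy as np
import pytest

from specswap import (
    AnnotatedPhylogeny,
    ConfigurationError,
    InputError,
    TreeSpec,
    enumerate_switch_edges,
    fig3_like_tree,
    loo_accuracy,
    min_changes,
    parse_newick,
    parsimony_predict,
    simulate_annotated_tree,
)

STATES = ("AAT", "TAT")


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every labeling of internal nodes and
# unannotated leaves, count edges whose endpoints differ.
# ---------------------------------------------------------------------------

def brute_force_min(annotated, root_constraint=None, collect_edges=False):
    tree = annotated.phylogeny.tree
    nodes = list(tree.preorder_node_iter())
    free = [
        n
        for n in nodes
        if not n.is_leaf() or n.taxon.label not in annotated.leaf_states
    ]
    fixed = {
        n: annotated.leaf_states[n.taxon.label]
        for n in nodes
        if n.is_leaf() and n.taxon.label in annotated.leaf_states
    }
    root = tree.seed_node
    best = None
    best_sets = set()
    for combo in itertools.product(STATES, repeat=len(free)):
        labeling = dict(fixed)
        labeling.update(zip(free, combo))
        if root_constraint and labeling[root] != root_constraint:
            continue
        switches = frozenset(
            id(n) for n in nodes if n.parent_node is not None and labeling[n] != labeling[n.parent_node]
        )
        cost = len(switches)
        if best is None or cost < best:
            best = cost
            best_sets = {switches}
        elif cost == best:
            best_sets.add(switches)
    return (best, best_sets) if collect_edges else best


def random_annotated_tree(rng, n_leaves, annotate_fraction=0.8):
    """Random bifurcating topology with random partial annotations."""
    names = [f"L{i}" for i in range(n_leaves)]
    rng.shuffle(names)

    def build(items):
        if len(items) == 1:
            return items[0]
        split = rng.integers(1, len(items))
        return f"({build(items[:split])},{build(items[split:])})"

    phylo = parse_newick(build(names) + ";")
    annotated = {}
    for name in names:
        if rng.random() < annotate_fraction:
            annotated[name] = STATES[rng.integers(2)]
    if not annotated:
        annotated[names[0]] = "AAT"
    return AnnotatedPhylogeny(phylo, annotated)


class TestMinChanges:
    def test_uniform_states_no_changes_and_forced_root(self):
        annotated = AnnotatedPhylogeny(
            parse_newick("((A,B),(C,D));"),
            {l: "AAT" for l in "ABCD"},
        )
        res = min_changes(annotated)
        assert res.min_changes == 0
        assert res.optimal_root_states == frozenset({"AAT"})

    def test_four_leaf_discordant_matches_enumeration(self):
        annotated = AnnotatedPhylogeny(
            parse_newick("((A,B),(C,D));"),
            {"A": "AAT", "B": "TAT", "C": "AAT", "D": "TAT"},
        )
        assert min_changes(annotated).min_changes == brute_force_min(annotated)

    def test_matches_bruteforce_on_200_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            annotated = random_annotated_tree(rng, n)
            dp_free = min_changes(annotated).min_changes
            assert dp_free == brute_force_min(annotated)
            for root_state in STATES:
                oracle = brute_force_min(annotated, root_state)
                if oracle is None:
                    continue
                assert min_changes(annotated, root_state).min_changes == oracle

    def test_child_order_permutation_invariance(self):
        a = AnnotatedPhylogeny(
            parse_newick("((A,B),(C,(D,E)));"),
            {"A": "AAT", "B": "TAT", "C": "TAT", "D": "AAT", "E": "TAT"},
        )
        b = AnnotatedPhylogeny(
            parse_newick("(((E,D),C),(B,A));"),
            dict(a.leaf_states),
        )
        assert min_changes(a).min_changes == min_changes(b).min_changes

    def test_root_constraint_never_below_unconstrained(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            annotated = random_annotated_tree(rng, int(rng.integers(4, 10)))
            free = min_changes(annotated).min_changes
            constrained = [min_changes(annotated, s).min_changes for s in STATES]
            assert min(constrained) == free
            assert all(c >= free for c in constrained)

    def test_no_annotations_rejected(self):
        phylo = parse_newick("((A,B),C);")
        with pytest.raises(InputError):
            min_changes(AnnotatedPhylogeny(phylo, {}))

    def test_state_outside_alphabet_rejected(self):
        phylo = parse_newick("((A,B),C);")
        with pytest.raises(InputError):
            AnnotatedPhylogeny(phylo, {"A": "XYZ"})


class TestSwitchEdges:
    def test_zero_change_case_empty(self):
        annotated = AnnotatedPhylogeny(parse_newick("((A,B),C);"), {l: "TAT" for l in "ABC"})
        res = min_changes(annotated)
        assert enumerate_switch_edges(annotated, res) == (frozenset(),)
        assert res.candidate_switch_edges == frozenset()

    def test_star_like_single_discordant_leaf(self):
        annotated = AnnotatedPhylogeny(
            parse_newick("((A,B),(C,D));"),
            {"A": "AAT", "B": "AAT", "C": "AAT", "D": "TAT"},
        )
        res = min_changes(annotated)
        assert res.min_changes == 1
        sets = enumerate_switch_edges(annotated, res)
        assert len(sets) == 1
        ((edge,),) = [tuple(s) for s in sets]
        assert edge[1] == "D"  # the pendant edge above the discordant leaf

    def test_matches_bruteforce_edge_sets_on_random_toys(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            annotated = random_annotated_tree(rng, int(rng.integers(3, 8)))
            res = min_changes(annotated)
            got = enumerate_switch_edges(annotated, res)
            _, oracle_sets = brute_force_min(annotated, collect_edges=True)
            assert len(got) == len(oracle_sets)
            assert all(len(s) == res.min_changes for s in got)
            # union of enumerated sets equals the candidate-edge union
            union = frozenset().union(*got) if got else frozenset()
            assert union == res.candidate_switch_edges


class TestPrediction:
    def test_query_inside_uniform_clade(self):
        annotated = AnnotatedPhylogeny(
            parse_newick("(((Q,A),B),(C,D));"),
            {"A": "AAT", "B": "AAT", "C": "TAT", "D": "TAT"},
        )
        assert parsimony_predict(annotated, "Q") == frozenset({"AAT"})

    def test_query_at_clade_boundary_undecided(self):
        annotated = AnnotatedPhylogeny(
            parse_newick("((A,B),(Q,(C,D)));"),
            {"A": "AAT", "B": "AAT", "C": "TAT", "D": "TAT"},
        )
        assert parsimony_predict(annotated, "Q") == frozenset({"AAT", "TAT"})

    def test_missing_query_rejected(self):
        annotated = AnnotatedPhylogeny(parse_newick("(A,B);"), {"A": "AAT", "B": "AAT"})
        with pytest.raises(InputError):
            parsimony_predict(annotated, "nope")

    def test_loo_perfect_on_clade_segregated_states(self):
        annotated = AnnotatedPhylogeny(
            parse_newick("(((A,B),(C,D)),((E,F),(G,H)));"),
            {**{l: "AAT" for l in "ABCD"}, **{l: "TAT" for l in "EFGH"}},
        )
        assert loo_accuracy(annotated) == 1.0

    def test_loo_two_sisters(self):
        annotated = AnnotatedPhylogeny(parse_newick("((A,B),(C,D));"), {"A": "AAT", "B": "AAT"})
        assert loo_accuracy(annotated) == 1.0

    def test_loo_needs_two_annotations(self):
        annotated = AnnotatedPhylogeny(parse_newick("(A,B);"), {"A": "AAT"})
        with pytest.raises(InputError):
            loo_accuracy(annotated)

    def test_loo_degrades_with_more_planted_switches(self):
        def mean_acc(k):
            accs = []
            for seed in range(5):
                annotated, _ = simulate_annotated_tree(
                    TreeSpec(n_leaves=24, n_switches=k, seed=seed)
                )
                accs.append(loo_accuracy(annotated))
            return float(np.mean(accs))

        assert mean_acc(1) >= mean_acc(6)


class TestPlantedSwitches:
    @pytest.mark.parametrize("k", [0, 1, 3, 5])
    def test_planted_count_recovered_exactly(self, k):
        for seed in (0, 1, 2):
            annotated, flipped = simulate_annotated_tree(
                TreeSpec(n_leaves=30, n_switches=k, seed=seed)
            )
            assert min_changes(annotated).min_changes == k
            assert len(flipped) >= k

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_annotated_tree(TreeSpec(n_leaves=6, n_switches=3, seed=0))


class TestFig3LikePreset:
    def test_root_constrained_counts_three_vs_five(self):
        annotated = fig3_like_tree()
        assert min_changes(annotated, "AAT").min_changes == 3
        assert min_changes(annotated, "TAT").min_changes == 5
        free = min_changes(annotated)
        assert free.min_changes == 3
        assert free.optimal_root_states == frozenset({"AAT"})

    def test_annotation_pattern(self):
        annotated = fig3_like_tree()
        states = list(annotated.leaf_states.values())
        assert states.count("AAT") == 12 and states.count("TAT") == 7
        assert annotated.phylogeny.n_leaves() == 92

    def test_candidate_switch_edges_cover_three_tat_clades(self):
        annotated = fig3_like_tree()
        res = min_changes(annotated, "AAT")
        assert len(res.candidate_switch_edges) >= 3
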