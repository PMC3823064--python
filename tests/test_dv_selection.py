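import numpy as np
import pytest

from specswap import (
    MSA,
    ConfigurationError,
    InputError,
    column_profiles,
    dv_score,
    group_candidates,
    map_columns_to_reference,
    pairwise_dv_matrix,
    pick_representatives,
    score_candidates,
    select_dv_positions,
    shortlist,
)
from specswap.dv_selection import DVPosition, DVPositionSet
from specswap.structure_shells import DistanceTable


def _distance_table(distances):
    return DistanceTable(
        tuple((i + 1, "ALA", float(d)) for i, d in enumerate(distances)), "PLP"
    )


def _positions(columns):
    return DVPositionSet(tuple(DVPosition(c, c, 1.0, 0.5) for c in columns))


class TestColumnMapping:
    def test_gapped_reference_mapping(self):
        msa = MSA((("ref", "A-CD"), ("x", "AAAA")))
        table = _distance_table([1.0, 2.0, 3.0])
        assert map_columns_to_reference(msa, "ref", table) == {1: 1, 3: 2, 4: 3}

    def test_length_mismatch_reports_both(self):
        msa = MSA((("ref", "ACDE"), ("x", "AAAA")))
        table = _distance_table([1.0, 2.0])
        with pytest.raises(InputError, match="4.*2"):
            map_columns_to_reference(msa, "ref", table)

    def test_explicit_offset(self):
        msa = MSA((("ref", "ACD"), ("x", "AAA")))
        table = _distance_table([1.0] * 10)
        assert map_columns_to_reference(msa, "ref", table, residue_offset=4) == {
            1: 5,
            2: 6,
            3: 7,
        }

    def test_simulated_msa_maps_onto_simulated_structure(self):
        from specswap import MsaSpec, StructureSpec, simulate_msa, simulate_structure

        msa = simulate_msa(MsaSpec(n_sequences=10, n_columns=25, seed=6))
        model, table = simulate_structure(
            StructureSpec(planted_distances=tuple(np.linspace(2, 20, 25)), seed=6)
        )
        mapping = map_columns_to_reference(msa, "REF", table)
        # the generator keeps the reference row gap-free: identity map
        assert mapping == {c: c for c in range(1, 26)}


class TestSelectDVPositions:
    def _setup(self, distances, fractions):
        cols = "".join("A" for _ in distances)
        n = 4
        # craft per-column modal fractions via explicit sequences
        seqs = []
        for i in range(n):
            seqs.append(
                "".join(
                    "A" if i < round(f * n) else "CDEF"[i % 4] for f in fractions
                )
            )
        msa = MSA(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        profiles = column_profiles(msa)
        table = _distance_table(distances)
        mapping = {c: c for c in range(1, len(distances) + 1)}
        return profiles, mapping, table

    def test_boundary_inclusion_and_exclusion(self):
        profiles, mapping, table = self._setup([14.9, 15.0], [0.25, 0.25])
        chosen = select_dv_positions(profiles, mapping, table, d_max=15.0)
        assert chosen.columns == (1,)  # 15.0 excluded by strict <

    def test_variability_window_closed_open(self):
        profiles, mapping, table = self._setup([1.0, 1.0, 1.0], [0.25, 0.75, 0.5])
        chosen = select_dv_positions(profiles, mapping, table)
        assert chosen.columns == (1, 3)  # 0.75 excluded, 0.25 included

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(21)
        n_cols = 20
        distances = rng.uniform(0, 30, n_cols)
        msa_cols = []
        n_seq = 12
        for _ in range(n_cols):
            k = rng.integers(1, n_seq + 1)
            col = ["A"] * k + [str(c) for c in rng.choice(list("CDEFGHIK"), n_seq - k)]
            msa_cols.append(col)
        seqs = ["".join(msa_cols[c][i] for c in range(n_cols)) for i in range(n_seq)]
        msa = MSA(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        profiles = column_profiles(msa)
        table = _distance_table(distances)
        mapping = {c: c for c in range(1, n_cols + 1)}
        chosen = select_dv_positions(profiles, mapping, table)
        expected = [
            c
            for c in range(1, n_cols + 1)
            if distances[c - 1] < 15.0 and 0.25 <= profiles[c - 1].modal_fraction < 0.75
        ]
        assert list(chosen.columns) == expected


class TestDVScore:
    def test_candidate_equal_to_a_reference_scores_zero(self):
        msa = MSA((("cand", "ACDE"), ("r1", "ACDE"), ("r2", "GGGG")))
        score, cols = dv_score("cand", msa, ["r1", "r2"], _positions([1, 2, 3, 4]))
        assert score == 0 and cols == frozenset()

    def test_differs_from_all_refs_at_two_positions(self):
        msa = MSA((("cand", "WCW"), ("r1", "ACD"), ("r2", "AGE")))
        # position 1: cand W vs A,A -> differs from all; 2: C vs C,G -> matches r1;
        # 3: W vs D,E -> differs from all
        score, cols = dv_score("cand", msa, ["r1", "r2"], _positions([1, 2, 3]))
        assert score == 2 and cols == frozenset({1, 3})

    def test_gap_rules(self):
        msa = MSA((("cand", "-A-"), ("r1", "AA-")))
        score, cols = dv_score("cand", msa, ["r1"], _positions([1, 2, 3]))
        # gap vs residue differs; gap vs gap identical
        assert cols == frozenset({1})

    def test_empty_panel_rejected(self, tiny_msa):
        with pytest.raises(ConfigurationError):
            dv_score("s1", tiny_msa, [], _positions([1]))

    def test_adding_reference_never_raises_score(self, random_msa):
        ids = list(random_msa.ids)
        positions = _positions(list(range(1, random_msa.length + 1)))
        cand = ids[0]
        panel = ids[1:4]
        base, _ = dv_score(cand, random_msa, panel, positions)
        grown, _ = dv_score(cand, random_msa, panel + [ids[4]], positions)
        assert grown <= base


class TestPairwiseMatrix:
    def test_empty_contributing_set_scores_zero(self):
        msa = MSA((("a", "AC"), ("b", "GG")))
        cards = score_candidates(["a", "b"], msa, ["a"], _positions([1, 2]))
        matrix = pairwise_dv_matrix(["a", "b"], cards, msa)
        assert matrix[("a", "b")] == 0  # a matches the panel everywhere

    def test_self_comparison_zero(self, random_msa):
        ids = list(random_msa.ids)[:5]
        cards = score_candidates(
            ids, random_msa, list(random_msa.ids)[5:8], _positions(list(range(1, 20)))
        )
        matrix = pairwise_dv_matrix(ids, cards, random_msa)
        assert all(matrix[(i, i)] == 0 for i in ids)

    def test_matches_bruteforce_and_asymmetry(self):
        msa = MSA(
            (
                ("c1", "WWWAC"),
                ("c2", "WADAC"),
                ("c3", "AAAWW"),
                ("ref", "AAAAA"),
            )
        )
        positions = _positions([1, 2, 3, 4, 5])
        cards = score_candidates(["c1", "c2", "c3"], msa, ["ref"], positions)
        matrix = pairwise_dv_matrix(["c1", "c2", "c3"], cards, msa)
        for i in ("c1", "c2", "c3"):
            for j in ("c1", "c2", "c3"):
                expected = sum(
                    1
                    for col in cards.contributing[i]
                    if msa.sequence(i)[col - 1] != msa.sequence(j)[col - 1]
                )
                assert matrix[(i, j)] == expected
        assert matrix[("c1", "c3")] != matrix[("c3", "c1")]


class TestGrouping:
    def _matrix(self, ids, directed):
        from specswap.dv_selection import PairwiseDVMatrix

        scores = {(i, j): 20 for i in ids for j in ids}
        for i in ids:
            scores[(i, i)] = 0
        scores.update(directed)
        return PairwiseDVMatrix(tuple(ids), scores)

    def test_all_scores_above_cutoff_gives_singletons(self):
        m = self._matrix(["a", "b", "c"], {})
        assert group_candidates(m) == (("a",), ("b",), ("c",))

    def test_transitive_chaining(self):
        m = self._matrix(
            ["a", "b", "c"],
            {("a", "b"): 3, ("b", "a"): 4, ("b", "c"): 2, ("c", "b"): 5},
        )
        assert group_candidates(m) == (("a", "b", "c"),)

    def test_one_directed_low_score_is_not_enough(self):
        m = self._matrix(["a", "b"], {("a", "b"): 3})  # (b, a) stays 20
        assert group_candidates(m) == (("a",), ("b",))

    def test_single_candidate(self):
        m = self._matrix(["only"], {})
        assert group_candidates(m) == (("only",),)

    def test_invariant_under_candidate_reordering(self):
        ids = ["a", "b", "c", "d"]
        directed = {("a", "c"): 1, ("c", "a"): 1, ("b", "d"): 2, ("d", "b"): 2}
        m1 = self._matrix(ids, directed)
        m2 = self._matrix(list(reversed(ids)), directed)
        assert set(group_candidates(m1)) == set(group_candidates(m2))


class TestRepresentatives:
    def test_singleton_group(self):
        part = pick_representatives([("x",)])
        assert part.representatives == ("x",)

    def test_default_policy_lexicographic(self):
        part = pick_representatives([("b", "a")])
        assert part.representatives == ("a",)

    def test_max_score_policy_with_tiebreak(self):
        from specswap.dv_selection import DVScoreCard

        cards = DVScoreCard({"a": 5, "b": 9, "c": 9}, {})
        part = pick_representatives([("a", "b", "c")], policy="max-score", scorecard=cards)
        assert part.representatives == ("b",)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigurationError):
            pick_representatives([("x",)], policy="by-vibes")


class TestRandomizedOracleEquivalence:
    """Full-chain equivalence against brute-force oracles on random alignments."""

    N_SEEDS = 100

    @staticmethod
    def _random_case(seed):
        rng = np.random.default_rng(seed)
        n_seq, n_cols = 20, 50
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = rng.choice(aa, size=(n_seq, n_cols))
        # sprinkle conservation so the variability window is exercised
        for c in range(n_cols):
            k = rng.integers(0, n_seq)
            seqs[rng.choice(n_seq, k, replace=False), c] = rng.choice(aa)
        msa = MSA(tuple((f"s{i:02d}", "".join(row)) for i, row in enumerate(seqs)))
        distances = rng.uniform(0, 30, n_cols)
        return msa, distances

    def test_positions_scores_matrix_groups_match_oracle(self):
        for seed in range(self.N_SEEDS):
            msa, distances = self._random_case(seed)
            profiles = column_profiles(msa)
            table = _distance_table(distances)
            mapping = {c: c for c in range(1, len(distances) + 1)}
            chosen = select_dv_positions(profiles, mapping, table)
            expected_cols = [
                c
                for c in range(1, len(distances) + 1)
                if distances[c - 1] < 15.0
                and 0.25 <= profiles[c - 1].modal_fraction < 0.75
            ]
            assert list(chosen.columns) == expected_cols

            ids = list(msa.ids)
            panel, candidates = ids[:5], ids[5:]
            cards = score_candidates(candidates, msa, panel, chosen)
            seqs = {i: msa.sequence(i) for i in ids}
            for cand in candidates:
                oracle_cols = {
                    col
                    for col in chosen.columns
                    if all(seqs[cand][col - 1] != seqs[r][col - 1] for r in panel)
                }
                assert cards.contributing[cand] == oracle_cols
                assert cards.scores[cand] == len(oracle_cols)

            matrix = pairwise_dv_matrix(candidates, cards, msa)
            for i in candidates[:5]:
                for j in candidates[:5]:
                    oracle = sum(
                        1
                        for col in cards.contributing[i]
                        if seqs[i][col - 1] != seqs[j][col - 1]
                    )
                    assert matrix[(i, j)] == oracle

            groups = group_candidates(matrix, cutoff=9)
            # oracle: union-find over the <9/<9 pair rule
            parent = {c: c for c in candidates}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in candidates:
                for j in candidates:
                    if i != j and matrix[(i, j)] < 9 and matrix[(j, i)] < 9:
                        parent[find(i)] = find(j)
            oracle_groups = {}
            for c in candidates:
                oracle_groups.setdefault(find(c), set()).add(c)
            assert {frozenset(g) for g in groups} == {
                frozenset(g) for g in oracle_groups.values()
            }


def test_planted_cluster_structure_recovered():
    """Three planted sequence clusters over the selected positions come back
    as exactly three groups."""
    rng = np.random.default_rng(99)
    n_cols = 40
    positions = _positions(list(range(1, n_cols + 1)))
    base = {
        0: "".join(rng.choice(list("ACDE"), n_cols)),
        1: "".join(rng.choice(list("FGHI"), n_cols)),
        2: "".join(rng.choice(list("KLMN"), n_cols)),
    }
    records = [("ref", "".join(rng.choice(list("PQRS"), n_cols)))]
    for cluster, seq in base.items():
        for member in range(3):
            mutated = list(seq)
            for pos in rng.choice(n_cols, 4, replace=False):  # within-cluster: 4+4 < 9
                mutated[pos] = "Y"
            records.append((f"c{cluster}m{member}", "".join(mutated)))
    msa = MSA(tuple(records))
    candidates = [r for r, _ in records[1:]]
    cards = score_candidates(candidates, msa, ["ref"], positions)
    matrix = pairwise_dv_matrix(candidates, cards, msa)
    groups = group_candidates(matrix, cutoff=9)
    assert len(groups) == 3
    assert {frozenset(g) for g in groups} == {
        frozenset({f"c{k}m{m}" for m in range(3)}) for k in range(3)
    }


def test_shortlist_strict_threshold():
    from specswap.dv_selection import DVScoreCard

    cards = DVScoreCard({"a": 10, "b": 11, "c": 4}, {})
    assert shortlist(cards, min_score=10) == ["b"]
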