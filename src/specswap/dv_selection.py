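"""Distance-and-variability (D&V) candidate selection.

The idea: positions near the cofactor (< 15 Å) that are moderately variable
(modal residue in 25–75% of sequences) are the ones most likely to determine
substrate specificity.  A candidate sequence scores one point for every such
position where it differs from *all* sequences in a characterized reference
panel; high scorers are divergent near the active site.  Asymmetric pairwise
scores over each sequence's contributing positions, thresholded at < 9 in
both directions, chain candidates into groups, from which one representative
each is picked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .conservation import ColumnProfile
from .errors import ConfigurationError, InputError
from .io_formats import GAP, MSA
from .structure_shells import DEFAULT_D_MAX, DistanceTable

#: Moderate-variability window on the modal non-gap fraction: [low, high).
DEFAULT_F_LOW = 0.25
DEFAULT_F_HIGH = 0.75

#: Pairwise-score cutoff: both directed scores < cutoff puts a pair in one group.
DEFAULT_GROUP_CUTOFF = 9

#: Shortlist threshold: candidates with D&V score strictly above this advance.
DEFAULT_SHORTLIST_MIN_SCORE = 10


# ---------------------------------------------------------------------------
# Column <-> reference residue mapping
# ---------------------------------------------------------------------------

def map_columns_to_reference(
    msa: MSA,
    ref_id: str,
    distances: DistanceTable,
    residue_offset: int | None = None,
) -> dict[int, int]:
    """Bijection from non-gap reference columns (1-based) to structure residue
    numbers.

    The reference sequence's k-th non-gap column maps to the k-th polymer
    residue in the distance table.  When the alignment's ungapped reference
    and the structure disagree in length, an explicit ``residue_offset``
    (structure numbering minus ungapped position) must be supplied.
    """
    ref_seq = msa.sequence(ref_id)
    nongap_cols = [i for i, c in enumerate(ref_seq, start=1) if c != GAP]
    residue_numbers = [num for num, _ in sorted((n, d) for n, _, d in distances.entries)]
    if residue_offset is not None:
        return {col: pos + residue_offset for pos, col in enumerate(nongap_cols, start=1)}
    if len(nongap_cols) != len(residue_numbers):
        raise InputError(
            f"reference {ref_id!r} has {len(nongap_cols)} residues but the structure "
            f"has {len(residue_numbers)}; supply residue_offset to map explicitly"
        )
    return dict(zip(nongap_cols, residue_numbers))


# ---------------------------------------------------------------------------
# Position selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DVPosition:
    column: int  # 1-based alignment column
    residue_number: int  # mapped reference/structure residue
    distance: float  # Å to cofactor
    modal_fraction: float


@dataclass(frozen=True)
class DVPositionSet:
    positions: tuple[DVPosition, ...]

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(p.column for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def select_dv_positions(
    profiles: Sequence[ColumnProfile],
    column_map: Mapping[int, int],
    distances: DistanceTable,
    d_max: float = DEFAULT_D_MAX,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
) -> DVPositionSet:
    """Columns with distance < d_max (strict) and modal fraction in
    [f_low, f_high) — near the cofactor and moderately variable."""
    if not 0 <= f_low < f_high <= 1:
        raise ConfigurationError(f"need 0 <= f_low < f_high <= 1, got {f_low}, {f_high}")
    if d_max <= 0:
        raise ConfigurationError(f"d_max must be positive, got {d_max}")
    dist_by_residue = distances.as_dict()
    chosen: list[DVPosition] = []
    for col in sorted(column_map):
        residue = column_map[col]
        if residue not in dist_by_residue:
            raise InputError(f"column {col} maps to residue {residue} absent from distances")
        d = dist_by_residue[residue]
        f = profiles[col - 1].modal_fraction
        if d < d_max and f_low <= f < f_high:
            chosen.append(DVPosition(col, residue, d, f))
    return DVPositionSet(tuple(chosen))


# ---------------------------------------------------------------------------
# D&V scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DVScoreCard:
    """Per-candidate D&V score and the columns that contributed to it."""

    scores: Mapping[str, int]
    contributing: Mapping[str, frozenset[int]]

    def __getitem__(self, candidate_id: str) -> int:
        return self.scores[candidate_id]


def _differs_from_all(candidate_char: str, reference_chars: Iterable[str]) -> bool:
    # gap vs residue counts as different; gap vs gap as identical
    return all(candidate_char != r for r in reference_chars)


def dv_score(
    candidate_id: str,
    msa: MSA,
    reference_ids: Sequence[str],
    positions: DVPositionSet,
) -> tuple[int, frozenset[int]]:
    """Score one candidate against the reference panel.

    +1 for each selected column where the candidate's symbol differs from the
    symbol of *every* reference sequence at that column.
    """
    if not reference_ids:
        raise ConfigurationError("empty reference panel")
    cand = msa.sequence(candidate_id)
    refs = [msa.sequence(r) for r in reference_ids]
    contributing = frozenset(
        col
        for col in positions.columns
        if _differs_from_all(cand[col - 1], (r[col - 1] for r in refs))
    )
    return len(contributing), contributing


def score_candidates(
    candidate_ids: Sequence[str],
    msa: MSA,
    reference_ids: Sequence[str],
    positions: DVPositionSet,
) -> DVScoreCard:
    scores: dict[str, int] = {}
    contributing: dict[str, frozenset[int]] = {}
    for cid in candidate_ids:
        scores[cid], contributing[cid] = dv_score(cid, msa, reference_ids, positions)
    return DVScoreCard(scores, contributing)


def shortlist(
    scorecard: DVScoreCard, min_score: int = DEFAULT_SHORTLIST_MIN_SCORE
) -> list[str]:
    """Candidates whose D&V score is strictly greater than ``min_score``."""
    return sorted(cid for cid, s in scorecard.scores.items() if s > min_score)


# ---------------------------------------------------------------------------
# Pairwise matrix and grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseDVMatrix:
    """Directed mismatch counts s(i->j) over i's contributing columns.

    Not necessarily symmetric: i and j are compared over the columns that
    contributed to *i's* D&V score, which generally differ from j's.
    """

    candidates: tuple[str, ...]
    scores: Mapping[tuple[str, str], int]

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return self.scores[pair]


def pairwise_dv_matrix(
    candidates: Sequence[str],
    scorecard: DVScoreCard,
    msa: MSA,
) -> PairwiseDVMatrix:
    missing = [c for c in candidates if c not in scorecard.contributing]
    if missing:
        raise InputError(f"no scorecard entry for candidate(s): {missing}")
    seqs = {c: msa.sequence(c) for c in candidates}
    scores: dict[tuple[str, str], int] = {}
    for i in candidates:
        cols = scorecard.contributing[i]
        for j in candidates:
            scores[(i, j)] = sum(
                1 for col in cols if seqs[i][col - 1] != seqs[j][col - 1]
            )
    return PairwiseDVMatrix(tuple(candidates), scores)


@dataclass(frozen=True)
class GroupPartition:
    """Disjoint candidate groups (sorted tuples) covering all candidates."""

    groups: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...]

    def group_of(self, candidate_id: str) -> tuple[str, ...]:
        for g in self.groups:
            if candidate_id in g:
                return g
        raise InputError(f"candidate {candidate_id!r} not in any group")


def group_candidates(
    matrix: PairwiseDVMatrix, cutoff: int = DEFAULT_GROUP_CUTOFF
) -> tuple[tuple[str, ...], ...]:
    """Chain candidates into groups: an undirected edge joins (i, j) when both
    directed scores are < cutoff; groups are the connected components.

    Groups are returned sorted by their smallest member for determinism.
    """
    graph = nx.Graph()
    graph.add_nodes_from(matrix.candidates)
    for i in matrix.candidates:
        for j in matrix.candidates:
            if i < j and matrix[(i, j)] < cutoff and matrix[(j, i)] < cutoff:
                graph.add_edge(i, j)
    groups = [tuple(sorted(comp)) for comp in nx.connected_components(graph)]
    return tuple(sorted(groups, key=lambda g: g[0]))


REPRESENTATIVE_POLICIES = ("lex", "max-score", "manual")


def pick_representatives(
    groups: Sequence[tuple[str, ...]],
    policy: str = "lex",
    scorecard: DVScoreCard | None = None,
    manual_choices: Mapping[int, str] | None = None,
) -> GroupPartition:
    """One representative per group.

    Policies: ``lex`` (lexicographically smallest id — the deterministic
    default standing in for non-computable criteria like gene availability),
    ``max-score`` (largest D&V score, ties broken lexicographically; needs a
    scorecard), ``manual`` (explicit 0-based group index -> id mapping).
    """
    if policy not in REPRESENTATIVE_POLICIES:
        raise ConfigurationError(
            f"unknown policy {policy!r}; choose from {REPRESENTATIVE_POLICIES}"
        )
    reps: list[str] = []
    for gi, group in enumerate(groups):
        if policy == "lex":
            reps.append(min(group))
        elif policy == "max-score":
            if scorecard is None:
                raise ConfigurationError("max-score policy requires a scorecard")
            reps.append(min(group, key=lambda c: (-scorecard.scores[c], c)))
        else:  # manual
            if manual_choices is None or gi not in manual_choices:
                raise ConfigurationError(f"manual policy missing choice for group {gi}")
            choice = manual_choices[gi]
            if choice not in group:
                raise ConfigurationError(f"manual choice {choice!r} not in group {gi}")
            reps.append(choice)
    return GroupPartition(tuple(tuple(g) for g in groups), tuple(reps))
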