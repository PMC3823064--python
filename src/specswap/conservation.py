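"""Column statistics on the alignment.

Covers per-column residue profiles, ClustalX-style quality (q) scores, the
permutation test asking whether active-site columns are more conserved than
random columns, group-conditional conserved-column (Venn) sets at the 75%
level, and pairwise percent identity.

Column indices are 1-based throughout, matching the way structure residue
numbers are printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, InputError
from .io_formats import AMINO_ACIDS, GAP, MSA

#: Conservation level used for the specificity-class Venn analysis.
DEFAULT_CONSERVATION_LEVEL = 0.75


# ---------------------------------------------------------------------------
# Column profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnProfile:
    counts: Mapping[str, int]  # over 20 aa + gap
    modal_residue: str | None  # None for all-gap columns
    modal_fraction: float  # over non-gap residues; 0.0 for all-gap columns
    gap_fraction: float


def column_profiles(msa: MSA) -> list[ColumnProfile]:
    """Residue counts, modal residue/fraction (gap-free denominator) and gap
    fraction for each column."""
    n = msa.n_sequences
    profiles: list[ColumnProfile] = []
    for col in range(1, msa.length + 1):
        column = msa.column(col)
        counts = {aa: column.count(aa) for aa in AMINO_ACIDS + GAP}
        n_gap = counts[GAP]
        n_res = n - n_gap
        if n_res == 0:
            profiles.append(ColumnProfile(counts, None, 0.0, 1.0))
            continue
        modal = max((aa for aa in AMINO_ACIDS), key=lambda aa: (counts[aa], -ord(aa)))
        profiles.append(
            ColumnProfile(counts, modal, counts[modal] / n_res, n_gap / n)
        )
    return profiles


# ---------------------------------------------------------------------------
# q-scores
# ---------------------------------------------------------------------------

def _qscores_profile(msa: MSA, matrix_name: str) -> np.ndarray:
    """ClustalX-style column quality.

    Each residue is projected onto substitution-matrix profile space (its row
    of the matrix over the 20 amino acids).  A column's consensus is the mean
    profile vector of its non-gap residues; each residue scores
    ``1 - d/D`` where ``d`` is its Euclidean distance to the consensus and
    ``D`` the largest inter-residue profile distance in the matrix.  Gaps
    score 0.  The column q-score is 100 x the mean per-sequence score, so a
    gap-free single-residue column scores exactly 100 and an all-gap column 0.
    """
    try:
        mat = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ConfigurationError(f"unknown substitution matrix: {matrix_name!r}") from exc
    vectors = {aa: np.array([float(mat[aa, bb]) for bb in AMINO_ACIDS]) for aa in AMINO_ACIDS}
    d_max = max(
        float(np.linalg.norm(vectors[a] - vectors[b]))
        for a, b in combinations(AMINO_ACIDS, 2)
    )
    scores = np.zeros(msa.length)
    for col in range(1, msa.length + 1):
        column = msa.column(col)
        residues = [c for c in column if c != GAP]
        if not residues:
            scores[col - 1] = 0.0
            continue
        consensus = np.mean([vectors[c] for c in residues], axis=0)
        per_seq = []
        for c in column:
            if c == GAP:
                per_seq.append(0.0)
            else:
                d = float(np.linalg.norm(vectors[c] - consensus))
                per_seq.append(max(0.0, 1.0 - d / d_max))
        scores[col - 1] = 100.0 * float(np.mean(per_seq))
    return scores


def _qscores_simple(msa: MSA, matrix_name: str) -> np.ndarray:
    """Fallback scorer: 100 x modal non-gap fraction x (1 - gap fraction)."""
    profiles = column_profiles(msa)
    return np.array([100.0 * p.modal_fraction * (1.0 - p.gap_fraction) for p in profiles])


QSCORE_SCORERS: dict[str, Callable[[MSA, str], np.ndarray]] = {
    "profile": _qscores_profile,
    "simple": _qscores_simple,
}


def qscores(msa: MSA, matrix: str = "BLOSUM62", scorer: str = "profile") -> np.ndarray:
    """Per-column quality scores on a 0–100 scale (length = n columns).

    ``scorer`` selects the scoring rule: ``"profile"`` (substitution-matrix
    profile distance, ClustalX-style) or ``"simple"`` (modal-fraction based).
    """
    if scorer not in QSCORE_SCORERS:
        raise ConfigurationError(
            f"unknown q-score scorer {scorer!r}; choose from {sorted(QSCORE_SCORERS)}"
        )
    q = QSCORE_SCORERS[scorer](msa, matrix)
    assert q.shape == (msa.length,)
    return np.clip(q, 0.0, 100.0)


def conservation_sum(q: np.ndarray, positions: Iterable[int]) -> float:
    """Sum of q-scores over 1-based column ``positions``."""
    positions = sorted(set(positions))
    if not positions:
        raise ConfigurationError("empty position set")
    if positions[0] < 1 or positions[-1] > len(q):
        raise InputError(f"positions outside 1..{len(q)}")
    return float(sum(q[p - 1] for p in positions))


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    observed_sum: float
    null_samples: int
    null_max: float
    p_value: float
    seed: int


def permutation_test(
    q: np.ndarray,
    observed_positions: Iterable[int],
    eligible_columns: Iterable[int],
    n_perm: int = 100_000,
    seed: int = 0,
    require_subset: bool = True,
) -> PermutationResult:
    """Is the q-score sum of the observed columns high relative to random ones?

    Draws ``n_perm`` sets of ``|observed|`` columns without replacement from
    ``eligible_columns``, sums their q-scores, and reports the add-one
    estimate ``p = (1 + #{null >= observed}) / (1 + n_perm)`` — never exactly
    zero, and consistent with reporting p < 1e-5 after 100,000 draws with no
    exceedance.
    """
    observed = sorted(set(observed_positions))
    eligible = sorted(set(eligible_columns))
    if not observed:
        raise ConfigurationError("empty observed position set")
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    if len(eligible) < len(observed):
        raise ConfigurationError(
            f"need at least {len(observed)} eligible columns, have {len(eligible)}"
        )
    if require_subset and not set(observed) <= set(eligible):
        extra = sorted(set(observed) - set(eligible))
        raise ConfigurationError(
            f"observed positions not all eligible: {extra} "
            "(pass require_subset=False to override)"
        )
    observed_sum = conservation_sum(q, observed)
    rng = np.random.default_rng(seed)
    k = len(observed)
    q_eligible = q[np.array(eligible) - 1]
    # vectorised draws in blocks to bound memory at large n_perm
    n_ge = 0
    null_max = -math.inf
    block = 10_000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        idx = np.argsort(rng.random((m, len(eligible))), axis=1)[:, :k]
        sums = q_eligible[idx].sum(axis=1)
        n_ge += int(np.count_nonzero(sums >= observed_sum - 1e-12))
        null_max = max(null_max, float(sums.max()))
        done += m
    p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(observed_sum, n_perm, null_max, p, seed)


# ---------------------------------------------------------------------------
# Conserved sets / Venn
# ---------------------------------------------------------------------------

def conserved_set(
    msa: MSA,
    subset_ids: Iterable[str],
    level: float = DEFAULT_CONSERVATION_LEVEL,
) -> set[int]:
    """Columns where one residue (gaps excluded) appears in >= ceil(level*n)
    of the subset's sequences."""
    ids = list(dict.fromkeys(subset_ids))
    if not ids:
        raise ConfigurationError("empty sequence subset")
    if not 0 < level <= 1:
        raise ConfigurationError(f"level must be in (0, 1], got {level}")
    sub = msa.subset(ids)
    threshold = math.ceil(level * sub.n_sequences)
    conserved: set[int] = set()
    for col, profile in enumerate(column_profiles(sub), start=1):
        if profile.modal_residue is None:
            continue
        if profile.counts[profile.modal_residue] >= threshold:
            conserved.add(col)
    return conserved


@dataclass(frozen=True)
class VennSets:
    """Conserved-column sets by specificity class (AAT/TAT style grouping)."""

    set_intersection: frozenset[int]  # conserved in >= level of A ∪ B
    set_A_only: frozenset[int]  # conserved in A but not in B
    set_B_only: frozenset[int]  # conserved in B but not in A
    level: float

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.set_intersection), len(self.set_A_only), len(self.set_B_only))


def venn_partition(
    msa: MSA,
    group_A_ids: Iterable[str],
    group_B_ids: Iterable[str],
    level: float = DEFAULT_CONSERVATION_LEVEL,
) -> VennSets:
    """Conserved columns shared by, or exclusive to, two specificity groups.

    The intersection set uses the pooled group at the same level; the "only"
    sets are per-group conserved sets minus the other group's.  Membership
    ignores *which* residue is conserved: a column conserved as Ala in A and
    Ser in B is in both per-group sets and hence in neither "only" set.
    """
    a_ids = list(dict.fromkeys(group_A_ids))
    b_ids = list(dict.fromkeys(group_B_ids))
    if not a_ids or not b_ids:
        raise ConfigurationError("both groups must be nonempty")
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise InputError(f"groups overlap: {sorted(overlap)}")
    cons_a = conserved_set(msa, a_ids, level)
    cons_b = conserved_set(msa, b_ids, level)
    cons_union = conserved_set(msa, a_ids + b_ids, level)
    return VennSets(
        set_intersection=frozenset(cons_union),
        set_A_only=frozenset(cons_a - cons_b),
        set_B_only=frozenset(cons_b - cons_a),
        level=level,
    )


# ---------------------------------------------------------------------------
# Percent identity
# ---------------------------------------------------------------------------

def percent_identity(msa: MSA, id1: str, id2: str) -> float:
    """100 x identical columns / columns where both sequences are non-gap."""
    s1 = msa.sequence(id1)
    s2 = msa.sequence(id2)
    both = [(a, b) for a, b in zip(s1, s2) if a != GAP and b != GAP]
    if not both:
        raise InputError(f"no shared ungapped columns between {id1!r} and {id2!r}")
    same = sum(1 for a, b in both if a == b)
    return 100.0 * same / len(both)


def identity_matrix(msa: MSA, ids: Sequence[str] | None = None) -> np.ndarray:
    """Symmetric percent-identity matrix over ``ids`` (default: all)."""
    ids = list(ids) if ids is not None else list(msa.ids)
    n = len(ids)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = percent_identity(msa, ids[i], ids[j])
    return out
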