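"""Generators emulating every input the analysis consumes.

Each generator is deterministic given its seed and emits objects (and,
optionally, files in the standard formats) that the readers in
``io_formats`` accept unchanged:

* alignments with exactly planted per-column modal-residue fractions and gap
  patterns (plus a gap-free reference row for structure mapping);
* structures with exactly planted residue-to-cofactor distances (one heavy
  atom per residue on a sphere around a single-atom pseudo-cofactor — exact
  distance control beats realism here);
* kinetic rate tables drawn from the ping-pong bi-bi law with multiplicative
  Gaussian noise (constant-CV, the way initial-rate assay error scales);
* annotated trees with k planted specificity-switch clades built so that the
  parsimony minimum is provably k, and a deterministic ~92-leaf preset whose
  constrained-root parsimony counts are 3 (AAT root) and 5 (TAT root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io_formats import (
    AMINO_ACIDS,
    GAP,
    Atom,
    KineticDataset,
    MSA,
    Phylogeny,
    StructureModel,
    parse_newick,
)
from .kinetics import RateLawParams, pingpong_rate
from .phylo_function import AnnotatedPhylogeny
from .structure_shells import DistanceTable

import pandas as pd


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaSpec:
    n_sequences: int = 92
    n_columns: int = 400
    modal_fractions: Sequence[float] | float = 0.5
    gap_probability: float = 0.05
    reference_id: str = "REF"
    seed: int = 0

    def column_targets(self) -> list[float]:
        if isinstance(self.modal_fractions, (int, float)):
            return [float(self.modal_fractions)] * self.n_columns
        targets = [float(f) for f in self.modal_fractions]
        if len(targets) != self.n_columns:
            raise ConfigurationError(
                f"{len(targets)} modal fractions for {self.n_columns} columns"
            )
        return targets


def simulate_msa(spec: MsaSpec) -> MSA:
    """Alignment with per-column planted modal fractions.

    In each column the modal residue is assigned to round(target * n_nongap)
    sequences; the rest draw uniformly from the remaining 19 amino acids, so
    the realized modal fraction matches the target up to rounding.  The
    reference row is kept gap-free so its ungapped length equals the column
    count (and can be mapped onto a structure of ``n_columns`` residues).
    """
    if spec.n_sequences < 2:
        raise ConfigurationError("need at least 2 sequences")
    if not 0 <= spec.gap_probability < 1:
        raise ConfigurationError("gap probability must be in [0, 1)")
    targets = spec.column_targets()
    if any(not 0 <= t <= 1 for t in targets):
        raise ConfigurationError("modal fractions must be in [0, 1]")
    if any(t < 1 / 20 for t in targets):
        raise ConfigurationError("modal fraction below 1/20 is infeasible for 20 symbols")
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_sequences, spec.n_columns
    seqs = np.empty((n, m), dtype="<U1")
    aa = np.array(list(AMINO_ACIDS))
    for col in range(m):
        modal = rng.choice(aa)
        others = aa[aa != modal]
        gaps = rng.random(n) < spec.gap_probability
        gaps[0] = False  # reference row stays ungapped
        nongap_idx = np.flatnonzero(~gaps)
        k = int(round(targets[col] * len(nongap_idx)))
        k = max(k, 1) if targets[col] > 0 else k
        modal_idx = rng.choice(nongap_idx, size=k, replace=False)
        column = np.where(gaps, GAP, "")
        column[nongap_idx] = rng.choice(others, size=len(nongap_idx))
        column[modal_idx] = modal
        seqs[:, col] = column
    ids = [spec.reference_id] + [f"SEQ{i:04d}" for i in range(1, n)]
    return MSA(tuple((rid, "".join(row)) for rid, row in zip(ids, seqs)))


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureSpec:
    planted_distances: Sequence[float] = (5.0,) * 50
    cofactor_name: str = "PLP"
    chain: str = "A"
    seed: int = 0


def simulate_structure(spec: StructureSpec) -> tuple[StructureModel, DistanceTable]:
    """Structure with exactly planted residue-to-cofactor distances.

    A single-atom pseudo-cofactor sits at the origin; residue i contributes
    one CA atom at the planted distance in a random direction.  Returns the
    model together with the planted distance table for closed-loop checks.
    """
    if any(d <= 0 for d in spec.planted_distances):
        raise ConfigurationError("planted distances must be positive")
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    entries: list[tuple[int, str, float]] = []
    for i, dist in enumerate(spec.planted_distances, start=1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        xyz = tuple(float(v) for v in direction * dist)
        atoms.append(
            Atom(
                residue_number=i,
                residue_name="ALA",
                chain=spec.chain,
                atom_name="CA",
                xyz=xyz,
                record_kind="polymer",
                element="C",
            )
        )
        entries.append((i, "ALA", float(dist)))
    atoms.append(
        Atom(
            residue_number=len(atoms) + 1,
            residue_name=spec.cofactor_name,
            chain=spec.chain,
            atom_name="P1",
            xyz=(0.0, 0.0, 0.0),
            record_kind="hetero",
            element="P",
        )
    )
    return StructureModel(tuple(atoms)), DistanceTable(
        tuple(entries), target_description=spec.cofactor_name
    )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsSpec:
    truth: RateLawParams = RateLawParams(kcat=100.0, Km_AA=2.0, Km_cosub=0.5)
    design: tuple[tuple[float, float], ...] = tuple(
        (a, b) for a in (0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0) for b in (0.5, 2.0, 10.0)
    )
    conc_E: float = 1e-8  # M
    noise: float = 0.01  # multiplicative sd (CV)
    enzyme: str = "ENZ1"
    substrate: str = "Asp"
    seed: int = 0


def simulate_kinetics(spec: KineticsSpec) -> KineticDataset:
    """Rates on the ping-pong law times (1 + eps), eps ~ N(0, noise^2).

    Negative draws (possible only at large noise) are resampled.
    """
    if spec.noise < 0:
        raise ConfigurationError("noise must be nonnegative")
    if not spec.design:
        raise ConfigurationError("empty design")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for a, b in spec.design:
        v = pingpong_rate(spec.truth, a, b, spec.conc_E)
        noisy = v * (1 + rng.normal(0, spec.noise)) if spec.noise > 0 else v
        while noisy < 0:
            noisy = v * (1 + rng.normal(0, spec.noise))
        rows.append(
            {
                "enzyme": spec.enzyme,
                "substrate": spec.substrate,
                "conc_aa_mM": a,
                "conc_cosub_mM": b,
                "conc_e": spec.conc_E,
                "rate": noisy,
            }
        )
    return KineticDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Annotated trees with planted switches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSpec:
    n_leaves: int = 92
    n_switches: int = 3
    root_state: str = "AAT"
    seed: int = 0


def _nest(names: Sequence[str]) -> str:
    """Balanced bifurcating newick over the given leaf names."""
    if len(names) == 1:
        return names[0]
    mid = len(names) // 2
    return f"({_nest(names[:mid])},{_nest(names[mid:])})"


def simulate_annotated_tree(
    spec: TreeSpec,
) -> tuple[AnnotatedPhylogeny, frozenset[str]]:
    """Random tree with ``n_switches`` planted specificity-switch clades.

    Construction guarantees the parsimony minimum equals the planted count:
    the tree is a spine of k+1 blocks; block i <= k contains a flipped clade
    next to a root-state clade, so each block independently needs one change
    (lower bound k) and switching exactly the k flipped-clade stem edges
    achieves it.  All leaves are annotated.  Returns the annotated tree and
    the set of flipped-clade leaf names (one clade per planted switch).

    Feasible when ``n_leaves >= 2*n_switches + 1``.
    """
    k = spec.n_switches
    other = "TAT" if spec.root_state == "AAT" else "AAT"
    if spec.root_state not in ("AAT", "TAT"):
        raise ConfigurationError(f"root state must be AAT or TAT, got {spec.root_state!r}")
    if k < 0 or spec.n_leaves < max(2, 2 * k + 1):
        raise ConfigurationError(
            f"cannot plant {k} coherent switches in a {spec.n_leaves}-leaf tree "
            f"(need n_leaves >= {max(2, 2 * k + 1)})"
        )
    rng = np.random.default_rng(spec.seed)
    names = [f"L{i:04d}" for i in range(spec.n_leaves)]
    order = list(rng.permutation(names))
    # sizes: k flipped clades and k+1 clean blocks, each >= 1 leaf
    n_units = 2 * k + 1
    sizes = np.ones(n_units, dtype=int)
    for _ in range(spec.n_leaves - n_units):
        sizes[rng.integers(n_units)] += 1
    pos = 0
    units: list[list[str]] = []
    for s in sizes:
        units.append(order[pos : pos + s])
        pos += s
    flipped_units = units[:k]
    clean_units = units[k:]
    flipped_leaves = frozenset(l for u in flipped_units for l in u)
    # spine: block_i = (clean_i, flipped_i) for i < k; last block is clean only
    blocks = [
        f"({_nest(clean_units[i])},{_nest(flipped_units[i])})" for i in range(k)
    ] + [_nest(clean_units[k])]
    newick = blocks[0]
    for b in blocks[1:]:
        newick = f"({b},{newick})"
    if k == 0:
        newick = _nest(clean_units[0])
        if spec.n_leaves == 1:
            raise ConfigurationError("need at least 2 leaves")
    phylo = parse_newick(newick + ";")
    states = {
        name: (other if name in flipped_leaves else spec.root_state) for name in names
    }
    return AnnotatedPhylogeny(phylo, states), flipped_leaves


def fig3_like_tree(
    n_leaves: int = 92, seed: int = 0
) -> AnnotatedPhylogeny:
    """Deterministic preset emulating the subfamily dendrogram's annotation
    pattern: 12 AAT and 7 TAT annotated leaves, the TATases split across
    three separate clades, plus unannotated padding leaves.

    Built so that constrained-root parsimony yields 3 changes with an AAT
    root and 5 with a TAT root (the unconstrained minimum is 3) — a
    consistency preset, not a reconstruction of the published topology.
    """
    if n_leaves < 19:
        raise ConfigurationError("preset needs at least the 19 annotated leaves")
    rng = np.random.default_rng(seed)
    aat = [f"AAT{i:02d}" for i in range(1, 13)]
    tat = [f"TAT{i}" for i in range(1, 8)]
    pad = [f"U{i:03d}" for i in range(1, n_leaves - 19 + 1)]
    # deal padding leaves round-robin into the 9 clades
    clades: list[list[str]] = [
        aat[0:2], aat[2:4], aat[4:6], aat[6:8], aat[8:10], aat[10:12],
        tat[0:3], tat[3:5], tat[5:7],
    ]
    for i, name in enumerate(pad):
        clades[i % len(clades)].append(name)
    for c in clades:
        rng.shuffle(c)
    A1, A2, A3, A4, A5, A6, T1, T2, T3 = (_nest(c) for c in clades)
    # P_i = (A, (T, A)) scores (1, 2); L = (P1, P2) scores (2, 4);
    # root = (L, P3) scores (3, 5): AAT root -> 3 switches, TAT root -> 5.
    p1 = f"({A1},({T1},{A2}))"
    p2 = f"({A3},({T2},{A4}))"
    p3 = f"({A5},({T3},{A6}))"
    newick = f"(({p1},{p2}),{p3});"
    phylo = parse_newick(newick)
    states = {name: "AAT" for name in aat}
    states.update({name: "TAT" for name in tat})
    return AnnotatedPhylogeny(phylo, states)
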