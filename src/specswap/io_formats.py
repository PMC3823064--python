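"""Readers and writers for the formats the pipeline touches.

Downstream modules never parse files themselves: everything enters the
pipeline through the four domain types defined here (``MSA``,
``StructureModel``, ``Phylogeny``, ``KineticDataset``).  Standard formats are
handled by the standard libraries (Bio.AlignIO for aligned FASTA, Bio.PDB for
coordinate files, dendropy for Newick, pandas for delimited tables); this
module only wraps them into validated containers.

Conventions: residue numbers are 1-based as printed in PDB files; alignment
columns are 1-based; all intervals are closed.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InputError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
VALID_CHARS = frozenset(AMINO_ACIDS + GAP)

KINETIC_COLUMNS = ["enzyme", "substrate", "conc_aa_mM", "conc_cosub_mM", "conc_e", "rate"]


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSA:
    """A gapped protein multiple sequence alignment.

    ``records`` is an ordered list of ``(id, sequence)`` pairs; all sequences
    have equal length and use the 20 standard amino acids plus ``-``.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if 0 in lengths:
            raise AlignmentError("alignment has zero columns")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        bad: dict[str, set[str]] = {}
        for rid, seq in self.records:
            offenders = set(seq) - VALID_CHARS
            if offenders:
                bad[rid] = offenders
        if bad:
            listing = "; ".join(f"{rid}: {''.join(sorted(ch))}" for rid, ch in bad.items())
            raise InputError(f"illegal characters in alignment ({listing})")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def sequence(self, seq_id: str) -> str:
        for rid, seq in self.records:
            if rid == seq_id:
                return seq
        raise InputError(f"sequence id not in alignment: {seq_id!r}")

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, in record order."""
        if not 1 <= col <= self.length:
            raise InputError(f"column {col} outside 1..{self.length}")
        return "".join(seq[col - 1] for _, seq in self.records)

    def subset(self, ids: Iterable[str]) -> "MSA":
        """Row subset preserving the original record order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise InputError(f"ids not in alignment: {sorted(missing)}")
        return MSA(tuple((rid, seq) for rid, seq in self.records if rid in wanted))


def read_alignment(path: str | Path) -> MSA:
    """Read an aligned-FASTA file into an :class:`MSA`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        # AlignIO rejects ragged FASTA; surface it as an alignment error with
        # the offending lengths for debuggability.
        records = list(SeqIO.parse(str(path), "fasta"))
        if records:
            lengths = sorted({len(r.seq) for r in records})
            if len(lengths) > 1:
                raise AlignmentError(
                    f"sequences in {path} are not aligned: lengths {lengths}"
                ) from exc
        raise InputError(f"could not parse {path} as aligned FASTA: {exc}") from exc
    return MSA(tuple((rec.id, str(rec.seq).upper()) for rec in aln))


def write_alignment(msa: MSA, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in msa.records]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    residue_number: int
    residue_name: str
    chain: str
    atom_name: str
    xyz: tuple[float, float, float]
    record_kind: str  # "polymer" | "hetero"
    element: str = ""


@dataclass(frozen=True)
class StructureModel:
    """Flat atom list from a PDB coordinate file (first model only)."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InputError("structure contains no atoms")
        for atom in self.atoms:
            if atom.residue_number <= 0:
                raise InputError(
                    f"non-positive residue number {atom.residue_number} for {atom.atom_name}"
                )
            if not all(np.isfinite(atom.xyz)):
                raise InputError(f"non-finite coordinates for atom {atom.atom_name}")

    def polymer_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.record_kind == "polymer")

    def hetero_atoms(self, residue_name: str | None = None) -> tuple[Atom, ...]:
        het = (a for a in self.atoms if a.record_kind == "hetero")
        if residue_name is None:
            return tuple(het)
        return tuple(a for a in het if a.residue_name == residue_name)

    def polymer_residues(self) -> list[tuple[int, str]]:
        """Ordered unique (residue_number, residue_name) of polymer atoms."""
        seen: dict[int, str] = {}
        for a in self.polymer_atoms():
            seen.setdefault(a.residue_number, a.residue_name)
        return sorted(seen.items())


_HYDROGEN_ELEMENTS = {"H", "D"}


def _is_hydrogen(atom: Atom) -> bool:
    if atom.element:
        return atom.element.upper() in _HYDROGEN_ELEMENTS
    name = atom.atom_name.lstrip("0123456789")
    return name[:1].upper() in _HYDROGEN_ELEMENTS


def read_structure(path: str | Path) -> StructureModel:
    """Read ATOM/HETATM records from a PDB coordinate file.

    Only the first model is used; altLoc indicators other than blank or 'A'
    are skipped so the atom set is deterministic.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise InputError(f"malformed PDB record in {path}: {exc}") from exc
    except ValueError as exc:
        raise InputError(f"malformed coordinate field in {path}: {exc}") from exc
    atoms: list[Atom] = []
    models = list(structure)
    if not models:
        raise InputError(f"no atoms parsed from {path}")
    for chain in models[0]:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            kind = "polymer" if hetflag == " " else "hetero"
            if hetflag == "W":
                kind = "hetero"
            for atom in residue:
                altloc = atom.get_altloc()
                if altloc not in (" ", "A"):
                    continue
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(
                    Atom(
                        residue_number=int(resseq),
                        residue_name=residue.resname.strip(),
                        chain=chain.id if chain.id.strip() else "A",
                        atom_name=atom.get_name(),
                        xyz=(x, y, z),
                        record_kind=kind,
                        element=(atom.element or "").strip(),
                    )
                )
    if not atoms:
        raise InputError(f"no atoms parsed from {path}")
    return StructureModel(tuple(atoms))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a structure as standard fixed-width ATOM/HETATM records."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "ATOM  " if a.record_kind == "polymer" else "HETATM"
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        element = a.element or a.atom_name[:1]
        lines.append(
            f"{record}{i:5d} {name:<4s}{'':1s}{a.residue_name:>3s} {a.chain[:1]}"
            f"{a.residue_number:4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """A rooted tree with uniquely named leaves (dendropy-backed)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise InputError(f"duplicate leaf names: {dupes}")

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def n_leaves(self) -> int:
        return len(self.leaf_labels())


def read_tree(path: str | Path) -> Phylogeny:
    path = Path(path)
    if not path.exists():
        raise InputError(f"tree file not found: {path}")
    return parse_newick(path.read_text())


def parse_newick(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"could not parse Newick: {exc}") from exc
    # collapse any unifurcations introduced by parsing so every internal node
    # has >= 2 children
    tree.suppress_unifurcations()
    return Phylogeny(tree)


def write_tree(phylo: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(
        phylo.tree.as_string(schema="newick", suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# Kinetic dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticDataset:
    """Initial-rate measurements: one row per assay point.

    Columns: enzyme, substrate, conc_aa_mM, conc_cosub_mM, conc_e, rate.
    Concentration units must be consistent across rows (conc_e in M so that
    kcat/Km comes out in M^-1 s^-1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KINETIC_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"kinetic table missing column(s): {missing}")
        num = self.table[["conc_aa_mM", "conc_cosub_mM", "conc_e", "rate"]]
        if (num[["conc_aa_mM", "conc_cosub_mM", "conc_e"]] < 0).any().any():
            raise InputError("negative concentration in kinetic table")
        if not np.isfinite(num["rate"]).all():
            raise InputError("non-finite rate in kinetic table")

    def __len__(self) -> int:
        return len(self.table)

    def for_assay(self, enzyme: str, substrate: str) -> pd.DataFrame:
        sel = self.table[
            (self.table["enzyme"] == enzyme) & (self.table["substrate"] == substrate)
        ]
        if sel.empty:
            raise InputError(f"no rows for enzyme={enzyme!r} substrate={substrate!r}")
        return sel.reset_index(drop=True)


def read_kinetic_table(path: str | Path) -> KineticDataset:
    """Read a comma- or tab-delimited rate table with a header row.

    Rows whose numeric fields cannot be parsed are skipped with a logged
    warning rather than aborting the run.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"kinetic table not found: {path}")
    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise InputError(f"could not parse kinetic table {path}: {exc}") from exc
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in KINETIC_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"kinetic table {path} missing column(s): {missing}")
    numeric_cols = ["conc_aa_mM", "conc_cosub_mM", "conc_e", "rate"]
    converted = raw.copy()
    for col in numeric_cols:
        converted[col] = pd.to_numeric(raw[col], errors="coerce")
    bad = converted[numeric_cols].isna().any(axis=1)
    if bad.any():
        for idx in converted.index[bad]:
            logger.warning(
                "skipping unparseable kinetic row %d: %s",
                idx + 2,  # +1 header, +1 1-based
                raw.loc[idx].to_dict(),
            )
        converted = converted[~bad]
    converted = converted.reset_index(drop=True)
    return KineticDataset(converted[KINETIC_COLUMNS])


def write_kinetic_table(dataset: KineticDataset, path: str | Path) -> None:
    dataset.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Leaf annotations (two-column TSV: leaf_id <tab> state)
# ---------------------------------------------------------------------------

def read_leaf_states(path: str | Path, alphabet: Sequence[str] = ("AAT", "TAT")) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    states: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 'leaf<TAB>state', got {line!r}")
        leaf, state = parts[0].strip(), parts[1].strip()
        if state not in alphabet:
            raise InputError(f"{path}:{lineno}: state {state!r} not in {list(alphabet)}")
        if leaf in states:
            raise InputError(f"{path}:{lineno}: duplicate annotation for {leaf!r}")
        states[leaf] = state
    return states


def write_leaf_states(states: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{leaf}\t{state}\n" for leaf, state in states.items())
    )
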