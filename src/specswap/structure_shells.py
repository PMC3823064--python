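"""Residue-to-cofactor distances and active-site shell assignment.

The active site is anchored on the PLP cofactor (and optionally a bound
ligand such as maleate).  Each polymer residue gets the minimum Euclidean
distance between any of its heavy atoms and any heavy atom of the target
group(s); ascending radial cutoffs then partition residues into shells.  The
first shell defaults to 3.40 Å; shells are spaced roughly 5 Å apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .io_formats import StructureModel, _is_hydrogen

#: Default shell radii in Å: first shell 3.40, then ~5 Å spacing.
DEFAULT_RADII: tuple[float, ...] = (3.40, 11.3, 16.3, 22.0)

#: Default distance cutoff (Å) for "near the active site" position selection.
DEFAULT_D_MAX: float = 15.0


@dataclass(frozen=True)
class DistanceTable:
    """Per-residue minimum heavy-atom distance to a target atom set."""

    entries: tuple[tuple[int, str, float], ...]  # (residue_number, residue_name, Å)
    target_description: str

    def __post_init__(self) -> None:
        for num, _name, dist in self.entries:
            if not (np.isfinite(dist) and dist >= 0):
                raise InputError(f"invalid distance {dist} for residue {num}")

    def distance(self, residue_number: int) -> float:
        for num, _name, dist in self.entries:
            if num == residue_number:
                return dist
        raise InputError(f"residue {residue_number} not in distance table")

    def as_dict(self) -> dict[int, float]:
        return {num: dist for num, _name, dist in self.entries}


@dataclass(frozen=True)
class ShellAssignment:
    """Shell index per residue; ``None`` beyond the outermost radius."""

    entries: tuple[tuple[int, int | None], ...]  # (residue_number, shell 1..k | None)
    radii: tuple[float, ...]

    def shell(self, residue_number: int) -> int | None:
        for num, shell in self.entries:
            if num == residue_number:
                return shell
        raise InputError(f"residue {residue_number} not in shell assignment")

    def residues_in_shell(self, shell_index: int) -> list[int]:
        return [num for num, s in self.entries if s == shell_index]


def residue_min_distances(
    structure: StructureModel,
    target_residue_names: Sequence[str],
    include_hydrogens: bool = False,
) -> DistanceTable:
    """Minimum distance from each polymer residue to the target hetero group(s).

    ``target_residue_names`` selects hetero residues by 3-letter name (e.g.
    ``["PLP"]`` or ``["PLP", "MAE"]``); when several are given the distance is
    the minimum over the union of their atoms.  Hydrogens are excluded unless
    requested (the crystal structures this targets have none).
    """
    if not target_residue_names:
        raise ConfigurationError("empty target selection")
    target_atoms = [
        a
        for name in dict.fromkeys(target_residue_names)
        for a in structure.hetero_atoms(name)
        if include_hydrogens or not _is_hydrogen(a)
    ]
    if not target_atoms:
        raise ConfigurationError(
            f"no hetero atoms match target names {list(target_residue_names)}"
        )
    polymer = [
        a for a in structure.polymer_atoms() if include_hydrogens or not _is_hydrogen(a)
    ]
    if not polymer:
        raise InputError("structure has no polymer atoms")

    target_xyz = np.array([a.xyz for a in target_atoms])  # (m, 3)
    entries: list[tuple[int, str, float]] = []
    for num, name in structure.polymer_residues():
        res_xyz = np.array([a.xyz for a in polymer if a.residue_number == num])
        if res_xyz.size == 0:
            continue  # residue had only hydrogens
        d = np.linalg.norm(res_xyz[:, None, :] - target_xyz[None, :, :], axis=2)
        entries.append((num, name, float(d.min())))
    desc = "+".join(dict.fromkeys(target_residue_names))
    return DistanceTable(tuple(entries), target_description=desc)


def assign_shells(
    distances: DistanceTable, radii: Sequence[float] = DEFAULT_RADII
) -> ShellAssignment:
    """Assign each residue the smallest shell whose (closed) radius contains it."""
    radii = tuple(float(r) for r in radii)
    if not radii:
        raise ConfigurationError("radii list is empty")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ConfigurationError(f"radii must be strictly ascending, got {list(radii)}")
    entries: list[tuple[int, int | None]] = []
    for num, _name, dist in distances.entries:
        shell: int | None = None
        for i, r in enumerate(radii, start=1):
            if dist <= r:
                shell = i
                break
        entries.append((num, shell))
    return ShellAssignment(tuple(entries), radii)


def first_shell_residues(
    structure: StructureModel,
    target_residue_names: Sequence[str],
    cutoff: float = DEFAULT_RADII[0],
) -> list[tuple[int, str]]:
    """Residues with any heavy atom within ``cutoff`` Å of the target group(s)."""
    table = residue_min_distances(structure, target_residue_names)
    return [(num, name) for num, name, dist in table.entries if dist <= cutoff]
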