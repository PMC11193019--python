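"""Atomic models with per-atom charge and radius (PQR dialect).

The electrostatics layer treats a structure as a list of point charges with
radii — the discrete charge density of the Poisson–Boltzmann source term.
Structures are exchanged in the PQR format (PDB-like columns with occupancy
and B-factor replaced by partial charge and radius), the de facto input
format of PB solvers. Both whitespace-delimited and fixed-column PQR files
are accepted; files are written whitespace-delimited.

Charge variants (e.g. a zwitterion with everything neutralised except the
carboxylate) and bound/free state pairs for valence calculations are
constructed here; protonation and force-field assignment are upstream of
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "AtomicModel",
    "ChargeVariant",
    "StatePair",
    "PQRParseError",
    "read_pqr",
    "write_pqr",
    "apply_charge_variant",
    "make_state_pair",
]


class PQRParseError(ValueError):
    """Raised when a PQR line cannot be interpreted; names the line number."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, position (Å), partial charge (e), radius (Å)."""

    name: str
    residue: str
    chain: str
    position: tuple[float, float, float]
    charge: float
    radius: float
    residue_number: int = 0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"atom {self.name}: radius must be >= 0, got {self.radius}")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite position {self.position}")


@dataclass(frozen=True)
class AtomicModel:
    """An ordered collection of atoms; the rho(r) of the PB source term."""

    atoms: tuple[AtomRecord, ...]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        """Sum of partial charges in e (exact bookkeeping identity)."""
        return float(sum(a.charge for a in self.atoms))

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of coordinates in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner) of atom centres in Å."""
        pos = self.positions
        if pos.shape[0] == 0:
            z = np.zeros(3)
            return z, z
        return pos.min(axis=0), pos.max(axis=0)


@dataclass(frozen=True)
class ChargeVariant:
    """Charge edit: zero everything, then restore/assign selected groups.

    ``keep_groups`` maps (residue-name, atom-name) selectors to the charge
    each matched atom receives. With an empty mapping every charge is
    zeroed. Coordinates and radii are never touched, so a variant isolates
    the electrostatic contribution of one functional group (for instance a
    lone −1 e on a carboxylate oxygen of an otherwise neutral ligand).
    """

    keep_groups: dict[tuple[str, str], float] = field(default_factory=dict)
    description: str = ""


@dataclass(frozen=True)
class StatePair:
    """Bound/free configurations of the same system for a valence run.

    The free state is the bound complex with the ligand atoms deleted;
    all shared atoms are bit-identical between the two states. For a
    net-neutral ligand the voltage-coupled energy of the free ligand in
    bulk is zero, so deletion and bulk relocation give identical valence
    slopes.
    """

    state_bound: AtomicModel
    state_free: AtomicModel
    description: str = ""


# --- PQR parsing ------------------------------------------------------------

_FIXED_COLUMNS = {
    # start, end (0-based, end exclusive) of PDB-style fixed columns
    "name": (12, 16),
    "residue": (17, 21),
    "chain": (21, 22),
    "resnum": (22, 27),
    "x": (30, 38),
    "y": (38, 46),
    "z": (46, 54),
}


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    fields = line.split()
    # Free-form PQR: record serial name residue [chain] resnum x y z q r
    try:
        if len(fields) == 11:
            (_, _, name, residue, chain, resnum, x, y, z, q, r) = fields
        elif len(fields) == 10:
            (_, _, name, residue, resnum, x, y, z, q, r) = fields
            chain = ""
        else:
            raise ValueError("unexpected field count")
        return AtomRecord(
            name=name,
            residue=residue,
            chain=chain,
            residue_number=int(resnum),
            position=(float(x), float(y), float(z)),
            charge=float(q),
            radius=float(r),
        )
    except ValueError:
        pass
    # Fixed-column fallback: charge and radius are the last two whitespace
    # fields, coordinates/labels at PDB columns.
    try:
        c = _FIXED_COLUMNS
        name = line[slice(*c["name"])].strip()
        residue = line[slice(*c["residue"])].strip()
        chain = line[slice(*c["chain"])].strip()
        resnum = int(line[slice(*c["resnum"])].strip() or 0)
        x = float(line[slice(*c["x"])])
        y = float(line[slice(*c["y"])])
        z = float(line[slice(*c["z"])])
        q, r = (float(v) for v in line[54:].split()[:2])
        return AtomRecord(
            name=name, residue=residue, chain=chain, residue_number=resnum,
            position=(x, y, z), charge=q, radius=r,
        )
    except (ValueError, IndexError) as exc:
        raise PQRParseError(f"line {lineno}: cannot parse PQR atom record: {line.rstrip()!r}") from exc


def read_pqr(path: str | Path) -> AtomicModel:
    """Read a PQR file into an :class:`AtomicModel`.

    Every ATOM/HETATM line becomes one atom, in file order. Both
    whitespace-delimited and fixed-column dialects are accepted. A
    malformed record raises :class:`PQRParseError` naming the line.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            atoms.append(_parse_atom_line(line, lineno))
    return AtomicModel(atoms=tuple(atoms))


def write_pqr(model: AtomicModel, path: str | Path) -> None:
    """Write a whitespace-delimited PQR file (charges/radii to 4 decimals)."""
    path = Path(path)
    with path.open("w") as handle:
        for i, a in enumerate(model.atoms, start=1):
            chain = a.chain if a.chain else "A"
            handle.write(
                f"ATOM {i:6d} {a.name:<4s} {a.residue:<4s} {chain:1s} "
                f"{a.residue_number:4d} {a.position[0]:10.4f} {a.position[1]:10.4f} "
                f"{a.position[2]:10.4f} {a.charge:8.4f} {a.radius:7.4f}\n"
            )
        handle.write("END\n")


# --- charge variants and state pairs ---------------------------------------


def apply_charge_variant(model: AtomicModel, variant: ChargeVariant) -> AtomicModel:
    """Return a copy of ``model`` with charges replaced per ``variant``.

    Atoms outside every ``keep_groups`` selector get charge 0; matched
    atoms receive the selector's charge. Coordinates, radii and atom
    order are unchanged. A selector that matches nothing is an error.
    """
    matched: dict[tuple[str, str], int] = {key: 0 for key in variant.keep_groups}
    new_atoms: list[AtomRecord] = []
    for atom in model.atoms:
        key = (atom.residue, atom.name)
        if key in variant.keep_groups:
            matched[key] += 1
            new_atoms.append(replace(atom, charge=variant.keep_groups[key]))
        else:
            new_atoms.append(replace(atom, charge=0.0))
    unmatched = [key for key, count in matched.items() if count == 0]
    if unmatched:
        raise ValueError(f"charge-variant selectors matched no atom: {unmatched}")
    return AtomicModel(atoms=tuple(new_atoms))


def _select(model: AtomicModel, residues: Iterable[str] | None,
            chains: Iterable[str] | None) -> np.ndarray:
    residues = set(residues) if residues is not None else None
    chains = set(chains) if chains is not None else None
    mask = np.ones(len(model), dtype=bool)
    for i, a in enumerate(model.atoms):
        if residues is not None and a.residue not in residues:
            mask[i] = False
        if chains is not None and a.chain not in chains:
            mask[i] = False
    return mask


def make_state_pair(
    complex_model: AtomicModel,
    ligand_residues: Sequence[str] | None = None,
    ligand_chains: Sequence[str] | None = None,
    description: str = "",
) -> StatePair:
    """Split a complex into a bound/free pair by deleting the ligand.

    The ligand is selected by residue name and/or chain; it must be a
    non-empty strict subset of the atoms. The bound state is the complex
    itself; the free state is the complex with ligand atoms removed, so
    all shared atoms are bit-identical between the states.
    """
    if ligand_residues is None and ligand_chains is None:
        raise ValueError("must select the ligand by residue and/or chain")
    mask = _select(complex_model, ligand_residues, ligand_chains)
    n_lig = int(mask.sum())
    if n_lig == 0:
        raise ValueError(
            f"ligand selector matched no atoms (residues={ligand_residues}, chains={ligand_chains})"
        )
    if n_lig == len(complex_model):
        raise ValueError("ligand selector matched every atom; must be a strict subset")
    free_atoms = tuple(a for a, is_lig in zip(complex_model.atoms, mask) if not is_lig)
    return StatePair(
        state_bound=complex_model,
        state_free=AtomicModel(atoms=free_atoms),
        description=description,
    )
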