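"""Core chemistry data model: atoms, molecules, systems, trajectories.

A :class:`MolecularSystem` is a flat list of atoms partitioned into molecules,
each molecule carrying a *role* (drug, excipient, counterion or water) that
drives every downstream analysis: the drug crystal is the union of all
drug-role molecules, contacts are evaluated between roles, and water is
excluded from extracted complexes.

Coordinates are taken as already whole and imaged — the analyses operate on a
centered cluster (the restrained-crystal setup), so no periodic unwrapping is
performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .elements import (
    BONDI_RADII,
    LIGHT_ELEMENTS,
    POLAR_ELEMENTS,
    normalize_element,
)

ROLES = ("drug", "excipient", "counterion", "water")


@dataclass
class Atom:
    """A single atom: element, Cartesian coordinates in Å, molecule membership.

    ``vdw_radius`` (Å) and ``partial_charge`` (e) are optional until assigned;
    ``is_heavy`` is derived from the element (anything but H/D).
    """

    atom_id: int
    element: str
    coords: np.ndarray
    molecule_id: int
    vdw_radius: Optional[float] = None
    partial_charge: Optional[float] = None

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.atom_id}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_id}: non-finite coordinates")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.atom_id}: vdW radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element not in LIGHT_ELEMENTS


@dataclass
class Molecule:
    """A molecule: ordered atom ids, bonds (atom-id pairs), role, formal charge."""

    molecule_id: int
    name: str
    role: str
    atom_ids: list[int]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.atom_ids:
            raise ValueError(f"molecule {self.molecule_id}: empty atom list")
        members = set(self.atom_ids)
        for a, b in self.bonds:
            if a not in members or b not in members:
                raise ValueError(
                    f"molecule {self.molecule_id}: bond ({a}, {b}) references "
                    "a non-member atom"
                )


class MolecularSystem:
    """Atoms partitioned into molecules, with array views for analysis.

    Parameters
    ----------
    atoms
        Atoms with ids 0..n-1 in order.
    molecules
        Molecules whose ``atom_ids`` partition the atom set.
    box_edge
        Informational box edge length in Å (no periodicity is applied).
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        molecules: Sequence[Molecule],
        box_edge: Optional[float] = None,
    ):
        self.atoms = list(atoms)
        self.molecules = list(molecules)
        self.box_edge = box_edge

        for i, atom in enumerate(self.atoms):
            if atom.atom_id != i:
                raise ValueError("atom ids must be 0..n-1 in order")
        mol_ids = [m.molecule_id for m in self.molecules]
        if len(set(mol_ids)) != len(mol_ids):
            raise ValueError("duplicate molecule ids")
        seen: dict[int, int] = {}
        for mol in self.molecules:
            for aid in mol.atom_ids:
                if aid in seen:
                    raise ValueError(
                        f"atom {aid} claimed by molecules {seen[aid]} "
                        f"and {mol.molecule_id}"
                    )
                seen[aid] = mol.molecule_id
        if len(seen) != len(self.atoms):
            missing = set(range(len(self.atoms))) - set(seen)
            raise ValueError(f"atoms without a molecule: {sorted(missing)[:5]} ...")
        for atom in self.atoms:
            atom.molecule_id = seen[atom.atom_id]
        self._mol_index = {m.molecule_id: m for m in self.molecules}

    # -- array views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) reference coordinates, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def molecule_index_of_atom(self) -> np.ndarray:
        """(n_atoms,) positional molecule index (0..n_molecules-1) per atom."""
        pos = {m.molecule_id: i for i, m in enumerate(self.molecules)}
        return np.array([pos[a.molecule_id] for a in self.atoms], dtype=int)

    @property
    def roles(self) -> np.ndarray:
        """(n_molecules,) role per molecule, positional order."""
        return np.array([m.role for m in self.molecules])

    def molecule(self, molecule_id: int) -> Molecule:
        return self._mol_index[molecule_id]

    def molecules_with_role(self, role: str) -> list[Molecule]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [m for m in self.molecules if m.role == role]

    def subset(
        self, molecule_ids: Iterable[int], coords: Optional[np.ndarray] = None
    ) -> "MolecularSystem":
        """New system containing only the given molecules, atoms renumbered.

        ``coords`` (full-system frame, Å) overrides the stored reference
        coordinates when given.
        """
        keep = [self._mol_index[mid] for mid in molecule_ids]
        frame = self.coords if coords is None else np.asarray(coords, float)
        new_atoms: list[Atom] = []
        new_mols: list[Molecule] = []
        remap: dict[int, int] = {}
        for new_mid, mol in enumerate(keep):
            for aid in mol.atom_ids:
                remap[aid] = len(new_atoms)
                old = self.atoms[aid]
                new_atoms.append(
                    Atom(
                        atom_id=len(new_atoms),
                        element=old.element,
                        coords=frame[aid].copy(),
                        molecule_id=new_mid,
                        vdw_radius=old.vdw_radius,
                        partial_charge=old.partial_charge,
                    )
                )
            new_mols.append(
                Molecule(
                    molecule_id=new_mid,
                    name=mol.name,
                    role=mol.role,
                    atom_ids=[remap[a] for a in mol.atom_ids],
                    bonds=[(remap[a], remap[b]) for a, b in mol.bonds],
                    formal_charge=mol.formal_charge,
                )
            )
        return MolecularSystem(new_atoms, new_mols, box_edge=self.box_edge)


@dataclass
class Trajectory:
    """A molecular system plus frames of coordinates.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``frame_interval`` is the
    saving interval in ps.
    """

    system: MolecularSystem
    frames: np.ndarray
    frame_interval: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise ValueError(
                f"frames must have shape (n_frames, {self.system.n_atoms}, 3); "
                f"got {self.frames.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def assign_vdw_radii(
    system: MolecularSystem,
    table: Optional[Mapping[str, float]] = None,
    default: Optional[float] = None,
) -> MolecularSystem:
    """Assign van der Waals radii in place from an element table (Bondi default).

    Raises ``KeyError`` naming the element when it is absent from the table
    and no ``default`` is given. Returns the system for chaining.
    """
    tab = BONDI_RADII if table is None else table
    for atom in system.atoms:
        r = tab.get(atom.element, default)
        if r is None:
            raise KeyError(
                f"no van der Waals radius for element {atom.element!r} "
                "and no default provided"
            )
        if r <= 0:
            raise ValueError(f"non-positive radius for element {atom.element!r}")
        atom.vdw_radius = float(r)
    return system


def _hydrogen_attachments(
    system: MolecularSystem, coords: Optional[np.ndarray]
) -> dict[int, int]:
    """Map each hydrogen atom id to its bonded heavy atom id.

    Uses explicit bonds when the molecule has them; otherwise falls back to
    the geometrically nearest heavy atom in the same molecule (requires
    coordinates). Raises when neither source is available.
    """
    attach: dict[int, int] = {}
    pos = system.coords if coords is None else np.asarray(coords, float)
    for mol in system.molecules:
        h_ids = [a for a in mol.atom_ids if not system.atoms[a].is_heavy]
        if not h_ids:
            continue
        if mol.bonds:
            neigh: dict[int, list[int]] = {a: [] for a in mol.atom_ids}
            for a, b in mol.bonds:
                neigh[a].append(b)
                neigh[b].append(a)
            for h in h_ids:
                heavies = [n for n in neigh[h] if system.atoms[n].is_heavy]
                if heavies:
                    attach[h] = heavies[0]
        else:
            heavy = [a for a in mol.atom_ids if system.atoms[a].is_heavy]
            if not heavy:
                continue
            hv = np.array(heavy)
            for h in h_ids:
                d = np.linalg.norm(pos[hv] - pos[h], axis=1)
                attach[h] = int(hv[np.argmin(d)])
    return attach


def assign_polarity(
    system: MolecularSystem,
    polar_elements: frozenset[str] = POLAR_ELEMENTS,
    coords: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-atom boolean polar flags under the element-based default rule.

    N, O, S and P atoms are polar, plus every hydrogen bonded to one of them;
    everything else is nonpolar. Hydrogen attachment uses explicit bonds when
    present and nearest-heavy-atom geometry otherwise. The rule is a pure
    function of elements and bonds, hence idempotent.
    """
    flags = np.array([a.element in polar_elements for a in system.atoms], dtype=bool)
    attach = _hydrogen_attachments(system, coords)
    for atom in system.atoms:
        if not atom.is_heavy:
            parent = attach.get(atom.atom_id)
            if parent is None:
                raise ValueError(
                    f"cannot resolve heavy-atom attachment for hydrogen "
                    f"{atom.atom_id}: no bonds and no heavy atom in molecule"
                )
            flags[atom.atom_id] = system.atoms[parent].element in polar_elements
    return flags


def crystal_selection(system: MolecularSystem) -> set[int]:
    """Molecule ids forming the drug crystal (= all drug-role molecules)."""
    ids = {m.molecule_id for m in system.molecules if m.role == "drug"}
    if not ids:
        raise ValueError("system contains no drug-role molecules")
    return ids
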