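"""Readers and writers for the pipeline's interchange formats.

Trajectories travel as multi-MODEL PDB files (one MODEL per frame) with a
YAML sidecar mapping residue names to molecule roles and display names;
2-D molecule graphs come from SDF (V2000) via RDKit; tabular data (stability
records, descriptor tables) round-trips through CSV. PDB handling is backed
by biotite; only the ATOM/HETATM/MODEL subset is used, coordinates at the
format's fixed 8.3 precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chem_model import Atom, MolecularSystem, Molecule, Trajectory
from .contacts import ComplexSnapshot
from .elements import normalize_element

#: Residue names recognised without an explicit annotation entry.
DEFAULT_ROLE_MAP = {
    "HOH": ("water", "water"),
    "WAT": ("water", "water"),
    "SOL": ("water", "water"),
    "NA": ("counterion", "sodium"),
    "K": ("counterion", "potassium"),
    "CL": ("counterion", "chloride"),
}


@dataclass
class TopologyAnnotation:
    """Residue-name → (role, molecule name) mapping with built-in water/ion defaults."""

    roles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def resolve(self, res_name: str) -> tuple[str, str]:
        key = res_name.strip().upper()
        if key in self.roles:
            return self.roles[key]
        if key in DEFAULT_ROLE_MAP:
            return DEFAULT_ROLE_MAP[key]
        raise KeyError(
            f"residue name {res_name!r} has no role annotation; add it to the "
            "roles mapping"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TopologyAnnotation":
        data = yaml.safe_load(Path(path).read_text())
        roles = {}
        for res, spec in (data or {}).items():
            if isinstance(spec, str):
                roles[res.strip().upper()] = (spec, res)
            else:
                roles[res.strip().upper()] = (spec["role"], spec.get("name", res))
        return cls(roles=roles)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            res: {"role": role, "name": name}
            for res, (role, name) in sorted(self.roles.items())
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


_NAME_TO_ELEMENT_PREFIXES = ("CL", "BR", "NA", "MG", "SI")


def _element_from_atom_name(name: str) -> str:
    """Infer an element from a PDB atom name (e.g. 'CA ' -> C, 'CL1' -> Cl)."""
    s = name.strip().upper()
    s = s.lstrip("0123456789")
    if not s:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if s[:2] in _NAME_TO_ELEMENT_PREFIXES:
        return normalize_element(s[:2])
    return normalize_element(s[0])


def read_structure(
    path: str | Path, annotation: Optional[TopologyAnnotation] = None
) -> Trajectory:
    """Multi-MODEL PDB → Trajectory; molecules grouped by (chain, residue).

    Elements come from the element column when present and are inferred from
    atom names otherwise. Every residue name must resolve to a role through
    ``annotation`` (or the built-in water/ion defaults). Raises when models
    have inconsistent atom counts.
    """
    annotation = annotation or TopologyAnnotation()
    path = Path(path)
    if annotation.roles == {} :
        sidecar = path.with_suffix(path.suffix + ".roles.yaml")
        if sidecar.exists():
            annotation = TopologyAnnotation.from_yaml(sidecar)
    pdb = PDBFile.read(str(path))
    # element columns (77-78) of the first model's atom records; biotite
    # guesses elements for blanks, but our name-based inference handles
    # two-letter elements (Cl, Br, Na) written without the element field
    raw_elements: list[str] = []
    for line in pdb.lines:
        if line.startswith(("ATOM", "HETATM")):
            raw_elements.append(line[76:78].strip() if len(line) >= 78 else "")
        elif line.startswith("ENDMDL"):
            break
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(f"{path}: inconsistent MODEL records ({exc})") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    n_atoms = stack.array_length()
    elements = []
    for i in range(n_atoms):
        el = raw_elements[i] if i < len(raw_elements) else ""
        if not el and stack.element[i]:
            el = ""  # fall through to name inference for blank columns
        if el:
            elements.append(normalize_element(el))
        else:
            try:
                elements.append(_element_from_atom_name(stack.atom_name[i]))
            except ValueError as exc:
                raise ValueError(f"{path}: atom record {i}: {exc}") from exc

    # group into molecules by (chain, res_id)
    keys = list(zip(stack.chain_id, stack.res_id))
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    coords0 = stack.coord[0]
    atoms: list[Atom] = []
    mols: list[Molecule] = []
    new_index: dict[int, int] = {}
    for mol_id, key in enumerate(order):
        members = groups[key]
        res_name = stack.res_name[members[0]]
        role, name = annotation.resolve(res_name)
        ids = []
        for i in members:
            new_index[i] = len(atoms)
            ids.append(len(atoms))
            atoms.append(
                Atom(
                    atom_id=len(atoms),
                    element=elements[i],
                    coords=coords0[i],
                    molecule_id=mol_id,
                )
            )
        mols.append(Molecule(molecule_id=mol_id, name=name, role=role, atom_ids=ids))

    perm = np.array([i for i in sorted(new_index, key=new_index.get)])
    frames = stack.coord[:, perm, :]
    system = MolecularSystem(atoms, mols)
    return Trajectory(system, frames)


def _res_codes(system: MolecularSystem) -> dict[str, str]:
    """Unique 3-char residue code per distinct molecule name."""
    codes: dict[str, str] = {}
    used: set[str] = set()
    for mol in system.molecules:
        if mol.name in codes:
            continue
        base = "".join(c for c in mol.name.upper() if c.isalnum())[:3] or "MOL"
        code = base
        k = 0
        while code in used:
            k += 1
            code = (base[:2] + str(k))[:3]
        codes[mol.name] = code
        used.add(code)
    return codes


def _to_atom_array(system: MolecularSystem, coords: np.ndarray, codes) -> struc.AtomArray:
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, float)
    pos = {m.molecule_id: i for i, m in enumerate(system.molecules)}
    counters: dict[int, int] = {}
    for atom in system.atoms:
        i = atom.atom_id
        mol = system.molecule(atom.molecule_id)
        mi = pos[mol.molecule_id]
        counters[mi] = counters.get(mi, 0) + 1
        arr.chain_id[i] = "A"
        arr.res_id[i] = mi + 1
        arr.res_name[i] = codes[mol.name]
        arr.atom_name[i] = f"{atom.element}{counters[mi]}"[:4]
        arr.element[i] = atom.element.upper()
        arr.hetero[i] = True
    return arr


def write_structure(
    traj_or_system: Trajectory | MolecularSystem,
    path: str | Path,
    write_roles: bool = True,
) -> None:
    """System or trajectory → (multi-)MODEL PDB + role sidecar YAML."""
    if isinstance(traj_or_system, Trajectory):
        system = traj_or_system.system
        frames = traj_or_system.frames
    else:
        system = traj_or_system
        frames = system.coords[None, :, :]
    codes = _res_codes(system)
    arrays = [_to_atom_array(system, f, codes) for f in frames]
    stack = struc.stack(arrays) if len(arrays) > 1 else arrays[0]
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if write_roles:
        ann = TopologyAnnotation(
            roles={codes[m.name]: (m.role, m.name) for m in system.molecules}
        )
        p = Path(path)
        ann.to_yaml(p.with_suffix(p.suffix + ".roles.yaml"))


def write_complex_pdb(snapshot: ComplexSnapshot, path: str | Path) -> None:
    """Extracted complex (crystal + adsorbed molecules, no water) → PDB."""
    if snapshot.system.n_atoms == 0:
        raise ValueError("empty snapshot")
    if any(m.role == "water" for m in snapshot.system.molecules):
        raise ValueError("complex snapshot must not contain water")
    write_structure(snapshot.system, path)


def read_molecule_2d(path: str | Path) -> MolecularSystem:
    """SDF (V2000) → one-molecule system with explicit hydrogens (graph only)."""
    from rdkit import Chem

    from .compounds import from_rdkit

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"{path}: no parseable molecule record")
    mol = Chem.AddHs(mols[0])
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else Path(path).stem
    return from_rdkit(mol, name or Path(path).stem)


def write_stability_table(records: Sequence, path: str | Path) -> None:
    """Stability records → CSV (empty min_wt_pct field encodes failure)."""
    rows = [
        {
            "drug": r.drug,
            "excipient": r.excipient,
            "min_wt_pct": "" if r.min_wt_pct is None else r.min_wt_pct,
            "success": int(bool(r.success)),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["drug", "excipient", "min_wt_pct", "success"])
    keys = list(zip(df["drug"], df["excipient"]))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (drug, excipient) keys")
    df.to_csv(path, index=False)


def read_stability_table(path: str | Path) -> list:
    """CSV → stability records; duplicate (drug, excipient) keys are an error."""
    from .models import StabilityRecord

    df = pd.read_csv(path)
    keys = list(zip(df["drug"], df["excipient"]))
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate (drug, excipient) keys")
    records = []
    for _, row in df.iterrows():
        raw = row.get("min_wt_pct", None)
        min_wt = None if pd.isna(raw) or raw == "" else float(raw)
        success = None
        if "success" in df.columns and not pd.isna(row["success"]):
            success = bool(int(row["success"]))
        records.append(
            StabilityRecord(
                drug=str(row["drug"]),
                excipient=str(row["excipient"]),
                min_wt_pct=min_wt,
                success=success,
            )
        )
    return records
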