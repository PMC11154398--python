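"""Reference compound library and RDKit bridge.

SMILES definitions for the drugs and excipients studied in the
nanosuspension screening work, at the chain lengths used in the simulations:
PEG and PPG as 20-mers, poloxamer as an EO5–PO10–EO5 triblock, and
polysorbate 80 (Tween 80) with five ethylene-oxide units per arm. GDC-0810
is provided in both its neutral (carboxylic acid) and ionic (carboxylate
anion) forms.

:func:`from_smiles` converts any SMILES into a one-molecule
:class:`~nanostab.chem_model.MolecularSystem` with explicit hydrogens, ready
for 2-D descriptor counting.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .chem_model import Atom, MolecularSystem, Molecule


def _peg_chain(n: int) -> str:
    """-(OCH2CH2)n-OH written from an attachment oxygen: 'O' + 'CCO'*n."""
    return "CCO" * n


def _ppg_chain(n: int) -> str:
    return "CC(C)O" * n


#: SMILES at the simulated chain lengths. Tween 80 arms each carry five
#: ethylene-oxide units; one arm is esterified with oleic acid.
SMILES: dict[str, str] = {
    "gdc-0810-neutral": (
        "CC/C(=C(\\c1ccc(/C=C/C(=O)O)cc1)c1ccc2[nH]ncc2c1)c1ccc(F)cc1Cl"
    ),
    "gdc-0810-anion": (
        "CC/C(=C(\\c1ccc(/C=C/C(=O)[O-])cc1)c1ccc2[nH]ncc2c1)c1ccc(F)cc1Cl"
    ),
    "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "indomethacin": "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",
    "itraconazole": (
        "CCC(C)N1N=CN(c2ccc(N3CCN(c4ccc(OCC5COC(Cn6cncn6)(c7ccc(Cl)cc7Cl)O5)"
        "cc4)CC3)cc2)C1=O"
    ),
    "sds": "CCCCCCCCCCCCOS(=O)(=O)[O-]",
    "sos": "CCCCCCCCOS(=O)(=O)[O-]",
    "sdc": "CC(CCC(=O)[O-])C1CCC2C3CCC4CC(O)CCC4(C)C3CC(O)C12C",
    "peg": "O" + _peg_chain(20),
    "ppg": "O" + _ppg_chain(20),
    "poloxamer": "O" + _peg_chain(5) + _ppg_chain(10) + _peg_chain(5),
    "tween80": (
        "O" + _peg_chain(5) + "CC("
        + "O" + _peg_chain(5) + ")C1OCC("
        + "O" + _peg_chain(5) + ")C1"
        + "O" + _peg_chain(5)
        + "C(=O)CCCCCCC/C=C\\CCCCCCCC"
    ),
}


def rdkit_mol(key_or_smiles: str) -> Chem.Mol:
    """RDKit molecule (explicit hydrogens) from a library key or raw SMILES."""
    smi = SMILES.get(key_or_smiles, key_or_smiles)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {key_or_smiles!r}")
    return Chem.AddHs(mol)


def from_rdkit(mol: Chem.Mol, name: str, role: str = "excipient") -> MolecularSystem:
    """One-molecule system (graph only, zero coordinates) from an RDKit Mol."""
    atoms = [
        Atom(
            atom_id=i,
            element=a.GetSymbol(),
            coords=np.zeros(3),
            molecule_id=0,
        )
        for i, a in enumerate(mol.GetAtoms())
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    molecule = Molecule(
        molecule_id=0,
        name=name,
        role=role,
        atom_ids=list(range(len(atoms))),
        bonds=bonds,
        formal_charge=Chem.GetFormalCharge(mol),
    )
    return MolecularSystem(atoms, [molecule])


def from_smiles(key_or_smiles: str, name: str = "", role: str = "excipient") -> MolecularSystem:
    """Library key or SMILES → one-molecule system with explicit hydrogens."""
    return from_rdkit(rdkit_mol(key_or_smiles), name or key_or_smiles, role)
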