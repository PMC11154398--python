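"""Molecule contact analysis on trajectories.

Two molecules are in contact in a frame when any pair of their heavy atoms is
within a cutoff (4.5 Å by default, boundary inclusive). The per-frame contact
matrix drives three analyses: atomistic contact frequencies (which atoms of
the drug/excipient touch the other side), coordination-number distributions
(how many molecules of one role surround a molecule of another), and complex
extraction (drug crystal plus every adsorbed excipient or counterion, water
discarded).

Distances are plain Euclidean on centered clusters; no minimum-image
convention is applied. Neighbor search uses a k-d tree; its correctness is
established against the exhaustive all-pairs oracle (see tests), not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chem_model import MolecularSystem, Trajectory, crystal_selection


@dataclass
class ContactParams:
    """Contact definition and trajectory slicing.

    cutoff : Å, boundary-inclusive heavy-atom distance defining a contact.
    heavy_only : ignore hydrogens when testing distances.
    equilibration_fraction : fraction of initial frames discarded before any
        statistics (default 0.5, i.e. the first half of the run).
    """

    cutoff: float = 4.5
    heavy_only: bool = True
    equilibration_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ValueError("equilibration_fraction must be in [0, 1)")


@dataclass
class CoordinationDistribution:
    """Probability over coordination counts, pooled over frames and molecules."""

    probabilities: dict[int, float]
    reference_role: str
    neighbor_role: str

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(k < 0 for k in self.probabilities):
            raise ValueError("coordination counts must be non-negative")

    def total_variation(self, other: dict[int, float]) -> float:
        keys = set(self.probabilities) | set(other)
        return 0.5 * sum(
            abs(self.probabilities.get(k, 0.0) - other.get(k, 0.0)) for k in keys
        )


@dataclass
class ComplexSnapshot:
    """The drug crystal plus every excipient/counterion adsorbed in one frame."""

    system: MolecularSystem
    frame_index: int
    bound_molecule_ids: list[int] = field(default_factory=list)


def analysis_frames(traj: Trajectory, params: ContactParams) -> np.ndarray:
    """Indices of post-equilibration frames."""
    start = int(np.floor(traj.n_frames * params.equilibration_fraction))
    idx = np.arange(start, traj.n_frames)
    if idx.size == 0:
        raise ValueError("no frames remain after discarding equilibration")
    return idx


def _contact_atom_mask(system: MolecularSystem, params: ContactParams) -> np.ndarray:
    return system.heavy_mask if params.heavy_only else np.ones(system.n_atoms, bool)


def frame_contact_matrix(
    frame: np.ndarray, system: MolecularSystem, params: Optional[ContactParams] = None
) -> np.ndarray:
    """Symmetric boolean molecule×molecule contact matrix for one frame.

    Molecules i ≠ j are in contact iff their minimum qualifying-atom distance
    is ≤ cutoff. k-d-tree accelerated; agrees exactly with
    :func:`frame_contact_matrix_brute`.
    """
    params = params or ContactParams()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_atoms, 3):
        raise ValueError(
            f"frame has shape {frame.shape}; expected ({system.n_atoms}, 3)"
        )
    mask = _contact_atom_mask(system, params)
    mol_of = system.molecule_index_of_atom[mask]
    pts = frame[mask]
    n_mol = system.n_molecules
    mat = np.zeros((n_mol, n_mol), dtype=bool)
    if pts.shape[0] == 0:
        return mat
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
    if pairs.size:
        mi = mol_of[pairs[:, 0]]
        mj = mol_of[pairs[:, 1]]
        diff = mi != mj
        mat[mi[diff], mj[diff]] = True
        mat[mj[diff], mi[diff]] = True
    return mat


def frame_contact_matrix_brute(
    frame: np.ndarray, system: MolecularSystem, params: Optional[ContactParams] = None
) -> np.ndarray:
    """Exhaustive O(N²) all-pairs contact matrix (independent oracle)."""
    params = params or ContactParams()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_atoms, 3):
        raise ValueError(
            f"frame has shape {frame.shape}; expected ({system.n_atoms}, 3)"
        )
    mask = _contact_atom_mask(system, params)
    mol_of = system.molecule_index_of_atom[mask]
    pts = frame[mask]
    n_mol = system.n_molecules
    mat = np.zeros((n_mol, n_mol), dtype=bool)
    if pts.shape[0] == 0:
        return mat
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    close = d2 <= params.cutoff**2
    for i in range(pts.shape[0]):
        js = np.nonzero(close[i])[0]
        for j in js:
            if mol_of[i] != mol_of[j]:
                mat[mol_of[i], mol_of[j]] = True
    return mat


def atom_contact_frequencies(
    traj: Trajectory, params: Optional[ContactParams] = None
) -> pd.DataFrame:
    """Fraction of analyzed frames each drug/excipient atom contacts the other role.

    For every drug atom the partner set is all excipient heavy atoms, and vice
    versa (heavy per ``params.heavy_only``); an atom is "in contact" in a
    frame when any partner atom lies within the cutoff. Returns a DataFrame
    with columns atom_id, element, role, frequency.
    """
    params = params or ContactParams()
    system = traj.system
    frames = analysis_frames(traj, params)
    mol_of = system.molecule_index_of_atom
    roles = system.roles
    atom_role = roles[mol_of]

    partner_mask = {
        "drug": (atom_role == "excipient") & _contact_atom_mask(system, params),
        "excipient": (atom_role == "drug") & _contact_atom_mask(system, params),
    }
    subject = (atom_role == "drug") | (atom_role == "excipient")
    counts = np.zeros(system.n_atoms, dtype=float)

    for fi in frames:
        frame = traj.frames[fi]
        for role in ("drug", "excipient"):
            sub = np.nonzero(atom_role == role)[0]
            part = np.nonzero(partner_mask[role])[0]
            if sub.size == 0 or part.size == 0:
                continue
            tree = cKDTree(frame[part])
            hits = tree.query_ball_point(frame[sub], params.cutoff)
            touched = np.array([len(h) > 0 for h in hits])
            counts[sub[touched]] += 1.0

    freq = counts / len(frames)
    sel = np.nonzero(subject)[0]
    return pd.DataFrame(
        {
            "atom_id": sel,
            "element": system.elements[sel],
            "role": atom_role[sel],
            "frequency": freq[sel],
        }
    )


def coordination_distribution(
    traj: Trajectory,
    params: Optional[ContactParams] = None,
    reference_role: str = "excipient",
    neighbor_role: str = "drug",
) -> CoordinationDistribution:
    """Distribution of neighbor-role molecules per reference-role molecule.

    Pooled over all post-equilibration frames and all reference molecules;
    a reference molecule with no contacts contributes to the 0 bin.
    """
    params = params or ContactParams()
    system = traj.system
    roles = system.roles
    ref_idx = np.nonzero(roles == reference_role)[0]
    nb_mask = roles == neighbor_role
    if ref_idx.size == 0:
        raise ValueError(f"no molecules with role {reference_role!r}")
    if not nb_mask.any():
        raise ValueError(f"no molecules with role {neighbor_role!r}")

    counts: dict[int, int] = {}
    frames = analysis_frames(traj, params)
    for fi in frames:
        mat = frame_contact_matrix(traj.frames[fi], system, params)
        k_per_ref = mat[np.ix_(ref_idx, np.nonzero(nb_mask)[0])].sum(axis=1)
        for k in k_per_ref:
            counts[int(k)] = counts.get(int(k), 0) + 1
    total = sum(counts.values())
    probs = {k: v / total for k, v in sorted(counts.items())}
    return CoordinationDistribution(probs, reference_role, neighbor_role)


def extract_complex(
    traj: Trajectory, params: Optional[ContactParams] = None, frame_index: int = -1
) -> ComplexSnapshot:
    """Drug crystal + every excipient/counterion in contact with it in a frame.

    Water is always excluded, as is any excipient or counterion not touching
    any drug molecule. ``frame_index`` may be negative (python indexing).
    """
    params = params or ContactParams()
    system = traj.system
    if not (-traj.n_frames <= frame_index < traj.n_frames):
        raise IndexError(f"frame {frame_index} out of range [0, {traj.n_frames})")
    frame_index = frame_index % traj.n_frames
    frame = traj.frames[frame_index]

    drug_ids = crystal_selection(system)
    mat = frame_contact_matrix(frame, system, params)
    pos = {m.molecule_id: i for i, m in enumerate(system.molecules)}
    drug_pos = [pos[mid] for mid in drug_ids]

    bound: list[int] = []
    for mol in system.molecules:
        if mol.role in ("excipient", "counterion"):
            if mat[pos[mol.molecule_id], drug_pos].any():
                bound.append(mol.molecule_id)

    keep = sorted(drug_ids) + sorted(bound)
    sub = system.subset(keep, coords=frame)
    return ComplexSnapshot(system=sub, frame_index=frame_index, bound_molecule_ids=bound)
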