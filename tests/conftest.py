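"""Shared fixtures: tiny hand-built systems and seeded synthetic trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from nanostab import (
    AdsorptionParams,
    Atom,
    CrystalSpec,
    MolecularSystem,
    Molecule,
    assign_vdw_radii,
    build_crystal_cluster,
    simulate_adsorption,
)


def make_point_system(positions, elements=None, roles=None, radii=True):
    """One single-atom molecule per position (the workhorse toy system)."""
    positions = np.atleast_2d(np.asarray(positions, float))
    n = positions.shape[0]
    elements = elements or ["C"] * n
    roles = roles or ["drug"] * n
    atoms = [Atom(i, elements[i], positions[i], i) for i in range(n)]
    mols = [Molecule(i, f"{roles[i]}{i}", roles[i], [i]) for i in range(n)]
    system = MolecularSystem(atoms, mols)
    if radii:
        assign_vdw_radii(system)
    return system


def make_water(origin=(0.0, 0.0, 0.0), molecule_id=0, atom_offset=0):
    """O + 2 H atoms with bonds, as (atoms, molecule)."""
    o = np.asarray(origin, float)
    coords = [o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]]
    atoms = [
        Atom(atom_offset + i, el, coords[i], molecule_id)
        for i, el in enumerate(["O", "H", "H"])
    ]
    mol = Molecule(
        molecule_id,
        "water",
        "water",
        [atom_offset, atom_offset + 1, atom_offset + 2],
        bonds=[(atom_offset, atom_offset + 1), (atom_offset, atom_offset + 2)],
    )
    return atoms, mol


@pytest.fixture(scope="session")
def point_crystal():
    """3×3×3 single-carbon lattice, 6 Å spacing (27 drug molecules)."""
    spec = CrystalSpec(unit_elements=["C"], unit_coords=[[0.0, 0.0, 0.0]], spacing=6.0)
    return build_crystal_cluster(spec)


@pytest.fixture(scope="session")
def sticky_trajectory(point_crystal):
    """Permanently-bound excipients with known coordination {1: 0.5, 3: 0.5}."""
    params = AdsorptionParams(
        n_excipients=20,
        p_on=1.0,
        p_off=1e-9,
        k_dist={1: 0.5, 3: 0.5},
        n_frames=2000,
        seed=42,
        n_waters=5,
    )
    traj, truth = simulate_adsorption(point_crystal, params=params)
    return traj, truth, params


@pytest.fixture(scope="session")
def balanced_trajectory(point_crystal):
    """p_on = p_off = 0.5: per-frame states are i.i.d., bound fraction 0.5."""
    params = AdsorptionParams(
        n_excipients=10,
        p_on=0.5,
        p_off=0.5,
        k_dist={2: 1.0},
        n_frames=2000,
        seed=7,
    )
    traj, truth = simulate_adsorption(point_crystal, params=params)
    return traj, truth, params
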