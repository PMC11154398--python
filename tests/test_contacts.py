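"""Contact matrix, atomistic contact frequencies, coordination, complex extraction."""

import numpy as np
import pytest

from nanostab import (
    Atom,
    ContactParams,
    MolecularSystem,
    Molecule,
    atom_contact_frequencies,
    coordination_distribution,
    extract_complex,
    frame_contact_matrix,
    frame_contact_matrix_brute,
)
from nanostab.chem_model import Trajectory, assign_vdw_radii

from conftest import make_point_system, make_water


def random_system(rng, max_molecules=60, max_atoms=500):
    """Random multi-atom molecules scattered in a 40 Å box."""
    n_mol = int(rng.integers(2, max_molecules + 1))
    atoms, mols = [], []
    roles = ["drug", "excipient", "counterion", "water"]
    for mid in range(n_mol):
        n_at = int(rng.integers(1, 6))
        if len(atoms) + n_at > max_atoms:
            break
        center = rng.uniform(0, 40, 3)
        ids = []
        for _ in range(n_at):
            el = str(rng.choice(["C", "O", "N", "H"]))
            ids.append(len(atoms))
            atoms.append(Atom(len(atoms), el, center + rng.normal(0, 1.0, 3), mid))
        mols.append(Molecule(mid, f"m{mid}", roles[mid % 4], ids))
    return MolecularSystem(atoms, mols)


class TestFrameContactMatrix:
    @pytest.mark.parametrize("d,expected", [(4.4, True), (4.5, True), (4.6, False)])
    def test_cutoff_boundary_inclusive(self, d, expected):
        system = make_point_system([[0, 0, 0], [d, 0, 0]])
        mat = frame_contact_matrix(system.coords, system)
        assert bool(mat[0, 1]) is expected

    def test_hydrogens_ignored_when_heavy_only(self):
        # heavy atoms 6 Å apart, hydrogens 2 Å apart between the molecules
        atoms = [
            Atom(0, "C", [0, 0, 0], 0),
            Atom(1, "H", [2.0, 0, 0], 0),
            Atom(2, "C", [6.0, 0, 0], 1),
            Atom(3, "H", [4.0, 0, 0], 1),
        ]
        mols = [Molecule(0, "a", "drug", [0, 1]), Molecule(1, "b", "excipient", [2, 3])]
        system = MolecularSystem(atoms, mols)
        assert not frame_contact_matrix(system.coords, system)[0, 1]
        loose = frame_contact_matrix(
            system.coords, system, ContactParams(heavy_only=False)
        )
        assert loose[0, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        system = random_system(rng)
        frame = system.coords
        fast = frame_contact_matrix(frame, system)
        brute = frame_contact_matrix_brute(frame, system)
        np.testing.assert_array_equal(fast, brute)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(123)
        system = random_system(rng)
        mat = frame_contact_matrix(system.coords, system)
        np.testing.assert_array_equal(mat, mat.T)
        assert not mat.diagonal().any()

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        system = random_system(rng)
        frame = system.coords
        prev = frame_contact_matrix(frame, system, ContactParams(cutoff=3.0))
        for cutoff in (4.5, 6.0, 9.0):
            cur = frame_contact_matrix(frame, system, ContactParams(cutoff=cutoff))
            assert (cur | prev == cur).all(), "growing cutoff removed a contact"
            prev = cur

    def test_atom_count_mismatch(self):
        system = make_point_system([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="shape"):
            frame_contact_matrix(np.zeros((3, 3)), system)


class TestAtomContactFrequencies:
    def test_permanently_docked_excipient_faces(self):
        # excipient next to one crystal face for the whole trajectory
        system = make_point_system(
            [[0, 0, 0], [6, 0, 0], [9, 0, 0]], roles=["drug", "drug", "excipient"]
        )
        traj = Trajectory(system, np.repeat(system.coords[None], 4, axis=0))
        freqs = atom_contact_frequencies(traj, ContactParams(equilibration_fraction=0.5))
        by_id = dict(zip(freqs.atom_id, freqs.frequency))
        assert by_id[1] == 1.0  # near face always touching
        assert by_id[0] == 0.0  # far face never
        assert by_id[2] == 1.0  # the excipient atom itself

    def test_frequencies_bounded(self, sticky_trajectory):
        traj, _, _ = sticky_trajectory
        freqs = atom_contact_frequencies(traj)
        assert ((freqs.frequency >= 0) & (freqs.frequency <= 1)).all()

    def test_bound_fraction_reflected_in_frequency(self, point_crystal):
        from nanostab import AdsorptionParams, simulate_adsorption

        params = AdsorptionParams(
            n_excipients=14, p_on=0.3, p_off=0.2, k_dist={2: 1.0},
            n_frames=2000, seed=11,
        )
        traj, truth = simulate_adsorption(point_crystal, params=params)
        cp = ContactParams(equilibration_fraction=0.5)
        freqs = atom_contact_frequencies(traj, cp)
        exc = freqs[freqs.role == "excipient"]
        heavy = exc[exc.element == "C"]
        # excipient heavy atoms touch the crystal exactly when bound
        target = params.p_on / (params.p_on + params.p_off)
        n = 1000 * 14
        se = np.sqrt(target * (1 - target) / n)
        assert abs(heavy.frequency.mean() - target) < 3 * se * np.sqrt(3)


class TestCoordinationDistribution:
    def test_constant_coordination(self):
        system = make_point_system(
            [[0, 0, 0], [4, 0, 0], [8, 0, 0], [4, 4, 0]],
            roles=["drug", "excipient", "drug", "drug"],
        )
        traj = Trajectory(system, np.repeat(system.coords[None], 2, axis=0))
        dist = coordination_distribution(traj, ContactParams(equilibration_fraction=0.0))
        assert dist.probabilities == {3: 1.0}

    def test_detached_excipients_bin_zero(self):
        system = make_point_system(
            [[0, 0, 0], [50, 0, 0]], roles=["drug", "excipient"]
        )
        traj = Trajectory(system, np.repeat(system.coords[None], 2, axis=0))
        dist = coordination_distribution(traj, ContactParams(equilibration_fraction=0.0))
        assert dist.probabilities == {0: 1.0}

    def test_unknown_role_rejected(self, sticky_trajectory):
        traj, _, _ = sticky_trajectory
        with pytest.raises(ValueError):
            coordination_distribution(traj, reference_role="polymer")

    def test_recovers_generator_ground_truth(self, sticky_trajectory):
        traj, truth, params = sticky_trajectory
        dist = coordination_distribution(traj)
        tv = dist.total_variation(params.k_dist)
        assert tv < 0.05

    def test_probabilities_normalized(self, balanced_trajectory):
        traj, _, _ = balanced_trajectory
        dist = coordination_distribution(traj)
        assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-9)


class TestExtractComplex:
    @staticmethod
    def _mixed_system():
        positions = [[0, 0, 0], [6, 0, 0], [4, 4, 0], [40, 0, 0]]
        roles = ["drug", "drug", "excipient", "excipient"]
        atoms = [Atom(i, "C", positions[i], i) for i in range(4)]
        mols = [Molecule(i, f"{roles[i]}{i}", roles[i], [i]) for i in range(4)]
        # a counterion touching the crystal and two waters (one touching)
        atoms.append(Atom(4, "Na", [0, 4, 0], 4))
        mols.append(Molecule(4, "sodium", "counterion", [4]))
        w_atoms, w_mol = make_water((0, 0, 3.0), molecule_id=5, atom_offset=5)
        atoms += w_atoms
        mols.append(w_mol)
        w_atoms2, w_mol2 = make_water((60, 0, 0), molecule_id=6, atom_offset=8)
        atoms += w_atoms2
        mols.append(w_mol2)
        system = MolecularSystem(atoms, mols)
        assign_vdw_radii(system)
        return system

    def test_filters_unbound_and_water_keeps_counterion(self):
        system = self._mixed_system()
        traj = Trajectory(system, system.coords[None])
        snap = extract_complex(traj, ContactParams(equilibration_fraction=0.0), 0)
        roles = sorted(m.role for m in snap.system.molecules)
        assert roles == ["counterion", "drug", "drug", "excipient"]
        assert all(m.role != "water" for m in snap.system.molecules)
        # bound excipient at (4,4,0): sqrt(32)=5.66>4.5 from origin but 4.47<4.5 from (6,0,0)
        assert len(snap.bound_molecule_ids) == 2

    def test_bare_crystal_when_nothing_bound(self):
        system = make_point_system(
            [[0, 0, 0], [6, 0, 0], [50, 0, 0]], roles=["drug", "drug", "excipient"]
        )
        traj = Trajectory(system, system.coords[None])
        snap = extract_complex(traj, ContactParams(equilibration_fraction=0.0), 0)
        assert snap.system.n_molecules == 2
        assert all(m.role == "drug" for m in snap.system.molecules)

    def test_frame_out_of_range(self):
        system = make_point_system([[0, 0, 0]])
        traj = Trajectory(system, system.coords[None])
        with pytest.raises(IndexError):
            extract_complex(traj, ContactParams(equilibration_fraction=0.0), 5)
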