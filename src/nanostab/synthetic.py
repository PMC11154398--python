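"""Synthetic inputs with known ground truth.

These generators stand in for the MD engine: the analyses in this package
consume only contact geometry and surface composition, not dynamics, so an
excipient that hops between validated surface sites under a two-state Markov
chain is a sufficient — and fully controllable — source of trajectories.

* :func:`build_crystal_cluster` lays copies of a unit molecule on a rigid
  rectangular lattice (the restrained drug crystal, a ~35 Å cube analogue).
* :func:`simulate_adsorption` attaches excipients that bind and unbind with
  per-frame probabilities ``p_on``/``p_off``; while bound, an excipient sits
  at a precomputed surface site touching exactly ``k`` crystal molecules,
  ``k`` drawn per frame from a chosen coordination distribution (a surface
  diffusion analogue). Every placement is validated against the same 4.5 Å
  heavy-atom contact rule the analysis uses.
* :func:`generate_logistic_dataset` / :func:`generate_lasso_dataset` draw
  labelled stability data and descriptor-ratio regression data from known
  model coefficients, for fit-recovery tests.

All randomness flows from one explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .chem_model import Atom, MolecularSystem, Molecule, Trajectory, assign_vdw_radii
from .contacts import ContactParams, frame_contact_matrix
from .models import Fasa2DModel, LogisticModel

RATIO_FEATURES = (
    "ha_drug_mw",
    "hd_drug_mw",
    "ha_exc_mw",
    "hd_exc_mw",
    "q_drug_mw",
    "q_exc_mw",
)


@dataclass
class CrystalSpec:
    """Lattice replication of a unit molecule into a rigid crystal cluster."""

    unit_elements: list[str]
    unit_coords: np.ndarray
    nx: int = 3
    ny: int = 3
    nz: int = 3
    spacing: float = 6.0
    name: str = "drug"

    def __post_init__(self) -> None:
        self.unit_coords = np.atleast_2d(np.asarray(self.unit_coords, float))
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("lattice counts must be >= 1")
        if len(self.unit_elements) != self.unit_coords.shape[0]:
            raise ValueError("unit_elements and unit_coords length mismatch")
        extent = 0.0
        if self.unit_coords.shape[0] > 1:
            d = self.unit_coords[:, None, :] - self.unit_coords[None, :, :]
            extent = float(np.sqrt((d**2).sum(-1)).max())
        if self.spacing <= extent:
            raise ValueError(
                f"spacing {self.spacing} Å must exceed the unit molecule's "
                f"extent {extent:.2f} Å"
            )


@dataclass
class AdsorptionParams:
    """Two-state (bound/unbound) excipient kinetics and coordination statistics.

    Defaults describe a mostly-adsorbed population (stationary bound fraction
    p_on/(p_on+p_off) = 0.8) with a broad coordination distribution, echoing
    runs in which the majority of excipients sit on the crystal surface.
    """

    n_excipients: int = 14
    p_on: float = 0.2
    p_off: float = 0.05
    k_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.3, 3: 0.3, 4: 0.2}
    )
    n_frames: int = 2000
    seed: int = 0
    n_waters: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_on <= 1 and 0 < self.p_off <= 1):
            raise ValueError("p_on and p_off must be in (0, 1]")
        if self.n_excipients < 1 or self.n_frames < 1:
            raise ValueError("n_excipients and n_frames must be >= 1")
        total = sum(self.k_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"k_dist sums to {total}, not 1")
        if any((k < 1 or not float(p) >= 0) for k, p in self.k_dist.items()):
            raise ValueError("k_dist support must be positive integers")

    @property
    def stationary_bound_fraction(self) -> float:
        return self.p_on / (self.p_on + self.p_off)


def build_crystal_cluster(spec: CrystalSpec) -> MolecularSystem:
    """nx·ny·nz copies of the unit molecule on a rectangular lattice, role=drug.

    Deterministic; raises if any inter-molecular heavy-atom pair comes within
    1.0 Å (clash).
    """
    atoms: list[Atom] = []
    mols: list[Molecule] = []
    centred = spec.unit_coords - spec.unit_coords.mean(axis=0)
    offset = (
        np.array([spec.nx - 1, spec.ny - 1, spec.nz - 1], dtype=float)
        * spec.spacing
        / 2.0
    )
    mol_id = 0
    for ix in range(spec.nx):
        for iy in range(spec.ny):
            for iz in range(spec.nz):
                origin = np.array([ix, iy, iz], dtype=float) * spec.spacing - offset
                ids = []
                for el, xyz in zip(spec.unit_elements, centred):
                    ids.append(len(atoms))
                    atoms.append(
                        Atom(
                            atom_id=len(atoms),
                            element=el,
                            coords=origin + xyz,
                            molecule_id=mol_id,
                        )
                    )
                mols.append(
                    Molecule(
                        molecule_id=mol_id,
                        name=spec.name,
                        role="drug",
                        atom_ids=ids,
                    )
                )
                mol_id += 1
    system = MolecularSystem(atoms, mols)

    heavy = system.heavy_mask
    coords = system.coords[heavy]
    mol_of = system.molecule_index_of_atom[heavy]
    if coords.shape[0] > 1:
        from scipy.spatial import cKDTree

        pairs = cKDTree(coords).query_pairs(1.0, output_type="ndarray")
        for a, b in pairs:
            if mol_of[a] != mol_of[b]:
                raise ValueError(
                    "lattice clash: inter-molecular heavy atoms closer than 1.0 Å"
                )
    return assign_vdw_radii(system)


# ---------------------------------------------------------------------------
# Adsorption trajectories
# ---------------------------------------------------------------------------


@dataclass
class ExcipientTemplate:
    """Rigid excipient geometry replicated into the simulation."""

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    name: str = "excipient"
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, float))
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3) matching elements")


def default_excipient() -> ExcipientTemplate:
    """A minimal surfactant-like probe: one heavy atom with two hydrogens."""
    return ExcipientTemplate(
        elements=["C", "H", "H"],
        coords=np.array([[0.0, 0.0, 0.0], [1.09, 0.0, 0.0], [-1.09, 0.0, 0.0]]),
        bonds=[(0, 1), (0, 2)],
        name="probe",
    )


def _count_crystal_contacts(
    placed: np.ndarray,
    exc_heavy: np.ndarray,
    crystal_coords: np.ndarray,
    crystal_mol_of: np.ndarray,
    cutoff: float,
) -> tuple[int, float]:
    """(number of crystal molecules contacted, min heavy-atom distance)."""
    d = np.linalg.norm(
        placed[exc_heavy][:, None, :] - crystal_coords[None, :, :], axis=-1
    )
    dmin_per_atom = d.min(axis=0)
    in_contact = dmin_per_atom <= cutoff
    mols = np.unique(crystal_mol_of[in_contact])
    return int(mols.size), float(d.min())


def _precompute_sites(
    crystal: MolecularSystem,
    exc_coords: np.ndarray,
    exc_heavy: np.ndarray,
    ks: list[int],
    cutoff: float,
    rng: np.random.Generator,
    n_candidates: int = 4000,
    min_clearance: float = 1.5,
) -> dict[int, np.ndarray]:
    """Surface placements giving exactly k crystal-molecule contacts.

    Candidate centroid positions are sampled in a shell around the crystal
    and validated with the same heavy-atom contact rule used by the analysis.
    Raises if some requested k has no achievable site.
    """
    heavy = crystal.heavy_mask
    ccoords = crystal.coords[heavy]
    cmol = crystal.molecule_index_of_atom[heavy]
    center = ccoords.mean(axis=0)
    radius = float(np.linalg.norm(ccoords - center, axis=1).max())
    exc_centred = exc_coords - exc_coords.mean(axis=0)

    sites: dict[int, list[np.ndarray]] = {k: [] for k in ks}
    lo, hi = 1.0, radius + cutoff + 2.0
    for _ in range(n_candidates):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.uniform(lo, hi)
        point = center + r * u
        placed = exc_centred + point
        k, dmin = _count_crystal_contacts(placed, exc_heavy, ccoords, cmol, cutoff)
        if k in sites and dmin >= min_clearance and len(sites[k]) < 200:
            sites[k].append(point)
        if all(len(v) >= 200 for v in sites.values()):
            break
    missing = [k for k, v in sites.items() if not v]
    if missing:
        raise ValueError(
            f"k_dist requests coordination numbers {missing} that no surface "
            "placement can achieve for this crystal/excipient geometry"
        )
    return {k: np.array(v) for k, v in sites.items()}


def simulate_adsorption(
    crystal: MolecularSystem,
    excipient: Optional[ExcipientTemplate] = None,
    params: Optional[AdsorptionParams] = None,
    contact_params: Optional[ContactParams] = None,
    frame_interval: float = 100.0,
) -> tuple[Trajectory, dict]:
    """Reversible excipient adsorption onto a restrained crystal.

    Each excipient follows an independent bound/unbound Markov chain with
    per-frame probabilities ``p_on`` (bind) and ``p_off`` (unbind), started
    from its stationary distribution. While bound it occupies a precomputed
    surface site contacting exactly ``k`` crystal molecules (``k`` redrawn
    each frame from ``k_dist``); while unbound it sits at least twice the
    contact cutoff from every crystal atom. Fully reproducible from the seed.

    Returns the trajectory and a ground-truth dict (k_dist, stationary bound
    fraction, per-frame bound states, seed).
    """
    params = params or AdsorptionParams()
    contact_params = contact_params or ContactParams()
    rng = np.random.default_rng(params.seed)

    tmpl = excipient or default_excipient()
    exc_els = list(tmpl.elements)
    exc_bonds = list(tmpl.bonds)
    exc_charge = tmpl.formal_charge
    exc_name = tmpl.name
    exc_xyz = tmpl.coords - tmpl.coords.mean(axis=0)
    exc_heavy = np.array(
        [i for i, e in enumerate(exc_els) if e not in ("H", "D")], dtype=int
    )

    ks = sorted(params.k_dist)
    sites = _precompute_sites(
        crystal, exc_xyz, exc_heavy, ks, contact_params.cutoff, rng
    )

    heavy = crystal.heavy_mask
    ccoords = crystal.coords[heavy]
    center = ccoords.mean(axis=0)
    radius = float(np.linalg.norm(ccoords - center, axis=1).max())
    far = radius + 2.0 * contact_params.cutoff + 2.0

    # assemble system: crystal + excipients (+ decoy waters)
    atoms = [
        Atom(a.atom_id, a.element, a.coords.copy(), a.molecule_id)
        for a in crystal.atoms
    ]
    mols = [
        Molecule(m.molecule_id, m.name, m.role, list(m.atom_ids), list(m.bonds))
        for m in crystal.molecules
    ]
    next_mol = max(m.molecule_id for m in mols) + 1
    exc_atom_start: list[int] = []
    for _ in range(params.n_excipients):
        start = len(atoms)
        exc_atom_start.append(start)
        for j, el in enumerate(exc_els):
            atoms.append(Atom(len(atoms), el, exc_xyz[j] + center, next_mol))
        mols.append(
            Molecule(
                next_mol,
                exc_name,
                "excipient",
                list(range(start, len(atoms))),
                bonds=[(start + a, start + b) for a, b in exc_bonds],
                formal_charge=exc_charge,
            )
        )
        next_mol += 1
    water_xyz = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
    for _ in range(params.n_waters):
        start = len(atoms)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = center + rng.uniform(radius * 0.5, far + 5.0) * u
        for j, el in enumerate(["O", "H", "H"]):
            atoms.append(Atom(len(atoms), el, water_xyz[j] + pos, next_mol))
        mols.append(
            Molecule(
                next_mol,
                "water",
                "water",
                list(range(start, len(atoms))),
                bonds=[(start, start + 1), (start, start + 2)],
            )
        )
        next_mol += 1
    system = MolecularSystem(atoms, mols)
    assign_vdw_radii(system)

    n_atoms = system.n_atoms
    base = system.coords
    frames = np.empty((params.n_frames, n_atoms, 3))
    bound_states = np.empty((params.n_frames, params.n_excipients), dtype=bool)

    pi_b = params.stationary_bound_fraction
    bound = rng.random(params.n_excipients) < pi_b
    k_values = np.array(ks)
    k_probs = np.array([params.k_dist[k] for k in ks])

    def _unbound_position() -> np.ndarray:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return center + (far + rng.uniform(0.0, 3.0)) * u

    for f in range(params.n_frames):
        if f > 0:
            flip = rng.random(params.n_excipients)
            bound = np.where(
                bound, flip >= params.p_off, flip < params.p_on
            )
        bound_states[f] = bound
        frame = base.copy()
        for e in range(params.n_excipients):
            if bound[e]:
                k = int(rng.choice(k_values, p=k_probs))
                pool = sites[k]
                point = pool[rng.integers(len(pool))]
            else:
                point = _unbound_position()
            s = exc_atom_start[e]
            frame[s : s + len(exc_els)] = exc_xyz + point
        frames[f] = frame

    truth = {
        "seed": params.seed,
        "p_on": params.p_on,
        "p_off": params.p_off,
        "k_dist": dict(params.k_dist),
        "stationary_bound_fraction": pi_b,
        "bound_states": bound_states,
        "empirical_bound_fraction": float(bound_states.mean()),
    }
    return Trajectory(system, frames, frame_interval=frame_interval), truth


# ---------------------------------------------------------------------------
# Regression datasets
# ---------------------------------------------------------------------------


def generate_logistic_dataset(
    model: LogisticModel,
    n: int,
    x_range: tuple[float, float] = (0.05, 0.45),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, success-labels) from a log(P_f/P_s) = b0 + b1·x model.

    x ~ Uniform(x_range); label = 1 (success) with probability
    P_s(x) = 1 / (1 + exp(b0 + b1·x)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = x_range
    if not hi > lo:
        raise ValueError("degenerate x_range")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)
    ps = model.predict_ps(x)
    labels = (rng.random(n) < ps).astype(int)
    return x, labels


def generate_lasso_dataset(
    model: Fasa2DModel,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    feature_range: tuple[float, float] = (0.0, 0.3),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Descriptor-ratio features and linear response from known coefficients.

    Features are the six descriptor ratios of the 2-D FASA_p model, sampled
    uniformly in ``feature_range`` (the span the ratios take for real drug
    and excipient molecules); y = intercept + coeffs·x + N(0, noise_sd).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.uniform(*feature_range, size=(n, len(RATIO_FEATURES)))
    y = model.intercept + X @ model.coefficients
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(X, columns=list(RATIO_FEATURES)), y
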