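"""Surface and shape descriptors of drug–excipient complexes.

The central quantity is the fraction of polar solvent-accessible surface area
(FASA_p) of the complex — the drug crystal plus adsorbed excipients — which
predicts whether a drug–excipient pair forms a stable nanosuspension. SASA is
computed with the Shrake–Rupley algorithm on a deterministic Fibonacci sphere
(probe 1.4 Å, 960 points per atom by default); accompanying descriptors are
the total accessible surface area (ASA), the mass-weighted radius of gyration
(R_g) and the dipole moment. ASA and R_g are reported both raw and normalized
by the bare crystal (ASA/ASA0, Rg/Rg0) to remove crystal-size effects.

Uncertainty is estimated by splitting the post-equilibration trajectory into
five equal time windows and evaluating the complex extracted at the end of
each window; the spread across windows is the reported standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .chem_model import (
    MolecularSystem,
    Trajectory,
    assign_polarity,
    crystal_selection,
)
from .contacts import ComplexSnapshot, ContactParams, analysis_frames, extract_complex
from .elements import ATOMIC_WEIGHTS, DEBYE_PER_E_ANGSTROM


@dataclass
class SasaParams:
    """Shrake–Rupley parameters: probe radius (Å) and test points per atom."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.n_sphere_points < 32:
            raise ValueError("need at least 32 sphere points")


@dataclass
class SurfaceDescriptors:
    """Complex surface descriptors with five-window mean ± std.

    Point estimates are from the last analyzed frame; ``*_std`` fields hold
    the across-window standard deviation. Ratios are relative to the bare
    drug crystal (``asa0``, ``rg0``).
    """

    asa: float
    polar_asa: float
    fasa_p: float
    rg: float
    dipole: float
    asa_ratio: float
    rg_ratio: float
    asa_std: float = 0.0
    fasa_p_std: float = 0.0
    rg_std: float = 0.0
    dipole_std: float = 0.0
    asa0: float = float("nan")
    rg0: float = float("nan")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately-uniform unit vectors (deterministic golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _system_of(obj) -> MolecularSystem:
    return obj.system if isinstance(obj, ComplexSnapshot) else obj


def shrake_rupley_sasa(
    snapshot: ComplexSnapshot | MolecularSystem,
    params: Optional[SasaParams] = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    Each atom's sphere of radius ``r_vdw + probe`` is sampled at
    ``n_sphere_points`` Fibonacci points; a point is buried when it falls
    strictly inside a neighbor's probe-expanded sphere. A point exactly on a
    neighbor's boundary is assigned to the lower-indexed atom, so coincident
    identical spheres contribute a single sphere's area rather than two.
    """
    params = params or SasaParams()
    system = _system_of(snapshot)
    if system.n_atoms == 0:
        raise ValueError("empty system")
    radii = np.array(
        [a.vdw_radius if a.vdw_radius is not None else np.nan for a in system.atoms]
    )
    if np.isnan(radii).any():
        bad = system.atoms[int(np.nonzero(np.isnan(radii))[0][0])]
        raise ValueError(f"atom {bad.atom_id} ({bad.element}) has no vdW radius")

    coords = system.coords
    big = radii + params.probe_radius
    sphere = fibonacci_sphere(params.n_sphere_points)
    n = system.n_atoms

    tree = cKDTree(coords)
    max_reach = 2.0 * big.max()
    neighbor_lists = tree.query_ball_tree(tree, max_reach)

    areas = np.zeros(n)
    # tolerance for the boundary tie-break (degenerate coincident spheres)
    eps = 1e-9
    for i in range(n):
        cand = [j for j in neighbor_lists[i] if j != i]
        if cand:
            cand = np.array(cand)
            d = np.linalg.norm(coords[cand] - coords[i], axis=1)
            cand = cand[d < big[i] + big[cand]]
        pts = coords[i] + big[i] * sphere
        exposed = np.ones(params.n_sphere_points, dtype=bool)
        for j in cand:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            r2 = big[j] ** 2
            buried = d2 < r2 * (1.0 - eps)
            if j < i:
                buried |= np.abs(d2 - r2) <= r2 * eps
            exposed &= ~buried
            if not exposed.any():
                break
        frac = exposed.sum() / params.n_sphere_points
        areas[i] = frac * 4.0 * np.pi * big[i] ** 2
    return areas


def fasa_p(
    snapshot: ComplexSnapshot | MolecularSystem,
    params: Optional[SasaParams] = None,
    per_atom_sasa: Optional[np.ndarray] = None,
) -> float:
    """Fraction of the solvent-accessible surface area on polar atoms.

    Polar atoms are N/O/S/P plus their bonded hydrogens (see
    :func:`nanostab.chem_model.assign_polarity`). Raises on zero total area.
    """
    system = _system_of(snapshot)
    areas = (
        shrake_rupley_sasa(snapshot, params) if per_atom_sasa is None else per_atom_sasa
    )
    total = float(areas.sum())
    if total <= 0.0:
        raise ValueError("total accessible surface area is zero")
    polar = assign_polarity(system)
    return float(areas[polar].sum() / total)


def _masses(system: MolecularSystem) -> np.ndarray:
    try:
        return np.array([ATOMIC_WEIGHTS[a.element] for a in system.atoms])
    except KeyError as exc:
        raise KeyError(f"no atomic weight for element {exc.args[0]!r}") from None


def radius_of_gyration(snapshot: ComplexSnapshot | MolecularSystem) -> float:
    """Mass-weighted radius of gyration about the center of mass, Å."""
    system = _system_of(snapshot)
    if system.n_atoms == 0:
        raise ValueError("empty system")
    m = _masses(system)
    x = system.coords
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((x - com) ** 2, axis=1)).sum() / m.sum()))


def dipole_moment(snapshot: ComplexSnapshot | MolecularSystem) -> float:
    """|dipole| in debye, origin at the center of mass.

    Uses per-atom partial charges when any are assigned; otherwise falls back
    to molecular formal charges located at each molecule's centroid. For a
    net-charged system the value is origin-dependent; the center-of-mass
    origin is the package convention.
    """
    system = _system_of(snapshot)
    if system.n_atoms == 0:
        raise ValueError("empty system")
    m = _masses(system)
    x = system.coords
    com = (m[:, None] * x).sum(axis=0) / m.sum()

    charges = [a.partial_charge for a in system.atoms]
    if any(q is not None for q in charges):
        q = np.array([0.0 if c is None else c for c in charges])
        mu = (q[:, None] * (x - com)).sum(axis=0)
    else:
        if all(mol.formal_charge == 0 for mol in system.molecules):
            return 0.0
        mu = np.zeros(3)
        for mol in system.molecules:
            if mol.formal_charge:
                centroid = x[mol.atom_ids].mean(axis=0)
                mu += mol.formal_charge * (centroid - com)
    return float(np.linalg.norm(mu) * DEBYE_PER_E_ANGSTROM)


def bare_crystal_reference(
    traj: Trajectory, sasa_params: Optional[SasaParams] = None
) -> tuple[float, float]:
    """(ASA0, Rg0) of the drug crystal alone, evaluated at frame 0.

    The crystal is positionally restrained, so frame 0 is representative.
    """
    system = traj.system
    crystal = system.subset(sorted(crystal_selection(system)), coords=traj.frames[0])
    areas = shrake_rupley_sasa(crystal, sasa_params)
    return float(areas.sum()), radius_of_gyration(crystal)


def descriptor_timeseries(
    traj: Trajectory,
    contact_params: Optional[ContactParams] = None,
    sasa_params: Optional[SasaParams] = None,
    n_windows: int = 5,
) -> SurfaceDescriptors:
    """Five-window surface descriptors of the extracted complex.

    Post-equilibration frames are split into ``n_windows`` equal contiguous
    windows; the complex is extracted at each window's final frame and its
    descriptors evaluated. Reported values are across-window means with
    across-window standard deviations; ASA and R_g ratios are relative to the
    bare crystal at frame 0.
    """
    contact_params = contact_params or ContactParams()
    sasa_params = sasa_params or SasaParams()
    frames = analysis_frames(traj, contact_params)
    if frames.size < n_windows:
        raise ValueError(
            f"need at least {n_windows} analyzed frames, have {frames.size}"
        )
    windows = np.array_split(frames, n_windows)
    asa0, rg0 = bare_crystal_reference(traj, sasa_params)

    asa_w, pol_w, fas_w, rg_w, dip_w = [], [], [], [], []
    for w in windows:
        snap = extract_complex(traj, contact_params, frame_index=int(w[-1]))
        areas = shrake_rupley_sasa(snap, sasa_params)
        asa_w.append(float(areas.sum()))
        fas_w.append(fasa_p(snap, sasa_params, per_atom_sasa=areas))
        pol_w.append(fas_w[-1] * asa_w[-1])
        rg_w.append(radius_of_gyration(snap))
        dip_w.append(dipole_moment(snap))

    asa_w, fas_w, rg_w, dip_w = map(np.array, (asa_w, fas_w, rg_w, dip_w))
    return SurfaceDescriptors(
        asa=float(asa_w.mean()),
        polar_asa=float(np.mean(pol_w)),
        fasa_p=float(fas_w.mean()),
        rg=float(rg_w.mean()),
        dipole=float(dip_w.mean()),
        asa_ratio=float(asa_w.mean() / asa0),
        rg_ratio=float(rg_w.mean() / rg0),
        asa_std=float(asa_w.std()),
        fasa_p_std=float(fas_w.std()),
        rg_std=float(rg_w.std()),
        dipole_std=float(dip_w.std()),
        asa0=asa0,
        rg0=rg0,
    )
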