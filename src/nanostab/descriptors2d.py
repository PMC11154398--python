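"""Two-dimensional molecular descriptors and the closed-form FASA_p predictor.

A drug or excipient is reduced to four cheap 2-D properties — molecular
weight (MW), Lipinski hydrogen-bond acceptor count (HA = number of N and O
atoms), Lipinski donor count (HD = number of hydrogens on N or O) and the
absolute formal charge |q| — and the polar surface fraction of the
drug–excipient complex is predicted from the six ratios

    FASA_p^pred = 13.9·HA_d/MW_d + 27.0·HD_d/MW_d + 2.3·HA_e/MW_e
                +  4.3·HD_e/MW_e + 118·|q_d|/MW_d + 10.6·|q_e|/MW_e − 0.108

(the reference coefficient set :data:`REF_FASA2D`, fitted by LASSO to 32
simulated complexes). When no excipient is present, all excipient terms are
set to zero. Counting conventions are Lipinski's; the convention is pluggable
through a custom counting function where a different toolkit's definitions
are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chem_model import Molecule, MolecularSystem
from .elements import ATOMIC_WEIGHTS


@dataclass(frozen=True)
class Descriptor2D:
    """MW (g/mol), H-bond acceptor/donor counts and absolute formal charge."""

    mw: float
    ha: int
    hd: int
    abs_q: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("MW must be positive")
        if min(self.ha, self.hd, self.abs_q) < 0:
            raise ValueError("HA, HD and |q| must be non-negative")


@dataclass(frozen=True)
class Fasa2DModel:
    """Linear FASA_p predictor on the six descriptor ratios plus intercept."""

    ha_drug: float
    hd_drug: float
    ha_exc: float
    hd_exc: float
    q_drug: float
    q_exc: float
    intercept: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            [
                self.ha_drug,
                self.hd_drug,
                self.ha_exc,
                self.hd_exc,
                self.q_drug,
                self.q_exc,
            ]
        )


#: Reference 2-D FASA_p model (LASSO fit over 32 simulated complexes).
REF_FASA2D = Fasa2DModel(
    ha_drug=13.9,
    hd_drug=27.0,
    ha_exc=2.3,
    hd_exc=4.3,
    q_drug=118.0,
    q_exc=10.6,
    intercept=-0.108,
)


def lipinski_descriptors(
    molecule: Molecule, system: MolecularSystem, name: Optional[str] = None
) -> Descriptor2D:
    """Count MW / HA / HD / |q| on a molecule graph with explicit hydrogens.

    HA is the number of N and O atoms; HD the number of hydrogens bonded to
    N or O; MW the sum of standard atomic weights; |q| the absolute molecular
    formal charge.
    """
    atoms = [system.atoms[a] for a in molecule.atom_ids]
    try:
        mw = sum(ATOMIC_WEIGHTS[a.element] for a in atoms)
    except KeyError as exc:
        raise KeyError(f"no atomic weight for element {exc.args[0]!r}") from None
    ha = sum(1 for a in atoms if a.element in ("N", "O"))
    neigh: dict[int, list[int]] = {a: [] for a in molecule.atom_ids}
    for a, b in molecule.bonds:
        neigh[a].append(b)
        neigh[b].append(a)
    hd = 0
    for a in atoms:
        if a.element in ("H", "D"):
            if any(system.atoms[n].element in ("N", "O") for n in neigh[a.atom_id]):
                hd += 1
    return Descriptor2D(
        mw=mw, ha=ha, hd=hd, abs_q=abs(molecule.formal_charge), name=name or molecule.name
    )


def predict_fasap_2d(
    drug: Descriptor2D,
    excipient: Optional[Descriptor2D] = None,
    model: Fasa2DModel = REF_FASA2D,
) -> float:
    """Predicted FASA_p from 2-D descriptors; excipient terms zero when absent."""
    val = (
        model.ha_drug * drug.ha / drug.mw
        + model.hd_drug * drug.hd / drug.mw
        + model.q_drug * drug.abs_q / drug.mw
        + model.intercept
    )
    if excipient is not None:
        val += (
            model.ha_exc * excipient.ha / excipient.mw
            + model.hd_exc * excipient.hd / excipient.mw
            + model.q_exc * excipient.abs_q / excipient.mw
        )
    return float(val)
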