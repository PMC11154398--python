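"""End-to-end orchestration: generator → contact analysis → descriptors → predictions.

Every artifact written here carries a provenance header (package version,
seed, configuration hash) so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .chem_model import Trajectory, assign_vdw_radii
from .contacts import ContactParams, atom_contact_frequencies, coordination_distribution
from .descriptors2d import REF_FASA2D, lipinski_descriptors, predict_fasap_2d
from .io_formats import read_structure, write_structure
from .models import REF_2D, REF_SIM, LogisticModel
from .surface import SasaParams, descriptor_timeseries
from .synthetic import AdsorptionParams, CrystalSpec, build_crystal_cluster, simulate_adsorption


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run."""

    output_dir: str = "nanostab_out"
    trajectory: Optional[str] = None
    contact: ContactParams = field(default_factory=ContactParams)
    sasa: SasaParams = field(default_factory=SasaParams)
    n_windows: int = 5
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "contact": asdict(self.contact),
                "sasa": asdict(self.sasa),
                "n_windows": self.n_windows,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def provenance_header(config: PipelineConfig) -> str:
    return f"# nanostab v{__version__} seed={config.seed} config={config.digest()}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        df.to_csv(fh, index=False)


def run_simulate(config: PipelineConfig, params: Optional[AdsorptionParams] = None):
    """Generate a synthetic adsorption trajectory plus ground-truth JSON."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or AdsorptionParams(seed=config.seed)
    crystal = build_crystal_cluster(CrystalSpec(unit_elements=["C"], unit_coords=[[0, 0, 0]]))
    traj, truth = simulate_adsorption(
        crystal, params=params, contact_params=config.contact
    )
    write_structure(traj, out / "trajectory.pdb")
    truth_out = {k: v for k, v in truth.items() if k != "bound_states"}
    truth_out["provenance"] = provenance_header(config).strip("# \n")
    (out / "ground_truth.json").write_text(json.dumps(truth_out, indent=2))
    return traj, truth


def run_analyze(config: PipelineConfig, traj: Optional[Trajectory] = None) -> pd.DataFrame:
    """Contacts → complex extraction → surface descriptors on one trajectory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traj is None:
        if config.trajectory is None:
            raise ValueError("config.trajectory path is required (stage: analyze)")
        try:
            traj = read_structure(config.trajectory)
        except Exception as exc:
            raise RuntimeError(f"analyze: failed reading trajectory ({exc})") from exc
        assign_vdw_radii(traj.system)

    try:
        freqs = atom_contact_frequencies(traj, config.contact)
        _write_csv(freqs, out / "atom_contact_frequencies.csv", config)
        dist = coordination_distribution(traj, config.contact, "excipient", "drug")
        (out / "coordination_distribution.json").write_text(
            json.dumps(
                {
                    "reference_role": dist.reference_role,
                    "neighbor_role": dist.neighbor_role,
                    "probabilities": {str(k): v for k, v in dist.probabilities.items()},
                },
                indent=2,
            )
        )
        desc = descriptor_timeseries(traj, config.contact, config.sasa, config.n_windows)
    except Exception as exc:
        raise RuntimeError(f"analyze: {exc}") from exc

    df = pd.DataFrame([asdict(desc)])
    _write_csv(df, out / "surface_descriptors.csv", config)
    return df


def run_predict2d(
    drug_system,
    excipient_system=None,
    model_2d=REF_FASA2D,
    logistic: LogisticModel = REF_2D,
) -> dict:
    """2-D descriptors → predicted FASA_p → P_s (three-decimal rounding)."""
    drug = lipinski_descriptors(drug_system.molecules[0], drug_system)
    exc = (
        lipinski_descriptors(excipient_system.molecules[0], excipient_system)
        if excipient_system is not None
        else None
    )
    fasa_pred = predict_fasap_2d(drug, exc, model_2d)
    ps = logistic.predict_ps(fasa_pred)
    return {
        "drug": drug.name,
        "excipient": exc.name if exc else "no excipient",
        "drug_mw": drug.mw,
        "drug_ha": drug.ha,
        "drug_hd": drug.hd,
        "drug_abs_q": drug.abs_q,
        "fasa_p_pred": fasa_pred,
        "ps": round(float(ps), 3),
    }


def run_predict_sim(fasa_p: float, logistic: LogisticModel = REF_SIM) -> dict:
    """Simulated FASA_p → P_s under the simulation-descriptor logistic model."""
    return {"fasa_p": fasa_p, "ps": round(float(logistic.predict_ps(fasa_p)), 3)}
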