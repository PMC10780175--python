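"""Shared fixtures: compound, physiologies, calibrated parameters, scenarios.

The rat calibration and the human scenario runs are session-scoped: they are
the expensive pieces and every downstream check reuses the same objects.
"""

import pytest

from renalpk.calibration import CalibrationResult
from renalpk.drug import compute_kps, load_drug
from renalpk.engine import PBPKModel
from renalpk.physiology import Physiology, TissueSpec, get_physiology
from renalpk.scenarios import calibrate_rat, run_scenario

SEED = 1


@pytest.fixture(scope="session")
def drug():
    return load_drug()


@pytest.fixture(scope="session")
def rat_phys():
    return get_physiology("rat")


@pytest.fixture(scope="session")
def rat_kps(drug, rat_phys):
    return compute_kps(drug, rat_phys)


@pytest.fixture(scope="session")
def rat_model(drug, rat_phys, rat_kps):
    return PBPKModel(drug, rat_phys, rat_kps)


@pytest.fixture(scope="session")
def rat_calibration(drug) -> CalibrationResult:
    return calibrate_rat(drug, seed=SEED)


@pytest.fixture(scope="session")
def human_bundles(drug, rat_calibration):
    """All four human arms, keyed by scenario label."""
    return {
        label: run_scenario(label, drug=drug, cal=rat_calibration)
        for label in ("human-healthy", "human-ckd",
                      "human-healthy-q8h", "human-ckd-q8h")
    }


def one_compartment_physiology(volume_ml: float = 900.0,
                               blood_ml: float = 90.0,
                               flow_ml_min: float = 1.0e5,
                               eliminating: str = "hepatic") -> Physiology:
    """Degenerate physiology: one lumped tissue plus minimal blood/lung pools.

    Flows are enormous so mixing is effectively instantaneous and the whole
    system behaves as a single well-stirred volume — the closed-form
    one-compartment oracle.
    """
    blood = dict(fraction_water=0.82, fraction_lipid=0.004, fraction_protein=0.16)
    tissues = {
        "venous": TissueSpec("venous", blood_ml * 2 / 3, flow_ml_min, **blood),
        "arterial": TissueSpec("arterial", blood_ml / 3, flow_ml_min, **blood),
        "lung": TissueSpec("lung", 1.0, flow_ml_min, 0.79, 0.021, 0.15),
        "tissue": TissueSpec("tissue", volume_ml, flow_ml_min, 0.75, 0.05, 0.18,
                             eliminating=eliminating),
    }
    return Physiology(species="rat", body_weight=1.0, tissues=tissues,
                      cardiac_output=flow_ml_min, gfr=0.0, hematocrit=0.45)
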