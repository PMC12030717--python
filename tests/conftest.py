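import numpy as np
import pytest

import tcbpbpk as tp
from tcbpbpk.physiology import OrganPhysiology, build_default_mouse


@pytest.fixture(scope="session")
def scenario():
    return tp.default_scenario()


MOLECULE_ORDER = ["gD", "gD-CD3L", "HER2-CD3L", "gD-CD3H", "gD-CD3VH", "HER2-CD3H"]

#: 0.5 mg/kg in a 20 g mouse at 150 kDa
STUDY_DOSE_NMOL = 0.01 / 150000.0 * 1.0e6


@pytest.fixture(scope="session")
def variant_results(scenario):
    """One 5000 h study-dose simulation per molecule variant (shared by the
    mass-balance and affinity-ordering checks)."""
    return {
        name: tp.simulate(scenario, name, dose_nmol=STUDY_DOSE_NMOL)
        for name in MOLECULE_ORDER
    }


@pytest.fixture(scope="session")
def dose_sweep_table(scenario):
    """Default 12-dose sweep of the low-CD3-affinity HER2 bispecific."""
    return tp.dose_sweep(scenario)


def reduced_body_scenario():
    """Three-organ body (blood, lung, muscle) with a closed flow balance,
    used by the linear-disposition oracle."""
    organs = [o for o in build_default_mouse(0.02) if o.name in
              ("venous_blood", "arterial_blood", "lung", "muscle")]
    by_name = {o.name: o for o in organs}
    lung = by_name["lung"]
    muscle = by_name["muscle"]
    muscle.plasma_flow = lung.plasma_flow - lung.lymph_flow
    muscle.lymph_flow = muscle.plasma_flow * 0.004
    config = tp.ScenarioConfig(
        organs=organs,
        molecules=tp.default_molecules(),
        doses=[tp.DoseEvent(molecule="gD", amount=0.01, unit="mg")],
        t_end=1000.0,
    )
    config.validate()
    return config
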