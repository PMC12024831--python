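import numpy as np
import pytest

import clopbbm as cb
from clopbbm import datasets


@pytest.fixture(scope="session")
def drug():
    return datasets.clopidogrel_drug_parameters()


@pytest.fixture(scope="session")
def disp():
    return datasets.clopidogrel_disposition_parameters()


@pytest.fixture(scope="session")
def physiology():
    return cb.default_fasted_physiology()


@pytest.fixture(scope="session")
def presets():
    return cb.formulation_presets()


@pytest.fixture(scope="session")
def ir_result(drug, disp):
    """75 mg oral IR (solid particles, Johnson dissolution), 24 h."""
    source = cb.ReleaseSource.from_psd(drug.d50_um, drug.d90_um, n_bins=10)
    return cb.simulate_oral(
        drug, disp, None, source, cb.DoseEvent(route="po", dose=75.0),
        t_end=24.0,
    )


@pytest.fixture(scope="session")
def preset_results(drug, disp, presets):
    """75 mg oral runs of the four solid-dispersion presets.

    Precipitation is disabled: the polymer carriers act as precipitation
    inhibitors (the study's concentration profiles showed none).
    """
    out = {}
    for name in ("C5", "C9", "P5", "P9"):
        source = cb.ReleaseSource.from_profile(cb.generate_profile(presets[name]))
        out[name] = cb.simulate_oral(
            drug, disp, None, source, cb.DoseEvent(route="po", dose=75.0),
            t_end=24.0, precipitation=False,
        )
    return out


@pytest.fixture(scope="session")
def iv_curve_10mg(drug, disp):
    """Analytic 10 mg i.v. bolus curve used by the fitting tests."""
    res = cb.simulate_iv(
        drug, disp,
        cb.DoseEvent(route="iv_bolus", dose=10.0, coadministered_water_mL=0.0),
        t_end=24.0,
    )
    return res.times, res.plasma_conc
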