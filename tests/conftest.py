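import numpy as np
import pytest

import lai_ivivc as L


@pytest.fixture(scope="session")
def fx():
    return L.study_fixtures()


@pytest.fixture(scope="session")
def uir(fx):
    return fx["uir"]


@pytest.fixture(scope="session")
def sc_schedule(fx):
    return np.asarray(fx["schedules"]["sc_pk"], float)


@pytest.fixture(scope="session")
def iv_schedule(fx):
    return np.asarray(fx["schedules"]["iv_pk"], float)


@pytest.fixture(scope="session")
def ivr_schedule_long(fx):
    return np.asarray(fx["schedules"]["ivr_long"], float)


@pytest.fixture(scope="session")
def dose_ug(fx):
    return fx["sc_dose_mg_per_kg"] * fx["reference_body_weight_g"]


@pytest.fixture(scope="session")
def table8_modeled(fx, uir, dose_ug):
    """Modeled PK parameters for all four formulations, recomputed from the
    transcribed phase parameters and scaling factors alone."""
    scaling = fx.scaling_fit()
    grid = L.absorption_tabulation_grid()
    out = {}
    for form in ("F1", "F2", "F3", "F4"):
        prof = L.convolve_model(fx.in_vitro_model(form), scaling, uir,
                                dose_ug, formulation=form, input_grid=grid)
        res = L.nca(prof)
        out[form] = {"Cmax": res.cmax,
                     "AUC_48h": res.auc_partial[48.0],
                     "AUC_168h": res.auc_partial[168.0],
                     "AUC_672h": res.auc_partial[672.0],
                     "AUC_2016h": res.auc_partial[2016.0]}
    return out
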