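import numpy as np
import pytest

from inta.config import ContrastCalibration, InstrumentSpec, OpticalConfig
from inta.estimate import build_records
from inta.simulate import POPULATION_PRESETS, PopulationSpec, simulate_sample


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def instr():
    return InstrumentSpec()


@pytest.fixture(scope="session")
def calib():
    return ContrastCalibration()


@pytest.fixture(scope="session")
def monodisperse_pop():
    """Single-size, single-RI reference population (100 nm, n = 1.40)."""
    return PopulationSpec("mono", 100.0, (100.0, 100.0), 1.40, (1.40, 1.40), 1.0)


@pytest.fixture(scope="session")
def ev_vldl_training(optics, instr, calib):
    """Full-pipeline record tables for pure EV and pure VLDL samples.

    Shared by the classifier unit tests and the acceptance suite; sized so
    each class comfortably exceeds the 100-record training minimum.
    """
    ev_set = simulate_sample(
        [POPULATION_PRESETS["EV"]], instr, optics, calib, seed=201, n_expected=1500
    )
    vldl_set = simulate_sample(
        [POPULATION_PRESETS["VLDL"]], instr, optics, calib, seed=202, n_expected=1800
    )
    ev_records = build_records(ev_set, seed=5201, n_sims=100)
    vldl_records = build_records(vldl_set, seed=5202, n_sims=100)
    kept_rate_ev = len(ev_records) / len(ev_set)
    kept_rate_vldl = len(vldl_records) / len(vldl_set)
    return {
        "ev": ev_records,
        "vldl": vldl_records,
        "kept_rate_ev": kept_rate_ev,
        "kept_rate_vldl": kept_rate_vldl,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
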