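import numpy as np
import pytest

import thrombosim as ts


@pytest.fixture(scope="session")
def patient():
    return ts.Patient(body_weight=80.0)


@pytest.fixture(scope="session")
def proteins():
    return ts.builtin_proteins()


@pytest.fixture(scope="session")
def kinetics():
    return ts.builtin_plasma_kinetics()


@pytest.fixture(scope="session")
def drugs():
    return {name: ts.builtin_drug(name) for name in ts.DRUG_NAMES}


def small_clot_config(**overrides):
    """A short, coarse clot used by fast behavioural tests (not the preset)."""
    base = ts.builtin_clot_config().to_dict()
    base.update(dict(L_clot=0.002, n_cells=10, x_monitor=0.001, spin_up=120.0))
    base.update(overrides)
    return ts.ClotConfig.from_dict(base)


@pytest.fixture()
def small_clot():
    return small_clot_config()


@pytest.fixture(scope="session")
def preset_runs(patient):
    """Full coupled runs of all four shipped presets (shared across tests)."""
    runs = {}
    for name in ts.DRUG_NAMES:
        scenario = ts.preset_scenario(name)
        traj, result, report = ts.run_scenario(scenario)
        runs[name] = dict(scenario=scenario, traj=traj, result=result,
                          report=report)
    return runs
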