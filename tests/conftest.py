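import pytest

import strchip as sc


@pytest.fixture(scope="session")
def panel():
    return sc.default_panel()


@pytest.fixture(scope="session")
def model():
    return sc.MigrationModel()


@pytest.fixture(scope="session")
def refs():
    return sc.reference_profiles()


@pytest.fixture(scope="session")
def noiseless_model():
    return sc.MigrationModel(noise_sd_fu=0.0)


@pytest.fixture(scope="session")
def calibration(panel, model):
    ladder = sc.simulate_ladder_trace(panel, model, seed=5)
    return sc.fit_calibration(ladder, panel.ladder_sizes_bp)
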