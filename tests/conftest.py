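import pytest

import phakinetics as pk


@pytest.fixture(scope="session")
def hl_crude() -> pk.ParameterSet:
    return pk.CRUDE_SCG_ESTIMATES["han_levenspiel"]


@pytest.fixture(scope="session")
def hl_saponified() -> pk.ParameterSet:
    return pk.SAPONIFIED_SCG_ESTIMATES["han_levenspiel"]


@pytest.fixture(scope="session")
def crude_comp() -> pk.OilComposition:
    return pk.COMPOSITION_PRESETS["scg_crude"]


@pytest.fixture(scope="session")
def sap_comp() -> pk.OilComposition:
    return pk.COMPOSITION_PRESETS["scg_saponified"]


@pytest.fixture(scope="session")
def noiseless_crude_dataset() -> pk.FlaskDataset:
    """Reference-design crude dataset with zero noise (truth exactly recoverable)."""
    cfg = pk.shake_flask_design("crude", noise_sigma=0.0)
    return pk.build_dataset(pk.generate_flasks(cfg))
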