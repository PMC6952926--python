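import numpy as np
import pytest

from cellmech import IndentConfig, IndentSimParams, TipModel, simulate_indentation_cycle


@pytest.fixture(scope="session")
def cone_tip() -> TipModel:
    return TipModel(geometry="cone", half_angle_rad=np.deg2rad(35.0), radius_m=None)


@pytest.fixture(scope="session")
def paraboloid_tip() -> TipModel:
    return TipModel(geometry="paraboloid", radius_m=1e-6)


@pytest.fixture(scope="session")
def clean_cycle(cone_tip):
    """A noise-free conical indentation cycle with known E and eta."""
    params = IndentSimParams(
        young_modulus_Pa=1500.0, target_eta=0.5, tip=cone_tip, noise_sigma_N=0.0
    )
    return simulate_indentation_cycle(params)


@pytest.fixture(scope="session")
def cone_config(cone_tip) -> IndentConfig:
    return IndentConfig(tip=cone_tip)
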