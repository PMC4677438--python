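import numpy as np
import pytest

from fluorobind import SimulationConfig, simulate_titration

#: the experimental quencher series in mol/L (0-320 uM)
PAPER_CONCS = np.array([0.0, 20, 40, 80, 120, 160, 240, 320]) * 1e-6

UNIT_FACTORS = {280.0: 1.0, 293.0: 1.0}  # disable the excitation contrast


@pytest.fixture
def noiseless_dynamic_series():
    """Triplicate noise-free titration generated from the Stern-Volmer line."""
    cfg = SimulationConfig(
        model="dynamic-sv",
        true_ksv=1.27e5,
        noise_sigma=0.0,
        replicates=3,
        excitation_quench_factors=UNIT_FACTORS,
    )
    return simulate_titration(cfg)


@pytest.fixture
def noisy_series():
    """Triplicate titration with 2% multiplicative noise, fixed seed."""
    cfg = SimulationConfig(
        model="dynamic-sv",
        noise_sigma=0.02,
        replicates=3,
        seed=42,
        excitation_quench_factors=UNIT_FACTORS,
    )
    return simulate_titration(cfg)
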