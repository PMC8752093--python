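import warnings

import numpy as np
import pytest

import fcslab as f

# desk-scale acquisition settings shared across tests: same optics and
# concentrations as the full-scale study conditions, shorter traces and
# coarser bins sized for a single CPU
BIN = 2e-5           # s
BOX_FACTOR = 5.0
KAPPA = 5.0
OMEGA_XY = 0.25      # um


@pytest.fixture(scope="session")
def volume():
    return f.DetectionVolume(omega_xy=OMEGA_XY, kappa=KAPPA)


@pytest.fixture(scope="session")
def single_species_config(volume):
    """One red-channel-style species at the 75 nM study concentration."""
    return f.SimulationConfig(
        volume=volume,
        species=(f.SpeciesSpec("mutant_like", D=10.6, concentration=75.0,
                               brightness_G=30000.0),),
        duration=1.0, base_bin=BIN, time_step=BIN,
        box_factor=BOX_FACTOR, seed=11)


@pytest.fixture(scope="session")
def single_species_trace(single_species_config):
    return f.simulate_trace(single_species_config)


@pytest.fixture(scope="session")
def single_species_curve(single_species_trace):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return f.correlate_multitau(single_species_trace, "GG")


def constant_trace(value, n_bins=2000, bin_width=1e-5):
    counts = np.full(n_bins, float(value))
    return f.IntensityTrace(counts_G=counts, counts_R=counts.copy(),
                            bin_width=bin_width)
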