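"""Shared fixtures: the reference pulse designs and reusable simulations.

Session scope keeps the Bloch-simulated profiles shared across tests, since
each full-profile simulation costs a few hundred milliseconds.
"""

import numpy as np
import pytest

import spenkit as sk

# Reference designs: 50 kHz / 4 ms WURST-40 chirp and 3 ms / TBW-4 sinc,
# both 90 degrees; companion gradient 250 kHz/m (FOV 0.2 m).
CHIRP_BW = 50e3
CHIRP_T = 4e-3
WURST_N = 40
GRAD = 250e3
SINC_T = 3e-3
SINC_TBW = 4.0


@pytest.fixture(scope="session")
def chirp_design():
    return sk.ChirpDesign(bandwidth=CHIRP_BW, duration=CHIRP_T,
                          wurst_order=WURST_N)


@pytest.fixture(scope="session")
def sinc_design():
    return sk.SincDesign(duration=SINC_T, time_bandwidth=SINC_TBW)


@pytest.fixture(scope="session")
def wurst_pulse(chirp_design):
    return sk.design_wurst_chirp(chirp_design)


@pytest.fixture(scope="session")
def block_pulse(chirp_design):
    return sk.design_block_chirp(chirp_design)


@pytest.fixture(scope="session")
def sinc_pulse(sinc_design):
    return sk.design_sinc(sinc_design)


@pytest.fixture(scope="session")
def block_profile(block_pulse):
    offsets = np.arange(-40e3, 40e3 + 1, 250.0)
    return sk.flip_angle_profile(block_pulse, offsets)


@pytest.fixture(scope="session")
def encoded_profile(wurst_pulse):
    """Bloch-simulated post-excitation phase profile for the reference
    chirp under its companion gradient (FOV = BW/G = 0.2 m)."""
    fov = CHIRP_BW / GRAD
    grid = sk.SimGrid(positions=sk.uniform_grid(fov, 1024), gradient=GRAD)
    return sk.encoded_phase_profile(wurst_pulse, grid)
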