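"""Shared fixtures: a scaled-down canvas (6 deg, 24 px/deg) keeps the full
filtering pipeline exact but fast; heavy objects are session-scoped."""

import numpy as np
import pytest

from visnorm import energy as en
from visnorm import stimuli as st

DIALECT = st.DIALECTS["small"]
PPD = DIALECT.ppd
SIZE_DEG = DIALECT.size_deg


@pytest.fixture(scope="session")
def bp_kernel():
    return st.make_bandpass_kernel(PPD)


@pytest.fixture(scope="session")
def bank():
    return en.build_filterbank(PPD)


@pytest.fixture(scope="session")
def snakes(bp_kernel):
    return st.synth_snakes(0.9, 1.0, n_exemplars=3, size_deg=SIZE_DEG,
                           ppd=PPD, seed=11, bp_kernel=bp_kernel)


@pytest.fixture(scope="session")
def gratings(bp_kernel):
    return st.synth_gratings(1.0 / 3.0, 1.0, 0.0, "lines", n_exemplars=3,
                             size_deg=SIZE_DEG, ppd=PPD, seed=12,
                             bp_kernel=bp_kernel)


@pytest.fixture(scope="session")
def snake_energy(snakes, bank):
    return en.compute_energy(snakes.exemplars[0], bank)


@pytest.fixture(scope="session")
def grating_energy(gratings, bank):
    return en.compute_energy(gratings.exemplars[0], bank)


@pytest.fixture(scope="session")
def target_energies(bank):
    """Energy-matched snakes/gratings contrast-ladder battery with energies."""
    from visnorm import experiments as ex

    sets, labels, match = ex.target_battery(DIALECT, n_exemplars=2, seed=0,
                                            bank=bank)
    energies = ex.battery_energies(sets, bank)
    return sets, labels, match, energies


def sinusoid(orientation_deg=0.0, freq_cpd=3.0, phase=0.0, contrast=1.0,
             size_deg=SIZE_DEG, ppd=PPD, aperture=False):
    """Full-field sinusoidal grating test image."""
    n = int(round(size_deg * ppd))
    u = st._coord_u(n, ppd, orientation_deg)
    pix = (contrast / 2) * np.sin(2 * np.pi * freq_cpd * u + phase)
    img = st.StimulusImage(pix, ppd, size_deg)
    return st.apply_aperture(img) if aperture else img
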