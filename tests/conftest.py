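import dataclasses

import numpy as np
import pytest

from milknir import BUILTIN_DEVICES, SampleDesign, generate_spectra


@pytest.fixture(scope="session")
def small_design():
    """A desk-scale rendition of the study design (same structure, fewer samples)."""
    return SampleDesign(n_cow_smp=12, n_buffalo_mix=1, n_spiked_smps=4,
                        n_replicates=3, seed=7)


@pytest.fixture(scope="session")
def device_a():
    return BUILTIN_DEVICES["A"]


@pytest.fixture(scope="session")
def quiet_device_a():
    """Device A without artifacts, for clean statistical checks."""
    return dataclasses.replace(BUILTIN_DEVICES["A"], artifact_rate=0.0)


@pytest.fixture(scope="session")
def small_spectra(small_design, quiet_device_a):
    return generate_spectra(small_design, quiet_device_a)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
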