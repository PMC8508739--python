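import numpy as np
import pytest

from unfoldscope import simulate, tcspc


@pytest.fixture(scope="session")
def decay_bundle():
    """Poisson-noised 19-wavelength bundle at the instrument defaults."""
    return simulate.simulate_decays(simulate.DecaySimSpec(seed=1))


@pytest.fixture(scope="session")
def bundle_fit(decay_bundle):
    """Global 3-component fit of the session bundle."""
    return tcspc.global_fit(
        decay_bundle.traces, decay_bundle.irf, n_components=3, seed=0
    )


@pytest.fixture()
def toy_pair():
    """Two parallel indole rings 7.8 A apart along the shared normal."""
    return simulate.build_toy_structure(simulate.ToyStructureSpec())


@pytest.fixture()
def delta_irf():
    """Identity IRF: all counts in channel 0."""
    counts = np.zeros(400)
    counts[0] = 1.0e4
    return tcspc.InstrumentResponse(counts=counts, channel_width=0.027)
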