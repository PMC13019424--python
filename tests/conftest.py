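import numpy as np
import pytest

from acylquant import (SPECIES, NoiseParams, SpectrumSet, WavenumberGrid,
                       pure_component_spectra)


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def fame_pures(grid):
    return pure_component_spectra("FAME", grid)


@pytest.fixture(scope="session")
def tag_pures(grid):
    return pure_component_spectra("TAG", grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def noisy_replicates(pures, species, n_reps, base_seed, sigma=0.01):
    """Replicate single-component measurements with channel noise and drift."""
    from acylquant.synth import Composition, mix

    out = []
    for r in range(n_reps):
        params = NoiseParams(sigma_rel=sigma, seed=base_seed + r)
        s = mix(Composition({species: 100.0}), pures, params, id=f"{species}_{r}")
        out.append(s)
    return SpectrumSet.from_spectra(out)
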