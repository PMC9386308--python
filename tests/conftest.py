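import numpy as np
import pytest

import grainspec as gs


@pytest.fixture(scope="session")
def study_fixture():
    """The standard 500-accession synthetic study set (seed 42)."""
    return gs.make_study_fixture(seed=42, n_samples=500)


@pytest.fixture(scope="session")
def small_fixture():
    """A smaller paired set for fast unit tests."""
    cfg = gs.SimulationConfig(n_samples=80, seed=7)
    ref = gs.simulate_compositions(cfg)
    spectra = gs.simulate_spectra(ref, gs.default_band_model(), cfg)
    return spectra, ref


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_spectra(matrix, wavelengths=None, ids=None, history=()):
    """Build a SpectraSet from a plain matrix for operator tests."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if wavelengths is None:
        wavelengths = 400.0 + 2.0 * np.arange(p)
    if ids is None:
        ids = [f"S{i}" for i in range(n)]
    return gs.SpectraSet(ids, np.asarray(wavelengths, float), matrix,
                         meta={"history": list(history)})
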