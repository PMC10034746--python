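import numpy as np
import pytest

import lipidcolony as lc


@pytest.fixture(scope="session")
def small_phantom():
    """One imaging-mode colony (500 cells) shared across tests."""
    cfg = lc.ColonyPhantomConfig(n_cells=500, seed=21)
    confocal, dataset, truth = lc.generate_colony(cfg, day=3)
    return cfg, confocal, dataset, truth


@pytest.fixture(scope="session")
def day_series():
    """Table-mode 8-day control series with an independent replicate."""
    cfg = lc.ColonyPhantomConfig(n_cells=600, seed=7)
    return cfg, lc.generate_day_series(cfg)


@pytest.fixture(scope="session")
def bifurcation_series():
    """Table-mode high-dose PI3K-inhibition series (SSEA1+/NCAM1+ arms)."""
    cfg = lc.ColonyPhantomConfig(n_cells=700, seed=12,
                                 condition="LY294002_100uM")
    return cfg, lc.generate_day_series(cfg, with_replicate=False)


@pytest.fixture
def tiny_dataset():
    """2x2-pixel centroid dataset with one empty spectrum."""
    rng = np.random.default_rng(0)
    spectra = [
        (np.sort(rng.uniform(200, 1600, 5)), rng.uniform(0.5, 10, 5))
        for _ in range(4)
    ]
    spectra[1] = (np.array([]), np.array([]))
    return lc.MSIDataset(
        spectra=spectra, coords=[(0, 0), (0, 1), (1, 0), (1, 1)],
        shape=(2, 2), pixel_size=10.0)
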