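import numpy as np
import pytest

import rfecs


@pytest.fixture(scope="session")
def toy_layout():
    return rfecs.GenomeLayout(("chrA", "chrB"), (10_000, 6_000), bin_width=100)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced synthetic genome for fast unit tests (not the study default)."""
    return rfecs.SimulationConfig(
        n_chroms=1, chrom_length=500_000, n_enhancers=20, n_promoters=20, seed=11
    )


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    """(training set, dataset, tracks) on the reduced genome."""
    return rfecs.make_training_fixture(small_cfg)


@pytest.fixture(scope="session")
def small_results(small_fixture):
    fbm, ds, tracks = small_fixture
    return rfecs.EnhancerForest(fbm).fit(n_trees=25, seed=11)


def constant_track(layout, mark, value):
    values = {c: np.full(layout.n_bins(c), float(value)) for c in layout.chrom_names}
    return rfecs.BinnedTrack(layout, values, mark)


@pytest.fixture
def make_constant_track():
    return constant_track
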