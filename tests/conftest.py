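import numpy as np
import pytest

import gridherd as gh


@pytest.fixture(scope="session")
def small_landscape():
    """A compact region: 6 districts on a 60x60 km grid, 6 settlements each,
    5 annual covariate stacks and truth for both species."""
    ls = gh.default_landscape(
        seed=7,
        n_districts=6,
        shape=(60, 60),
        n_settlements_per_district=6,
        years=tuple(range(2000, 2005)),
    )
    return ls


@pytest.fixture(scope="session")
def small_census(small_landscape):
    return gh.compute_density(gh.aggregate_truth_to_census(small_landscape))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the reference landscape (24 districts,
    200x200 grid, 20 years, 2 species, seed 42)."""
    out = tmp_path_factory.mktemp("default_run")
    config = gh.RunConfig(out_dir=str(out), seed=42)
    return gh.run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
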