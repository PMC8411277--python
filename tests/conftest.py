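import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mirtrios.synthetic_fixtures import (
    FixtureConfig,
    PlantedTrio,
    generate_fixture,
)


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    """A small bundle with two seed-site trios and one triplex-site trio."""
    cfg = FixtureConfig(
        rng_seed=7,
        n_enhancers=24,
        enhancer_len=400,
        n_mirnas=3,
        n_genes=13,
        n_samples=12,
        planted_trios=(
            PlantedTrio(0, 2, 0, "seed_site", 0.95),
            PlantedTrio(1, 9, 4, "seed_site", 0.95),
            PlantedTrio(2, 17, 8, "triplex_site", 0.95),
        ),
    )
    return generate_fixture(cfg, tmp_path_factory.mktemp("bundle"))
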