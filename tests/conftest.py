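import pytest
from hypothesis import settings

from hdrscan.simdata import PlantedRegion, SimConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A small complete simulated study: 11 vs 14 samples, F=0.10, two
    planted regions (one per fixation mode), genes over both regions."""
    config = SimConfig(
        seed=11,
        planted_regions=[
            PlantedRegion("scaffold_1", 20_000, 22_000, "fixed_difference"),
            PlantedRegion("scaffold_2", 5_000, 7_000, "fixed_with_het"),
        ],
    )
    return simulate_dataset(config, tmp_path_factory.mktemp("simdata"))
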