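import numpy as np
import pytest

from nbssbench import pipeline
from nbssbench.data_model import ConversionConfig, OrganismRecord, StationSample
from nbssbench.synthetic_data import ScenarioConfig, generate_community


@pytest.fixture
def conv_config() -> ConversionConfig:
    return ConversionConfig()


def make_record(dm_ug: float, group: str = "macrofauna", taxon: str = "Polychaeta",
                count: float = 1.0) -> OrganismRecord:
    """A record with a preset dry mass (skips the allometry chain)."""
    return OrganismRecord(
        taxon_id=taxon, group=group, length_mm=1.0, width_mm=1.0,
        count_weight=count, dry_mass_ug=dm_ug,
    )


def make_grab(records, fjord="F1", station="F1S1") -> StationSample:
    return StationSample(fjord, station, "van_veen_grab", 1000.0, list(records))


@pytest.fixture(scope="session")
def paper_like_run():
    """One converted paper-like community, shared across tests."""
    cfg = ScenarioConfig(seed=12345)
    samples, profiles, truth = generate_community(cfg)
    converted = pipeline.convert_samples(samples)
    return cfg, converted, profiles, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
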