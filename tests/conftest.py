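import sys
from datetime import date
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_table

from riverwq import SceneConfig, build_normalization_table, generate_scene
from riverwq.wqi import PARAMETER_IDS, WaterQualityRecord

from oracle_table import DOMAINS


@pytest.fixture(scope="session")
def table():
    return build_normalization_table()


def make_record(values, site_id="SS1", season="summer", day=None):
    return WaterQualityRecord(
        site_id=site_id,
        date=day or date(2018, 1, 15),
        season=season,
        values=dict(values),
    )


def random_record(rng, site_id="SS1"):
    """A record with every parameter drawn uniformly over its scan domain."""
    values = {p: float(rng.uniform(*DOMAINS[p])) for p in PARAMETER_IDS}
    return make_record(values, site_id=site_id)


@pytest.fixture(scope="session")
def small_scene_config():
    """A compact scene: short river, coarse cells, quick to generate, still
    large enough to hold local and regional buffers."""
    return SceneConfig(
        seed=7,
        river_length_m=30_000.0,
        cell_size_m=40.0,
        margin_m=2600.0,
        sinuosity_amplitude_m=800.0,
        sinuosity_wavelength_m=12_000.0,
        blob_size_m=1200.0,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    return generate_scene(small_scene_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180215)
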