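import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ldlrscreen import PipelineConfig, SimulationConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_sim() -> SimulationConfig:
    """A 96-well mini-screen small enough for exhaustive checks."""
    return SimulationConfig(
        n_genes=150,
        wells_per_plate=96,
        n_ns_per_plate=8,
        n_pos_per_plate=2,
        n_neg_per_plate=2,
        n_cytotox_per_plate=2,
        seed=42,
    )


@pytest.fixture
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


def make_wells(rows: list[tuple]) -> pd.DataFrame:
    """Build a well table from (plate, well, replicate, gene, role, count,
    intensity) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "replicate", "gene", "role",
            "valid_object_count", "mean_intensity",
        ],
    )


@pytest.fixture
def wells_factory():
    return make_wells
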