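import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon

from endemapper import (
    RangeMetrics,
    SimulationConfig,
    generate_taxa_and_records,
    run_analysis,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_metrics(
    taxon_id="T0",
    eoo_km2=100.0,
    aoo_km2=8.0,
    n_points=10,
    inside_fraction=1.0,
    eoo_outside_km2=0.0,
    n_outside_points=0,
    eoo_is_fallback=False,
    n_unique_points=None,
    n_aoo_cells=None,
) -> RangeMetrics:
    """Hand-built range metrics for classification tests."""
    return RangeMetrics(
        taxon_id=taxon_id,
        eoo_km2=eoo_km2,
        aoo_km2=aoo_km2,
        n_points=n_points,
        n_unique_points=n_unique_points if n_unique_points is not None else n_points,
        n_aoo_cells=n_aoo_cells if n_aoo_cells is not None else int(aoo_km2 / 4),
        inside_fraction=inside_fraction,
        eoo_outside_km2=eoo_outside_km2,
        n_outside_points=n_outside_points,
        eoo_is_fallback=eoo_is_fallback,
    )


@pytest.fixture(scope="session")
def square_country() -> Polygon:
    """A 2° × 2° square country near the equator."""
    return Polygon([(31, 0), (33, 0), (33, 2), (31, 2)])


@pytest.fixture(scope="session")
def dataset60():
    """Moderate synthetic study: 60 taxa, ~1,400 records."""
    return generate_taxa_and_records(SimulationConfig(seed=1, n_taxa=60))


@pytest.fixture(scope="session")
def analysis60(dataset60):
    return run_analysis(dataset60.records, dataset60.taxa, dataset60.country)
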