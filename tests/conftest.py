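import numpy as np
import pytest
import shapely

from edaphoniche import (
    LandscapeConfig,
    PlotRecord,
    PolygonLayer,
    generate_landscape,
    sample_plots,
    simulate_abundances,
)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(
        extent=(0.0, 0.0, 20_000.0, 20_000.0),
        cell_size=500.0,
        n_classes=4,
        class_patch_scale=4_000.0,
        cec_correlation=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_plots(small_landscape):
    _, truth = small_landscape
    return sample_plots(truth, 150, 0.1, seed=11)


@pytest.fixture(scope="session")
def small_abundances(small_landscape, small_plots):
    _, truth = small_landscape
    return simulate_abundances(small_plots, truth.species, seed=13)


@pytest.fixture
def two_squares():
    """Two adjacent unit-km squares sharing an edge at x=1000."""
    left = shapely.box(0, 0, 1000, 1000)
    right = shapely.box(1000, 0, 2000, 1000)
    return PolygonLayer([left, right], ["ACh", "GLe"])


def make_plot(i, x, y, dataset="synthetic", cation=1.0, **kw):
    return PlotRecord(plot_id=f"p{i}", dataset=dataset, x=x, y=y, cation_cmolkg=cation, **kw)
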