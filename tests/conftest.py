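import numpy as np
import pytest

from rodsizer import (
    CellGeometry,
    DivisionRule,
    ModelParams,
    StrainConfig,
    make_contour,
    simulate_lineages,
    strain_presets,
)


@pytest.fixture(scope="session")
def area_rule():
    return DivisionRule("area", 165.0)


@pytest.fixture(scope="session")
def normal_strain(area_rule):
    return strain_presets(area_rule)["normal"]


@pytest.fixture(scope="session")
def area_records(normal_strain):
    """1000 cycles of the normal-width strain under the area sizer."""
    return simulate_lineages(normal_strain, 1000, seed=11)


@pytest.fixture(scope="session")
def three_strain_area_records(area_rule):
    """Thin/normal/fat populations sharing the fixed-area rule."""
    presets = strain_presets(area_rule, threshold_cv=0.05)
    return {
        name: simulate_lineages(cfg, 500, seed=20 + i)
        for i, (name, cfg) in enumerate(presets.items())
    }


@pytest.fixture(scope="session")
def ideal_contour():
    return make_contour(14.0, 2.0, n_vertices=256)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def wt_geometry():
    return CellGeometry.from_length_radius(14.0, 1.876)
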