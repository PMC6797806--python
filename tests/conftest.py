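"""Shared fixtures: reduced-resolution reference meshes and configurations.

The reference configuration for trend tests is the 3-tooth geometry at
0.6 mm element size (~3,100 elements, ~1,160 trabecular) with the default
materials, loads and remodeling parameters.
"""

import numpy as np
import pytest
from hypothesis import settings

from osteoadapt.config import RunConfig
from osteoadapt.geometry import (
    GeometryParams,
    build_geometry,
    generate_mesh,
    rectangular_mesh,
)
from osteoadapt.materials import MaterialTable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: Element size of the reduced reference mesh used throughout the tests.
REDUCED_H = 0.6


@pytest.fixture(scope="session")
def reduced_params() -> GeometryParams:
    return GeometryParams(element_size=REDUCED_H)


@pytest.fixture(scope="session")
def reduced_mesh(reduced_params):
    return generate_mesh(build_geometry(reduced_params), reduced_params)


@pytest.fixture(scope="session")
def base_config(reduced_params) -> RunConfig:
    return RunConfig(geometry=reduced_params)


@pytest.fixture(scope="session")
def materials() -> MaterialTable:
    return MaterialTable()


@pytest.fixture()
def bar_mesh():
    """10 x 20 mm single-region trabecular bar, 1 mm elements."""
    return rectangular_mesh(10.0, 20.0, 1.0)
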