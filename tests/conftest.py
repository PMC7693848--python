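"""Shared fixtures: solved flow fields are expensive, so they are built once
per session at the coarse desk-scale resolution (3 µm) and reused by the
flow, transport and acceptance tests."""

import warnings

import pytest
from hypothesis import settings

from spiralfoil import geometry as geo
from spiralfoil.flow import FlowConfig, solve_flow
from spiralfoil.transport import (
    DEFAULT_RADII,
    canonical_inlet_distributions,
    simulate_separation,
)

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

RESOLUTION = 3.0  # µm; the documented desk-scale grid


@pytest.fixture(scope="session")
def flow_config():
    return FlowConfig(resolution=RESOLUTION)


@pytest.fixture(scope="session")
def empty_domain():
    return geo.build_downstream_domain(include_foil=False, include_wall=False)


@pytest.fixture(scope="session")
def empty_field(empty_domain, flow_config):
    return solve_flow(empty_domain, flow_config)


@pytest.fixture(scope="session")
def foil_domain():
    return geo.build_downstream_domain()


@pytest.fixture(scope="session")
def foil_field(foil_domain, flow_config):
    return solve_flow(foil_domain, flow_config)


@pytest.fixture(scope="session")
def reference_domain():
    """No-hydrofoil reference: the wall is a downstream collector."""
    return geo.build_downstream_domain(include_foil=False, wall_in_flow=False)


@pytest.fixture(scope="session")
def reference_field(reference_domain, flow_config):
    return solve_flow(reference_domain, flow_config)


@pytest.fixture(scope="session")
def inlet_distributions():
    return canonical_inlet_distributions()


@pytest.fixture(scope="session")
def foil_outcome(foil_domain, foil_field, inlet_distributions):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_separation(
            foil_domain, foil_field, inlet_distributions, DEFAULT_RADII
        )


@pytest.fixture(scope="session")
def reference_outcome(reference_domain, reference_field, inlet_distributions):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_separation(
            reference_domain, reference_field, inlet_distributions, DEFAULT_RADII
        )
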