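"""Shared fixtures: one full default run per geometry, reused across tests."""

import pytest

from follisim import FollicleGeometry, default_parameters, run_simulation


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def antrum_result(params):
    """Default 5-day antrum simulation (the headline scenario)."""
    return run_simulation(params, FollicleGeometry(variant="antrum"))


@pytest.fixture(scope="session")
def two_comp_result(params):
    """Default 5-day two-compartment simulation (gradient/time-course runs)."""
    return run_simulation(params, FollicleGeometry(variant="two_compartment"))


@pytest.fixture(scope="session")
def thick_theca_result(params):
    """Antrum simulation with a 20% thicker theca, otherwise identical."""
    return run_simulation(params, FollicleGeometry(variant="antrum", theca_scale=1.2))
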