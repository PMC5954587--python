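"""Shared fixtures.

The long (10-year) simulations are session-scoped and reused across the
acceptance tests; everything else is generated per test from seeded
synthetic weather.
"""

from __future__ import annotations

import dataclasses

import pytest

from olivecan import default_config, generate_synthetic_weather, run
from olivecan.evaluation import load_reference_dataset


@pytest.fixture(scope="session")
def weather_decade():
    """11 years of seeded synthetic weather (first year is the pre-run)."""
    return generate_synthetic_weather(11, 11, start_year=2000)


@pytest.fixture(scope="session")
def decade_irrigated(weather_decade):
    """10-year run under the default auto-irrigation management."""
    cfg = default_config(years=10, start_year=2001)
    return run(cfg, weather_decade)


@pytest.fixture(scope="session")
def decade_rainfed(weather_decade):
    """Same weather and orchard, but no irrigation at all."""
    cfg = default_config(years=10, start_year=2001)
    cfg = dataclasses.replace(
        cfg, management=dataclasses.replace(cfg.management, irrigation_mode="none")
    )
    return run(cfg, weather_decade)


@pytest.fixture(scope="session")
def reference_table():
    """The packaged observed/simulated evaluation dataset."""
    return load_reference_dataset()
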