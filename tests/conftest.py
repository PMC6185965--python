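import numpy as np
import pandas as pd
import pytest

from cropdrivers import protocol
from cropdrivers.crop_model import preset
from cropdrivers.synthetic_data import (
    CLIMATE_PROFILES,
    ClimateProfile,
    RegionPlan,
    SoilProfile,
    generate_grid,
    generate_weather,
)


@pytest.fixture
def soil():
    return SoilProfile(depth_cm=100.0, tawc_mm=140.0, wp=0.10, fc=0.24)


@pytest.fixture(scope="session")
def south_weather():
    return generate_weather(CLIMATE_PROFILES["south"], 3, seed=42)


@pytest.fixture(scope="session")
def central_weather():
    return generate_weather(CLIMATE_PROFILES["central"], 3, seed=42)


@pytest.fixture(scope="session")
def small_plan():
    return RegionPlan(
        regions=("A", "B"),
        lat_band={"A": "south", "B": "central"},
        irrigated_fraction={"A": 0.3, "B": 0.05},
    )


@pytest.fixture(scope="session")
def small_cells(small_plan):
    return generate_grid(4, seed=7, region_plan=small_plan)


@pytest.fixture(scope="session")
def small_factorial(small_cells):
    """4 cells x 12 sowing years x 2 models x 6 treatments x 2 arms,
    baseline plus one warmed scenario; shared by several test modules."""
    from cropdrivers.synthetic_data import ScenarioDeltas, apply_delta_change

    weather = {
        c.cell_id: generate_weather(
            CLIMATE_PROFILES[c.lat_band], 13, seed=100 + i
        )
        for i, c in enumerate(small_cells)
    }
    deltas = ScenarioDeltas(
        scenario_id="warm", temp_offsets=(3.0,) * 12,
        precip_factors=(0.8,) * 12, co2_ppm=499.0,
    )
    warmed = {cid: apply_delta_change(w, deltas) for cid, w in weather.items()}
    ensemble = protocol.make_ensemble(
        preset("grain_maize"),
        protocol.EnsembleSpec(n_models=2, seed=5, n_air_only=1),
    )
    table = protocol.run_factorial(
        small_cells,
        {("baseline", "obs"): weather, ("warm", "g1"): warmed},
        ensemble,
        {"baseline": 360.0, "warm": 499.0},
    )
    return table
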