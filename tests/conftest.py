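import numpy as np
import pandas as pd
import pytest

from flywaykit import (
    SyntheticScenario,
    assemble_migration_locations,
    assign_windows,
    classify_flight,
    cluster_stopovers,
    qc_telemetry,
    simulate_sightings,
    simulate_telemetry,
)
from flywaykit.windows import WindowGrid


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return SyntheticScenario()


@pytest.fixture(scope="session")
def null_scenario(scenario) -> SyntheticScenario:
    return scenario.stationary()


@pytest.fixture(scope="session")
def grid(scenario) -> WindowGrid:
    return WindowGrid(scenario.y_south_m, scenario.window_height_m, scenario.n_windows)


@pytest.fixture(scope="session")
def sightings(scenario, grid) -> pd.DataFrame:
    records, _ = simulate_sightings(scenario, n=4000, seed=101)
    return assign_windows(records, grid)


@pytest.fixture(scope="session")
def telemetry_locations(scenario, grid) -> pd.DataFrame:
    fixes, _ = simulate_telemetry(scenario, n_birds=20, seed=102)
    retained, _ = qc_telemetry(fixes)
    kind = classify_flight(retained["velocity_ms"].to_numpy())
    sites = cluster_stopovers(retained[kind == "ground"])
    locs = assemble_migration_locations(sites, retained[kind == "flight"])
    return assign_windows(locs, grid)


def make_track(bird="B0", start="2014-04-01", step_h=6.0, points=((0, 0),)) -> pd.DataFrame:
    """Telemetry frame from planar km coordinates at fixed cadence."""
    t0 = pd.Timestamp(start)
    rows = [
        {
            "bird_id": bird,
            "timestamp": t0 + pd.Timedelta(hours=step_h * i),
            "x": p[0] * 1e3,
            "y": p[1] * 1e3,
            "velocity_ms": 1.0 if len(p) < 3 else p[2],
        }
        for i, p in enumerate(points)
    ]
    return pd.DataFrame(rows)
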