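import warnings

import numpy as np
import pandas as pd
import pytest

from canopyhazard.census import CensusDataset
from canopyhazard.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*alive observation.*below the recruitment.*"
        )
        yield


@pytest.fixture(scope="session")
def small_sim():
    """A modest 8-plot, ~3,500-tree simulation shared across read-only tests."""
    cfg = SimulationConfig(
        n_plots_per_region=2,
        plot_area_ha=(0.5, 1.0),
        horizon_yr=14,
        seed=11,
    )
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth


def make_plot_frame(plot_id="P1", region="Western", area=1.0, dates=(2000.0, 2003.0, 2006.0),
                    lat=-5.0, lon=-70.0, elev=150.0):
    return pd.DataFrame(
        {
            "region": [region],
            "area_ha": [area],
            "lat": [lat],
            "lon": [lon],
            "elev_m": [elev],
            "census_dates": [tuple(dates)],
        },
        index=pd.Index([plot_id], name="plot_id"),
    )


def make_obs(plot_id, tree_id, obs, species="Genus001 sp0001", family="Family01",
             is_palm=False):
    """obs: list of (census_index, date, d_mm, status, mode)."""
    rows = []
    for ci, date, d, status, mode in obs:
        rows.append(
            {
                "plot_id": plot_id,
                "tree_id": tree_id,
                "species": species,
                "genus": species.split()[0],
                "family": family,
                "is_palm": is_palm,
                "census_date": date,
                "d_mm": d,
                "status": status,
                "mode_of_death": mode,
                "census_index": ci,
            }
        )
    return rows


def make_dataset(plots: pd.DataFrame, tree_rows: list, traits: pd.DataFrame | None = None):
    trees = pd.DataFrame(tree_rows)
    return CensusDataset(plots=plots, trees=trees, traits=traits)
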