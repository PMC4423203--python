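import numpy as np
import pandas as pd
import pytest

from hyperdom.allometry import AllometryConfig, HeightModel
from hyperdom.census import (
    Dataset,
    assign_regions,
    assign_wood_density,
    read_census_tables,
)
from hyperdom.simulate import SimulationConfig, simulate_dataset

REGION_CODES = ("GS", "BS", "EC", "NW", "SW")


@pytest.fixture(scope="session")
def pinned_allometry():
    """Synthetic allometry config with hand-checkable coefficients.

    Height Weibull (a=50, b=0.03, c=0.8) for every region; dicot coefficient
    0.0509; palm power law AGB = D^2 (ln-intercept 0, slope 2).
    """
    return AllometryConfig(
        dicot_coef=0.0509,
        palm_ln_intercept=0.0,
        palm_ln_slope=2.0,
        height=HeightModel({r: (50.0, 0.03, 0.8) for r in REGION_CODES}),
        version="test-pinned",
    )


def toy_tables(tmp_path):
    """Three trees (two of species A, one of B-genus indet) in one plot."""
    trees = pd.DataFrame(
        [
            # tree, plot, taxon, recruit, census, date, d, pom, alive
            ("t1", "p1", "spA", None, 1, 2000.0, 12.0, 1.3, True),
            ("t1", "p1", "spA", None, 2, 2005.0, 13.0, 1.3, True),
            ("t2", "p1", "spA", None, 1, 2000.0, 20.0, 1.3, True),
            ("t2", "p1", "spA", None, 2, 2005.0, 21.5, 1.3, True),
            ("t3", "p1", "gB", None, 1, 2000.0, 30.0, 1.3, True),
            ("t3", "p1", "gB", None, 2, 2005.0, 30.0, 1.3, True),
        ],
        columns=["tree_id", "plot_id", "taxon_id", "recruit_census",
                 "census_index", "date", "d_cm", "pom_m", "alive"],
    )
    plots = pd.DataFrame(
        [["p1", 1.0, -3.0, -60.0, 120.0, True, True, False, "EC"]],
        columns=["plot_id", "area_ha", "lat", "lon", "elev_m", "old_growth",
                 "terra_firme", "cerrado", "region_label"],
    )
    taxa = pd.DataFrame(
        [
            ["spA", "Fabaceae", "GenA", "GenA alpha", "species"],
            ["gB", "Moraceae", "GenB", "", "genus"],
        ],
        columns=["taxon_id", "family", "genus", "species", "id_level"],
    )
    wd = pd.DataFrame(
        [
            ["species", "GenA alpha", 0.60],
            ["genus", "GenB", 0.62],
            ["family", "Moraceae", 0.55],
        ],
        columns=["level", "name", "rho_g_cm3"],
    )
    paths = {}
    for name, df in [("trees", trees), ("plots", plots), ("taxa", taxa),
                     ("wood_density", wd)]:
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


@pytest.fixture
def toy_dataset(tmp_path) -> Dataset:
    paths = toy_tables(tmp_path)
    return read_census_tables(paths["trees"], paths["plots"], paths["taxa"],
                              paths["wood_density"])


def prepared(ds: Dataset) -> Dataset:
    return assign_wood_density(assign_regions(ds))


@pytest.fixture(scope="session")
def desk_sim():
    """Desk-scale synthetic dataset with all realism features on."""
    ds, truth = simulate_dataset(SimulationConfig(seed=42))
    return prepared(ds), truth


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free identification: no stripping, POM changes, palms or
    missing wood-density entries — the exact-recovery configuration."""
    cfg = SimulationConfig(
        seed=7, unidentified_fraction=0.0, pom_change_prob=0.0,
        monocot_fraction=0.0, wd_missing_species_fraction=0.0,
    )
    ds, truth = simulate_dataset(cfg)
    return prepared(ds), truth
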