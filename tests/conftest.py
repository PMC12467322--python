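import warnings

import numpy as np
import pandas as pd
import pytest

from beenet import SimulationConfig, simulate_community

warnings.filterwarnings("ignore", category=UserWarning)


def make_records(rows, plot_id="P1", plot_type="nearby"):
    """Rows: (individual_id, bee_species, plant_species, grain_count)."""
    return pd.DataFrame(
        [
            {
                "individual_id": ind,
                "bee_species": bee,
                "plot_id": plot_id,
                "plot_type": plot_type,
                "survey_round": 1,
                "plant_species": plant,
                "grain_count": grains,
            }
            for ind, bee, plant, grains in rows
        ]
    )


def random_records(rng, n_individuals=200, n_bees=10, n_plants=20,
                   plot_id="P1", plot_type="nearby"):
    rows = []
    for i in range(n_individuals):
        bee = f"B{rng.integers(n_bees) + 1:02d}"
        plants = rng.choice(n_plants, size=rng.integers(1, 5), replace=False)
        for k in plants:
            rows.append((f"ind{i}", bee, f"L{k + 1:02d}", int(rng.integers(0, 12))))
    return make_records(rows, plot_id, plot_type)


@pytest.fixture(scope="session")
def community():
    """One default synthetic community, shared read-only across tests."""
    return simulate_community(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_records():
    return make_records(
        [
            ("b1", "B1", "P1", 5),
            ("b1", "B1", "P2", 3),
            ("b2", "B1", "P1", 2),
            ("b3", "B2", "P1", 4),
        ]
    )
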