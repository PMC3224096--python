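import numpy as np
import pandas as pd
import pytest

import spotglow as sg


def make_spot_frame(records):
    return pd.DataFrame(
        records,
        columns=[
            "gene_id", "site", "condition", "array_id", "spot_replicate",
            "grid_row", "grid_col", "F", "B",
        ],
    )


@pytest.fixture
def tiny_dataset():
    """Two genes, one spot each, two arrays (one per condition)."""
    rows = []
    for array_id, cond, f1, f2 in [("a1", "A", 500.0, 150.0), ("b1", "B", 800.0, 150.0)]:
        rows.append(("g1", "site1", cond, array_id, 1, 0, 0, f1, 200.0))
        rows.append(("g2", "site1", cond, array_id, 1, 0, 1, f2, 200.0))
    return sg.SpotDataset(make_spot_frame(rows), n_spot_replicates=1)


@pytest.fixture
def small_config():
    return sg.SimulationConfig(n_genes=150, grid_shape=(25, 18), seed=7)


@pytest.fixture
def small_dataset(small_config):
    return sg.simulate_dataset(small_config)


@pytest.fixture
def noise_free_dataset():
    cfg = sg.SimulationConfig(
        n_genes=60, grid_shape=(15, 12), eta_sd=0.0, eps_sd=0.0,
        background_spatial_sd=15.0, background_spot_sd=5.0, seed=5,
    )
    return sg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_simulation():
    """The seeded default study conditions shared by the heavier analyses."""
    cfg = sg.SimulationConfig(seed=11)
    dataset, truth = sg.simulate_dataset(cfg)
    gold = sg.simulate_gold_standard(
        truth, cfg.gold_noise_sd, cfg.gold_n_replicates, seed=12
    )
    return cfg, dataset, truth, gold


@pytest.fixture(scope="session")
def default_report(default_simulation):
    _, dataset, _, gold = default_simulation
    return sg.compare_methods(dataset, gold)


def spot_level_matrix(values_by_array, genes=None, n_rep=1):
    """Build a spot-level matrix frame (gene_id, spot_replicate) x arrays."""
    arrays = list(values_by_array)
    n = len(next(iter(values_by_array.values())))
    genes = genes or [f"g{i}" for i in range(1, n // n_rep + 1)]
    idx = pd.MultiIndex.from_product(
        [genes, range(1, n_rep + 1)], names=["gene_id", "spot_replicate"]
    )
    return pd.DataFrame({a: np.asarray(v, float) for a, v in values_by_array.items()},
                        index=idx)[arrays]
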