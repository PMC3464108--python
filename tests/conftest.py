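"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sgascore import SimulationConfig, simulate_screen


def make_plate(
    sizes: np.ndarray,
    plate_id: str = "p1",
    condition: str = "control",
    experiment_id: str = "exp1",
    genes=None,
) -> pd.DataFrame:
    """Build a colony-table frame from a 2-D size grid (row-major genes)."""
    sizes = np.asarray(sizes, dtype=float)
    rows, cols = sizes.shape
    r = np.repeat(np.arange(1, rows + 1), cols)
    c = np.tile(np.arange(1, cols + 1), rows)
    n = rows * cols
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "screen_id": "s",
            "experiment_id": experiment_id,
            "condition": condition,
            "temperature": "25C",
            "plate_id": plate_id,
            "row": r,
            "col": c,
            "gene": genes,
            "replicate": 1,
            "size": sizes.ravel(),
        }
    )


def random_plates(rng: np.random.Generator, n_plates=3, rows=6, cols=7,
                  zero_frac=0.02) -> pd.DataFrame:
    """A random multi-plate colony table with lognormal sizes and a few
    dead spots."""
    frames = []
    for p in range(n_plates):
        sizes = 100.0 * np.exp(rng.normal(0, 0.2)) * np.exp(
            rng.normal(0, 0.15, size=(rows, cols))
        )
        dead = rng.random((rows, cols)) < zero_frac
        sizes[dead] = 0.0
        frames.append(make_plate(sizes, plate_id=f"p{p}"))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_screen():
    """A small two-experiment screen with one planted sick and one planted
    rescue gene class (96 genes fill one 384-position plate exactly)."""
    config = SimulationConfig(
        n_genes=96, replicates_per_gene=4, n_experiments=2,
        sick_fraction=0.05, rescue_fraction=0.02, seed=11,
    )
    return simulate_screen(config)
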