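import numpy as np
import pandas as pd
import pytest

from packstep import design, experiments
from packstep.synthetic import make_fixture_world


@pytest.fixture(scope="session")
def world():
    """Small static 3-pack world shared across the suite."""
    return make_fixture_world(seed=0, n_packs=3, steps_per_pack=400)


@pytest.fixture(scope="session")
def steps(world):
    return experiments.tracks_to_steps(world)


@pytest.fixture(scope="session")
def design_table(world, steps):
    """Standardized design table for the fixture world (20 controls)."""
    table, terms = experiments.recovery_design(world, n_controls=20, seed=7)
    return table, terms


@pytest.fixture(scope="session")
def small_strata():
    """A tiny hand-checkable stratified table: 60 strata, 2 covariates."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(60):
        x = rng.normal(size=(4, 2))
        w = np.exp(x @ np.array([1.0, -0.5]))
        used = rng.choice(4, p=w / w.sum())
        for r in range(4):
            rows.append(
                {
                    "stratum_id": f"s{s:03d}",
                    "pack_id": "packA" if s % 2 else "packB",
                    "y": int(r == used),
                    "u": x[r, 0],
                    "v": x[r, 1],
                }
            )
    return pd.DataFrame(rows)
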