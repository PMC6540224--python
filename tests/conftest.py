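import numpy as np
import pandas as pd
import pytest

from efoscreen import ScoreTable, SyntheticConfig, generate


@pytest.fixture
def tiny_table() -> ScoreTable:
    """5 molecules, 2 score columns, 2 actives."""
    return ScoreTable(
        molecule_ids=np.array(["m1", "m2", "m3", "m4", "m5"], dtype=object),
        labels=np.array([1, 0, 1, 0, 0]),
        scores=pd.DataFrame(
            {"plp": [-52.0, -31.5, -48.0, -20.0, -25.5],
             "xscore": [6.1, 4.0, 5.8, 3.2, 3.9]}
        ),
        properties=pd.DataFrame(
            {"molecular_weight": [250.0, 310.0, 410.0, 180.0, 275.0],
             "heavy_atoms": [18.0, 22.0, 30.0, 13.0, 20.0]}
        ),
    )


def random_table(seed: int, n: int = 60, n_active: int | None = None,
                 n_scores: int = 3) -> ScoreTable:
    """Small random table with no planted signal."""
    rng = np.random.default_rng(seed)
    if n_active is None:
        n_active = int(rng.integers(1, max(2, n // 4)))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_active, replace=False)] = 1
    return ScoreTable(
        molecule_ids=np.array([f"mol_{i:04d}" for i in range(n)], dtype=object),
        labels=labels,
        scores=pd.DataFrame(
            rng.standard_normal((n, n_scores)),
            columns=[f"s{j}" for j in range(n_scores)],
        ),
    )


@pytest.fixture
def planted_table():
    """Small DUD-like table with a clear planted 2-score signal."""
    cfg = SyntheticConfig(
        n_molecules=400, n_active=16, n_scores=4, effect_size=2.5,
        loadings=(-1.0, -0.9, -0.3, -0.25), noise_sds=(0.7, 0.7, 1.0, 1.0),
        seed=123,
    )
    return generate(cfg)
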