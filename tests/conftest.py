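import numpy as np
import pandas as pd
import pytest

from cotwin.simulate import (
    PlantedBlock,
    SimulationConfig,
    generate_cohort,
    generate_methylation,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-pair cohort with one planted 6-probe block, shared by read-only tests."""
    cfg = SimulationConfig(
        n_pairs=20,
        n_probes=200,
        n_genes=40,
        n_batches=5,
        seed=42,
        planted_dmrs=[PlantedBlock(6, 0.6, 1.3)],
    )
    cohort = generate_cohort(cfg)
    betas, manifest, truth = generate_methylation(cfg, cohort)
    return cfg, cohort, betas, manifest, truth


@pytest.fixture()
def toy_sample_sheet():
    """Two complete pairs with identical shared covariates within pair."""
    rows = []
    for j, pair in enumerate(["p0", "p1"]):
        for role, tag in (("depressed", "d"), ("nondepressed", "n")):
            rows.append(
                {
                    "sample_id": f"{pair}_{tag}",
                    "pair_id": pair,
                    "role": role,
                    "batch_id": "chip0",
                    "age": 30.0 + j,
                    "sex": j % 2,
                    "bmi": 25.0 + (0.5 if role == "depressed" else 0.0),
                    "smoking": 0.0,
                    "alcohol": 2.0,
                    "income": 3,
                    "education": 2,
                    "ace": 0,
                    "ptsd": 0,
                    "antidepressant": 0,
                }
            )
    return pd.DataFrame(rows)


def make_pair_sheet(n_pairs: int, n_batches: int = 1, seed: int = 0) -> pd.DataFrame:
    """Minimal complete sample sheet for synthetic matrices."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_pairs):
        age = float(rng.integers(20, 60))
        sex = int(rng.integers(0, 2))
        for role, tag in (("depressed", "d"), ("nondepressed", "n")):
            rows.append(
                {
                    "sample_id": f"p{j}_{tag}",
                    "pair_id": f"p{j}",
                    "role": role,
                    "batch_id": f"b{j % n_batches}",
                    "age": age,
                    "sex": sex,
                    "bmi": float(rng.normal(26, 4)),
                    "smoking": float(abs(rng.normal(0, 5))),
                    "alcohol": float(rng.integers(0, 10)),
                    "income": int(rng.integers(1, 6)),
                    "education": int(rng.integers(1, 5)),
                    "ace": int(rng.integers(0, 2)),
                    "ptsd": int(rng.integers(0, 2)),
                    "antidepressant": int(rng.integers(0, 2)),
                }
            )
    return pd.DataFrame(rows)
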