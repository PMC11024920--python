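"""Shared fixtures: small simulated studies and constructed tables."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from flocknet.config import SimConfig
from flocknet.simulate import simulate_study

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete study: 2 sites x 20 birds, short periods."""
    cfg = SimConfig(n_individuals_per_site=20, baseline_days=3, trial_days=2,
                    events_per_site_day=12.0, seed=101)
    population, stream, truth = simulate_study(cfg)
    return cfg, population, stream, truth


@pytest.fixture(scope="session")
def glm_fixture():
    """Shipped 40-row synthetic usage-model table (fixed, versioned)."""
    df = pd.read_csv(DATA_DIR / "glm_fixture.csv", dtype={"tag_id": str})
    df["immigrant"] = df["immigrant"].astype(bool)
    return df


def fixture_model_frames(df):
    """Split the flat GLM fixture into (responses, metrics, traits)."""
    responses = pd.DataFrame({
        "novel_count": df["novel_count"].to_numpy(),
        "familiar_count": df["familiar_count"].to_numpy(),
        "first_arrival_novel": df["novel_count"].to_numpy() > df["familiar_count"].to_numpy(),
        "latency_clock": np.nan, "latency_elapsed": np.nan,
        "post_first_novel_count": 0, "post_first_familiar_count": 0,
        "first_use_day": 0,
        "n_detections": (df["novel_count"] + df["familiar_count"]).to_numpy(),
    }, index=pd.Index(df["tag_id"], name="tag_id"))
    metrics = pd.DataFrame({
        "strength": df["strength"].to_numpy(),
        "average_edge_weight": df["strength"].to_numpy() / 10,
        "eigenvector_centrality": df["strength"].to_numpy()
        / df["strength"].max(),
        "mean_flock_size": 5.0, "n_unique_associates": 10, "n_events": 20,
        "prior_detections": df["prior_detections"].to_numpy(),
    }, index=responses.index)
    traits = df[["tag_id", "site_id", "sex", "age", "immigrant"]].copy()
    return responses, metrics, traits
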