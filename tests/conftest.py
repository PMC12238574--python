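"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from noiseplast.pipeline import PipelineParams, run_pipeline
from noiseplast.simdata import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-scale screen used by unit and integration tests."""
    kwargs = dict(
        n_nonessential=12,
        n_essential=5,
        n_conditions=8,
        n_replicates=2,
        events_per_population=600,
        seed=7,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


SMALL_PARAMS = PipelineParams(min_events=200)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_result(small_dataset):
    ds = small_dataset
    return run_pipeline(
        ds.events,
        gene_meta=ds.gene_meta,
        condition_meta=ds.condition_meta,
        params=SMALL_PARAMS,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_events(n=50, seed=0, **keys) -> pd.DataFrame:
    """A single-population canonical event table with positive channels."""
    r = np.random.default_rng(seed)
    base = dict(
        strain_id="gX", condition_id="c1", replicate_id="r1", batch_id="d1"
    )
    base.update(keys)
    return pd.DataFrame(
        {
            **base,
            "fsc": 10.0 ** r.normal(2.5, 0.05, n),
            "ssc": 10.0 ** r.normal(2.5, 0.08, n),
            "yfp_raw": 10.0 ** r.normal(2.0, 0.3, n) + 20.0,
        }
    )[
        [
            "strain_id",
            "condition_id",
            "replicate_id",
            "batch_id",
            "fsc",
            "ssc",
            "yfp_raw",
        ]
    ]
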