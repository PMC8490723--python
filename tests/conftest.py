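"""Shared fixtures.

``study_runs`` simulates and analyses ten replicate studies with the
default configuration; it is session-scoped because the calibration and
sign-reproduction checks both consume it and a full study takes ~10 s.
"""

from __future__ import annotations

import logging

import pytest

from slipgait import StudyConfig, compute_study_metrics, simulate_study
from slipgait.config import BeltProtocol, GeneratorConfig

logging.getLogger("slipgait").setLevel(logging.ERROR)

N_REPLICATES = 10
REPLICATE_SEEDS = list(range(1, N_REPLICATES + 1))


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A reduced study (4 participants, 2 slips) for fast pipeline tests."""
    return StudyConfig(
        generator=GeneratorConfig(n_ya=2, n_oa=2),
        protocol=BeltProtocol(n_slips=2),
    )


@pytest.fixture(scope="session")
def study_runs(default_config):
    """Metrics for ten replicate default studies (seeds 1..10)."""
    runs = []
    for seed in REPLICATE_SEEDS:
        dataset = simulate_study(default_config, seed)
        metrics, outcomes, baselines, events, curves = compute_study_metrics(
            dataset, default_config.analysis
        )
        runs.append(
            {
                "seed": seed,
                "dataset": dataset,
                "metrics": metrics,
                "outcomes": outcomes,
                "baselines": baselines,
            }
        )
    return runs
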