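"""Shared fixtures: session-scoped synthetic datasets.

The heavier fixtures (sequence benchmark, feature tables) are built once
per session and shared, so the model/evaluation tests do not regenerate
the same transcripts repeatedly.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noncode import (
    SimulationConfig,
    extract_features,
    planted_feature_table,
    simulate_transcripts,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def benchmark_records():
    """Separable synthetic benchmark: 400 coding + 400 noncoding, defaults."""
    config = SimulationConfig(n_coding=400, n_noncoding=400, seed=BENCHMARK_SEED)
    return simulate_transcripts(config)


@pytest.fixture(scope="session")
def benchmark_table(benchmark_records):
    """91-feature labeled table of the separable benchmark (n = 800)."""
    records, labels = benchmark_records
    label_map = {r.id: int(l) for r, l in zip(records, labels)}
    return extract_features(records, labels=label_map)


@pytest.fixture(scope="session")
def planted_table():
    """Tabular planted-signal set: 3 informative of 91, 2 SD shift, n=400."""
    return planted_feature_table(n=400, shift=2.0, seed=5)


@pytest.fixture(scope="session")
def noise_table():
    """Pure-noise table: no informative features at all."""
    return planted_feature_table(n=200, informative=(), seed=6)
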