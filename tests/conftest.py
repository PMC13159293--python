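"""Shared fixtures: one synthetic study and its seeded search runs.

The heavyweight artifacts (the study and the five seeded MAP-Elites runs)
are session-scoped so the directional-protocol tests share them instead of
re-running the searches.
"""

from __future__ import annotations

import numpy as np
import pytest

from qdrx.pipeline import Study, build_study, run_global, run_search
from qdrx.synthetic_data import SyntheticKGConfig, simulate_kg

STUDY_SEED = 1
SEARCH_SEEDS = [100, 101, 102, 103, 104]


@pytest.fixture(scope="session")
def kg_small():
    """A compact knowledge graph for unit tests."""
    return simulate_kg(
        SyntheticKGConfig(
            n_genes=120, n_drugs=60, n_diseases=3,
            n_anchor_genes=8, n_anchor_drugs=4, seed=7,
        )
    )


@pytest.fixture(scope="session")
def study() -> Study:
    return build_study(STUDY_SEED)


@pytest.fixture(scope="session")
def search_runs(study):
    """Five independently seeded MAP-Elites runs on the shared study."""
    return [run_search(study, s, generations=40, batch_per_gen=25) for s in SEARCH_SEEDS]


@pytest.fixture(scope="session")
def global_runs(study):
    """Five seeded global-learner baseline runs (test-subset metrics)."""
    return [run_global(study, 200 + k) for k in range(5)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
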