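"""Shared fixtures: the seeded reference scenario and its full analysis chain.

The expensive objects (simulated cohorts, inferred network, downstream
results) are session-scoped so every test file reuses one computation.
"""
from __future__ import annotations

import numpy as np
import pytest

from regmaster.diffexp import moderated_t_test
from regmaster.network import filter_regulons, infer_network
from regmaster.simulate import reference_scenario

SCENARIO_SEED = 1
INFER_SEED = 11
GSEA_SEED = 12
CMAP_SEED = 13

# regulons are planted with 30 targets; the analysis tier keeps anything
# with at least this many inferred targets
ANALYSIS_TIER = 10


@pytest.fixture(scope="session")
def scenario():
    """(config, truth, reference_expr, studies, signature_db) at the fixed seed."""
    return reference_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def network(scenario):
    _, truth, ref, _, _ = scenario
    return infer_network(ref, list(truth.tf_ids), seed=INFER_SEED)


@pytest.fixture(scope="session")
def analysis_network(network):
    return filter_regulons(network, ANALYSIS_TIER)


@pytest.fixture(scope="session")
def de_results(scenario):
    _, _, _, studies, _ = scenario
    return [moderated_t_test(s.expression, s.phenotype, study_id=s.study_id) for s in studies]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
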