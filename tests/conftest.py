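from __future__ import annotations

import pytest

from drugtally.synthetic import SimulationConfig, generate, table3_fixture

# the hypothetical patient's published count under each preset measure
HYPOTHETICAL_COUNTS = {
    "default": 3, "v1": 3, "v2": 2, "v3": 3, "v4": 3,
    "v5": 4, "v6": 4, "v7": 3, "v8": 4, "v9": 4,
    "v10": 3, "v11": 3, "v12": 3, "v13": 4, "v14": 3,
}


@pytest.fixture(scope="session")
def table3():
    """(history, dictionary) for the hypothetical patient."""
    return table3_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort: (dictionary, histories)."""
    from drugtally.io import assemble_histories

    cfg = SimulationConfig(n_patients=40, seed=11)
    dictionary, fills, stays, index_events = generate(cfg)
    histories = assemble_histories(fills, stays, index_events)
    return dictionary, histories
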