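import warnings

import pytest

from facespace import SimulationConfig, aggregate_score, filter_rts, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: 8 participants, 12 identities x 10 occurrences."""
    return SimulationConfig(
        n_participants=8,
        n_occurrences=10,
        n_inverted=12,
        n_chairs=12,
        seed=20240917,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_cleaned(small_data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return filter_rts(small_data.trials)


@pytest.fixture(scope="session")
def small_composites(small_data):
    comp = aggregate_score(small_data.battery).table
    return comp.merge(
        small_data.battery[["participant_id", "gender"]], on="participant_id"
    )
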