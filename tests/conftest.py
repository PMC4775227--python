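import numpy as np
import pytest

import hdxthermo as ht


@pytest.fixture
def noise_free_thermal_series():
    """Seven-temperature bimodal series with the default thermal law, no noise."""
    scenario = ht.ExchangeScenario(noise_rel=0.0)
    clusters, fractions = ht.simulate_series(scenario)
    return scenario, clusters, fractions


@pytest.fixture
def controls():
    """Unexchanged and fully deuterated control envelopes for one peptide."""
    scenario = ht.ExchangeScenario(noise_rel=0.0)
    unexchanged = ht.simulate_isotope_envelope(scenario, 0.0)
    unexchanged.condition_type = "control"
    unexchanged.condition_value = "unexchanged"
    full = ht.simulate_isotope_envelope(scenario, 1.0)
    full.condition_type = "control"
    full.condition_value = "fully_deuterated"
    return scenario, unexchanged, full


def per_seed_rng(seed):
    return np.random.default_rng(seed)
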