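import numpy as np
import pytest

import allochthon as al
from allochthon.polygon import screen_consumers
from allochthon.trophic import correct_table


@pytest.fixture(scope="session")
def foodweb():
    """Default synthetic food web (3 sources, 60 consumers/group, seed 1)."""
    table, truth = al.simulate_foodweb(al.GeneratorConfig(seed=1, n_per_group=60))
    return table, truth


@pytest.fixture(scope="session")
def corrected_foodweb(foodweb):
    """Food web with source-corrected δ2H and polygon screening applied."""
    table, truth = foodweb
    corr = correct_table(table.consumers, table.water)
    d2h = dict(zip(corr["sample_id"], corr["d2H_source"]))
    vals = np.array([[c.d13C, d2h[c.sample_id]] for c in table.consumers])
    results = screen_consumers(table.consumers, table.sources, ("d13C", "d2H"),
                               seed=2, consumer_values=vals)
    retained = {r.sample_id for r in results if r.retained}
    return table, truth, d2h, retained, results


@pytest.fixture
def two_sources_1d():
    """Well-separated one-tracer sources for small oracle problems."""
    return [
        al.SourceDistribution("left", {"d13C": -30.0}, {"d13C": 1.5}),
        al.SourceDistribution("right", {"d13C": -10.0}, {"d13C": 1.5}),
    ]
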