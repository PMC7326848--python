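"""Shared Monte Carlo samples, generated once per session.

The detection stage is CRT-independent, so unsmeared triple samples can be
shared across tests that study different resolution settings.
"""

import numpy as np
import pytest

from ops_imaging.detector import simulate_triples
from ops_imaging.generator import SourceSpec, generate_events, nema_sources


@pytest.fixture(scope="session")
def source6_raw():
    """Unsmeared registered triples from the (20, 0, 75) cm source alone."""
    rng = np.random.default_rng(601)
    src = SourceSpec(6, (20.0, 0.0, 75.0), 3.0)
    events = generate_events([src], 3_000_000, rng)
    raw, _ = simulate_triples(events, rng=rng, smear=False)
    return raw


@pytest.fixture(scope="session")
def nema_raw():
    """Unsmeared registered triples from the six-source arrangement."""
    rng = np.random.default_rng(602)
    events = generate_events(nema_sources(), 2_000_000, rng)
    raw, counters = simulate_triples(events, rng=rng, smear=False)
    return raw, counters
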