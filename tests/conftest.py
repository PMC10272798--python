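"""Shared fixtures: one reference inflation run and one Sobol campaign.

Both are expensive (seconds to minutes), so they are computed once per
session and shared; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import cuffsim
from cuffsim import beat_metrics as bm
from cuffsim import circulation as circ
from cuffsim import sobol as sbl

#: Acceptance-scale Sobol campaign settings (power-of-two base sample).
SOBOL_N = 512
SOBOL_SEED = 0
SOBOL_DT = 5e-4


@pytest.fixture(scope="session")
def reference_input() -> circ.SystemicInput:
    return circ.SystemicInput()


@pytest.fixture(scope="session")
def reference_run(reference_input):
    """Default inflation run: 120/80 mmHg, HR 60, 6 mmHg/s, hold 60 s."""
    return circ.simulate(reference_input, circ.CuffProtocol(), dt=5e-4)


@pytest.fixture(scope="session")
def reference_beats(reference_run, reference_input):
    return bm.segment_beats(reference_run, reference_input)


@pytest.fixture(scope="session")
def reference_ptt(reference_beats):
    return bm.compute_ptt_series(reference_beats)


@pytest.fixture(scope="session")
def reference_metrics(reference_run, reference_beats, reference_ptt, reference_input):
    return bm.extract_metrics(
        reference_run, reference_beats, reference_ptt, reference_input
    )


@pytest.fixture(scope="session")
def sobol_bundle():
    """Full sensitivity campaign: (SobolResult, outputs matrix, design)."""
    return sbl.run_sobol_analysis(n_base=SOBOL_N, seed=SOBOL_SEED, dt=SOBOL_DT)


@pytest.fixture(scope="session")
def short_run(reference_input):
    """A shorter run (reduced hold) for tests that only need the ramp."""
    protocol = circ.CuffProtocol(hold_s=20.0)
    return protocol, circ.simulate(reference_input, protocol, dt=5e-4)
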