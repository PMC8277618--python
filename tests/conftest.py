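"""Shared fixtures: small simulated populations and cached posterior calls.

All fixtures are deterministic (fixed seeds) and session-scoped so the
simulation cost is paid once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from polydose.observe import ObservationNoiseConfig
from polydose.pipeline import call_simulated_reads
from polydose.simulate import SimPopulationConfig, simulate_f1


def offspring_truth(truth):
    """True dosages as a markers x offspring matrix (caller layout)."""
    return truth.true_dosages.T


def full_truth(truth):
    """True dosages markers x samples with the parents prepended."""
    return np.vstack([truth.parental_dosages().T, truth.true_dosages]).T


@pytest.fixture(scope="session")
def truth_small():
    """200 F1, five seg types every 5 cM over 100 cM: 105 markers."""
    return simulate_f1(SimPopulationConfig(marker_spacing=5.0, seed=11))


@pytest.fixture(scope="session")
def truth_tiny():
    """100 F1, five seg types every 10 cM: 55 markers (fast end-to-end runs)."""
    return simulate_f1(
        SimPopulationConfig(n_individuals=100, marker_spacing=10.0, seed=7)
    )


@pytest.fixture(scope="session")
def reads40_post(truth_small):
    """Family-called posteriors for 40x reads, no overdispersion."""
    noise = ObservationNoiseConfig(overdispersion=0.0, depth=40, seed=101)
    return call_simulated_reads(truth_small, noise)


@pytest.fixture(scope="session")
def reads_tiny_post(truth_tiny):
    noise = ObservationNoiseConfig(overdispersion=0.0, depth=60, seed=17)
    return call_simulated_reads(truth_tiny, noise)
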