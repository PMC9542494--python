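"""Shared fixtures: simulated experiments reused across test modules."""

import pytest

from invasionlab.synthetic import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def sim_default():
    """One full-design mechanistic simulation (180 invaded + 45 reference)."""
    return simulate_experiment(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def sim_small():
    """A reduced-replication simulation for fast structural tests."""
    return simulate_experiment(SimulationConfig(), seed=7, replicates=2,
                               reference_replicates=2)


@pytest.fixture(scope="session")
def full_report(sim_default):
    """The full model battery run once on the default simulation."""
    from invasionlab.inference import run_full_analysis

    return run_full_analysis(sim_default.counts, sim_default.day4_reference)
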