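import numpy as np
import pytest

from vpckit import SimulationConfig, simulate_session


def small_config(seed: int = 0, **over) -> SimulationConfig:
    """A reduced-geometry session config for fast unit tests."""
    base = dict(
        n_blocks_rest=2, n_blocks_fix=1, block_duration=210.0,
        stim_epochs_per_block=1, stim_onsets=(60.0,),
        areas=(("CN", "none", 4), ("LIP", "deep", 4)),
        vpc_prob_by_condition={"NS": 0.6, "10Hz": 0.6, "50Hz": 0.6, "200Hz": 0.6},
        str_prob=0.5, kindling_slope=0.0, seed=seed,
    )
    base.update(over)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_session():
    """One cached small session with at least one event of each type."""
    for seed in range(20):
        rec, beh, ledger, truth = simulate_session(small_config(seed=30 + seed))
        kinds = set(truth.true_events.event_type) if len(truth.true_events) else set()
        if {"VPC", "STR"} <= kinds:
            return rec, beh, ledger, truth
    raise RuntimeError("no seed produced both event types")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
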