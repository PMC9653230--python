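"""Shared fixtures.

The channel steady states are expensive (minutes each), so they are
computed once per session and shared between the phenomenology,
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rodcolony.dynamics import RunConfig, run, run_frozen_column
from rodcolony.fields import RegionSpec, region_order, region_stress
from rodcolony.params import ModelParams
from rodcolony.theory import steady_state_distribution

CENTRAL_REGION = RegionSpec.rect((0.0, 0.0), 25.0, 5.0)


def channel_config(lmax: float, seed: int) -> RunConfig:
    """The reduced-scale (50 x 50) channel protocol: 10 generations of
    burn-in, then 5 generations sampled 5x per generation."""
    return RunConfig(geometry="channel", width=50.0, height=50.0,
                     lmax=lmax, seed=seed, generations=15.0,
                     burn_in_generations=10.0, snapshot_start=10.1,
                     snapshot_every=0.2)


def measure_channel(result):
    """Central-region measurements of a channel run."""
    snaps = result.snapshots
    xis = np.array([region_order(s, CENTRAL_REGION) for s in snaps])
    sig = np.mean([region_stress(s, CENTRAL_REGION) for s in snaps], axis=0)
    sxx, syy = abs(sig[0, 0]), abs(sig[1, 1])
    return {
        "xi": float(np.nanmean(xis)),
        "sigma": sig,
        "delta_sigma": (sxx - syy) / (sxx + syy),
        "n_final": snaps[-1].n,
        "snapshots": snaps,
    }


@pytest.fixture(scope="session")
def params6():
    return ModelParams(lmax=6.0)


@pytest.fixture(scope="session")
def dist6():
    return steady_state_distribution(6.0, (0.75, 1.25))


@pytest.fixture(scope="session")
def channel_lmax2():
    """Steady-state 50 x 50 channel of short rods (lmax = 2)."""
    return measure_channel(run(channel_config(2.0, seed=1)))


@pytest.fixture(scope="session")
def channel_lmax6_seeds():
    """Steady-state 50 x 50 channels of long rods (lmax = 6), 3 seeds."""
    return [measure_channel(run(channel_config(6.0, seed=s)))
            for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def frozen_column_run():
    """A 1D frozen-orientation column, height 50, lmax = 6: 10
    generations of burn-in and 20 generations of measurement."""
    cfg = RunConfig(geometry="column", width=10.0, height=50.0, lmax=6.0,
                    seed=3, generations=30.0, burn_in_generations=10.0,
                    snapshot_start=10.0, snapshot_every=0.05)
    return run_frozen_column(cfg)
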