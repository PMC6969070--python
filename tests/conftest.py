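"""Shared fixtures: RNGs and the heavy 1000-replication condition grids.

The full-scale condition runs are session-scoped because several acceptance
checks (cost differences, knowledge parity, monotonicity, conservation)
read different metrics off the same simulations.
"""

from dataclasses import replace

import numpy as np
import pytest

import replisim as rs

TEMPERATURES = (1.0, 5.0, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _regime_grid(base: rs.ScenarioConfig, n_replications: int = 1000):
    """Run both regimes at each temperature, matched seeds across regimes."""
    out = {}
    for i, t in enumerate(TEMPERATURES):
        for regime in (rs.PRIVATE, rs.PUBLIC):
            cfg = replace(
                base,
                regime=regime,
                interest=replace(base.interest, temperature=t),
                n_replications=n_replications,
                seed=base.seed + i,
            )
            out[(regime, t)] = rs.run_condition(cfg)
    return out


@pytest.fixture(scope="session")
def discovery_grid():
    """Discovery mode, frequentist, power .8 (n=34, sigma=2), 1000 reps."""
    base = rs.ScenarioConfig(
        mode=rs.DISCOVERY,
        test=rs.TestConfig(framework=rs.FREQUENTIST, sigma_noise=2.0, n=34),
        seed=1100,
    )
    return _regime_grid(base)


@pytest.fixture(scope="session")
def theory_grid():
    """Theory mode, perfect theory (rho = 1), frequentist power .8."""
    base = rs.ScenarioConfig(
        mode=rs.THEORY,
        rho=1.0,
        test=rs.TestConfig(framework=rs.FREQUENTIST, sigma_noise=2.0, n=34),
        seed=1200,
    )
    return _regime_grid(base)


@pytest.fixture(scope="session")
def symmetric_grid():
    """Theory mode, symmetric Bayesian notability (BF10 > 3 or BF01 > 3)."""
    base = rs.ScenarioConfig(
        mode=rs.THEORY,
        rho=1.0,
        test=rs.TestConfig(framework=rs.BAYESIAN, sigma_noise=1.5, n=34),
        symmetric_null=True,
        seed=1300,
    )
    return _regime_grid(base)
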