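"""Shared fixtures: synthetic observers and simulated behavioral datasets."""

from __future__ import annotations

import numpy as np
import pytest

from corrddm.ddm import DDMSpec
from corrddm.fitting import apply_rt_exclusions
from corrddm.task import TaskConfig, records_to_dataframe, simulate_observer_dataset

# zero-correlation generative means per evidence level for a k0=8 observer
# calibrated to the staircase target (accuracy 0.794 at 1.4 s viewing)
MU0_K8 = {"low": 0.0548, "high": 0.1371}


def make_spec(**overrides) -> DDMSpec:
    """Reference full-rho observer used across fitting tests."""
    kw = dict(
        variant="full_rho",
        k0=8.0,
        B0=1.2,
        tB=0.05,
        ndt=0.35,
        lapse=0.02,
        rho_hat_minus=-0.5,
        rho_hat_plus=0.5,
        mu_0=MU0_K8,
    )
    kw.update(overrides)
    return DDMSpec(**kw)


def make_dataset(
    spec: DDMSpec,
    seed: int,
    magnitude: float = 0.6,
    n_blocks: int = 1,
    trials_per_block: int = 192,
    exclusions: bool = True,
):
    cfg = TaskConfig(
        correlation_magnitude=magnitude,
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed + 7919)
    df = records_to_dataframe(
        simulate_observer_dataset(spec, cfg, rng), config=cfg
    )
    return apply_rt_exclusions(df) if exclusions else df


@pytest.fixture(scope="session")
def reference_spec() -> DDMSpec:
    return make_spec()


@pytest.fixture(scope="session")
def small_dataset(reference_spec):
    """One simulated participant, 192 trials, exclusions applied."""
    return make_dataset(reference_spec, seed=5)
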