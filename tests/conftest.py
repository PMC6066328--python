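"""Shared fixtures for the dynamic-force-spectroscopy test suite."""

import numpy as np
import pytest

from dfspec import (
    DetectionParams,
    KineticParams,
    SimulationConfig,
    TetherModel,
    simulate_retract_curve,
)
from dfspec.events import RuptureEvent


@pytest.fixture(scope="session")
def kin():
    """Reference bond: slow dissociator, 0.3 nm barrier."""
    return KineticParams(k0_off=0.2, x_beta=0.3)


@pytest.fixture(scope="session")
def tether():
    return TetherModel.peg_5k_pair()


@pytest.fixture(scope="session")
def detection():
    return DetectionParams()


def make_curve(kin, curve_class="specific", velocity=1000.0, noise_sd=0.0, seed=0,
               curve_id="test"):
    """One simulated retraction curve with its ground truth."""
    cfg = SimulationConfig(kin=kin, fractions=(1.0, 0.0, 0.0), noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    return simulate_retract_curve(cfg, curve_class, rng, velocity=velocity, curve_id=curve_id)


def make_stage_events(kin, rng, rates_per_group=50, nominal_rates=None, log_sd=0.08,
                      lc=80.9):
    """Stage-level rupture events sampled directly from the Bell-Evans model.

    Loading rates are log-normal around six nominal rates; forces come
    from the inverse-CDF sampler. No curve extraction involved.
    """
    from dfspec import sample_rupture_force

    if nominal_rates is None:
        nominal_rates = np.geomspace(300.0, 30000.0, 6)
    events = []
    i = 0
    for rn in nominal_rates:
        rr = rn * 10 ** rng.normal(0.0, log_sd, rates_per_group)
        uu = rng.uniform(1e-12, 1.0, rates_per_group)
        for r, u in zip(rr, uu):
            events.append(
                RuptureEvent(
                    curve_id=f"e{i}",
                    rupture_force=float(sample_rupture_force(float(r), kin, float(u))),
                    rupture_index=0,
                    contour_length=lc,
                    loading_rate=float(r),
                    accepted=True,
                )
            )
            i += 1
    return events
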