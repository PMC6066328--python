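"""Reproducible simulation studies at the reference study scales.

These wrap the library into the named computations a reader would run to
check the headline numbers: bootstrap uncertainty of adhesion
frequencies at the reference trial counts, off-rate recovery of the full
pipeline at the reference event counts, and the lifetime fold-difference
between a slow and a fast dissociator.
"""

from __future__ import annotations

import numpy as np

from .binding import binding_probability
from .physics import KineticParams
from .pipeline import ExperimentConfig, Report, run_pipeline
from .simulate import kinetics_study_config, simulate_binding_outcomes

__all__ = [
    "bootstrap_se_study",
    "recover_off_rate",
    "lifetime_fold_study",
]

#: barrier width used for all off-rate recovery studies (nm)
X_BETA_STUDY = 0.3


def bootstrap_se_study(p: float, n: int, n_replicates: int, seed: int,
                       B: int = 1000) -> float:
    """Average bootstrap s.e. (percent) of p-hat over replicate experiments.

    Each replicate draws ``n`` Bernoulli(p) contact trials, estimates the
    binding probability and its bootstrap-with-replacement standard
    error (``B`` resamples), and the s.e. values are averaged.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 * n_replicates)
    ses = []
    for i in range(n_replicates):
        outcomes = simulate_binding_outcomes(p, n, seed=int(sub[2 * i]))
        res = binding_probability(outcomes, B=B, seed=int(sub[2 * i + 1]))
        ses.append(res.se)
    return 100.0 * float(np.mean(ses))


def recover_off_rate(k0_true: float, n_accepted_target: int, seed: int,
                     B: int = 1) -> Report:
    """Full pipeline on one synthetic dataset with known kinetics.

    Simulates an adhesion-enriched force-curve experiment sized so that
    about ``n_accepted_target`` specific events survive the
    contour-length gate, runs detection, tether fitting, gating, rate
    estimation and the Bell-Evans fit, and returns the report.
    """
    kin = KineticParams(k0_off=k0_true, x_beta=X_BETA_STUDY)
    sim = kinetics_study_config(kin, n_accepted_target, seed=seed)
    config = ExperimentConfig(simulation=sim, bootstrap_B=B, bootstrap_seed=seed,
                              cluster_seed=seed)
    return run_pipeline(config)


def lifetime_fold_study(k0_slow: float, n_slow: int, k0_fast: float, n_fast: int,
                        n_pairs: int, seed: int) -> float:
    """Mean recovered lifetime fold-difference over paired simulations.

    Each pair simulates one dataset per bond (the slow dissociator at
    ``n_slow`` accepted events, the fast one at ``n_fast``), recovers
    both off-rates, and forms the lifetime ratio
    (1/k0_slow-hat) / (1/k0_fast-hat); the ratios are averaged.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 * n_pairs)
    ratios = []
    for i in range(n_pairs):
        slow = recover_off_rate(k0_slow, n_slow, seed=int(sub[2 * i]))
        fast = recover_off_rate(k0_fast, n_fast, seed=int(sub[2 * i + 1]))
        ratios.append(fast.k0_off / slow.k0_off)
    return float(np.mean(ratios))
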