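"""Physics-based synthetic AFM retraction curves and contact-trial outcomes.

A retraction experiment pulls the cantilever base away from the surface at
constant velocity v.  When a bond bridges tip and surface through the PEG
tethers, the tip-sample separation z(t) = v*t is shared between tether
extension and cantilever deflection, so the instantaneous force solves the
series-compliance balance

    z(t) = x_tether(F) + F / k_c .

Bond survival evolves under the Bell hazard k(F(t)); the rupture time is
drawn by integrating the hazard along the trajectory against a unit
exponential variate (time-transformation / thinning identity), after which
the force returns to baseline.  Gaussian force noise emulates the
photodiode/thermal noise floor.

Three curve classes are generated:

* ``specific``  -- the molecular complex bridges the two full-length PEG
  tethers; ruptures cluster at the two-tether contour length.
* ``nonspecific`` -- spurious short-tether adhesion (contour length drawn
  uniformly from a low range, weak exponential-tailed rupture forces);
  the contaminant population the contour-length filter must reject.
* ``empty``     -- no interaction; baseline noise only.

Default study conditions: six pulling velocities log-spaced over two
decades (100 - 10,000 nm/s), a soft k_c = 10 pN/nm cantilever, 5 pN force
noise, 20 kHz sampling, and a specific/nonspecific/empty mixture of
6%/2%/92% matching the working adhesion frequency of the binding-
probability experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError, SimulationError
from .physics import KineticParams, TetherModel, bell_off_rate

__all__ = [
    "SimulationConfig",
    "ForceCurve",
    "GroundTruth",
    "CURVE_CLASSES",
    "simulate_retract_curve",
    "simulate_experiment",
    "simulate_binding_outcomes",
    "kinetics_study_config",
]

CURVE_CLASSES = ("specific", "nonspecific", "empty")

#: default six pulling velocities, nm/s, log-spaced over two decades
DEFAULT_VELOCITIES = tuple(float(v) for v in np.geomspace(100.0, 10000.0, 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated experiment.

    ``fractions`` is (specific, nonspecific, empty) and must sum to 1.
    ``nonspecific_lc_range`` is the contour-length range (nm) of spurious
    short-tether adhesions. ``f_cap`` bounds the simulated force ramp.
    """

    kin: KineticParams = field(default_factory=lambda: KineticParams(k0_off=0.2, x_beta=0.3))
    tether: TetherModel = field(default_factory=TetherModel.peg_5k_pair)
    spring_constant: float = 10.0
    velocities: Sequence[float] = DEFAULT_VELOCITIES
    curves_per_velocity: int = 200
    fractions: tuple[float, float, float] = (0.06, 0.02, 0.92)
    noise_sd: float = 5.0
    sampling_rate: float = 20000.0
    nonspecific_lc_range: tuple[float, float] = (5.0, 40.0)
    seed: int = 0
    f_cap: float = 300.0
    nonspecific_force_scale: float = 12.0
    nonspecific_force_cap: float = 50.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise DomainError(f"fractions must be 3 non-negative values summing to 1, got {self.fractions}")
        if not all(v > 0 for v in self.velocities):
            raise DomainError("all pulling velocities must be positive")
        if self.noise_sd < 0 or self.sampling_rate <= 0 or self.spring_constant <= 0:
            raise DomainError("noise_sd >= 0, sampling_rate > 0, spring_constant > 0 required")
        lo, hi = self.nonspecific_lc_range
        if not (0 < lo < hi):
            raise DomainError(f"invalid nonspecific_lc_range {self.nonspecific_lc_range}")


@dataclass(eq=False)
class ForceCurve:
    """One retraction trace: force vs tip-sample distance with metadata."""

    curve_id: str
    time: np.ndarray  # s, strictly increasing
    tip_sample_distance: np.ndarray  # nm, = velocity * time on retraction
    force: np.ndarray  # pN, tensile positive
    pulling_velocity: float  # nm/s
    spring_constant: float  # pN/nm

    def __post_init__(self) -> None:
        n = len(self.time)
        if n < 2 or len(self.force) != n or len(self.tip_sample_distance) != n:
            raise DomainError("curve arrays must have equal length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")


@dataclass(frozen=True)
class GroundTruth:
    """Per-curve generator truth used to validate the analysis stages."""

    curve_id: str
    true_class: str
    true_rupture_force: Optional[float] = None  # pN, noiseless force at rupture
    true_rupture_index: Optional[int] = None
    true_lc: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        if self.true_class not in CURVE_CLASSES:
            raise DomainError(f"unknown curve class {self.true_class!r}")
        has_rupture = self.true_rupture_force is not None
        if (self.true_class == "empty") == has_rupture:
            raise DomainError("rupture fields must be present iff class != empty")


@lru_cache(maxsize=64)
def _distance_force_table(tether: TetherModel, k_c: float, f_cap: float, n_grid: int = 4096):
    """Monotone table z(F) = x_tether(F) + F/k_c for fast inversion F(z)."""
    from .physics import fjc_extension

    f = np.linspace(0.0, f_cap, n_grid)
    z = fjc_extension(f, tether) + f / k_c
    return z, f


def _force_of_distance(z: np.ndarray, tether: TetherModel, k_c: float, f_cap: float) -> np.ndarray:
    ztab, ftab = _distance_force_table(tether, k_c, f_cap)
    if np.any(~np.isfinite(ztab)):
        raise SimulationError("series-compliance table is not finite")
    return np.interp(z, ztab, ftab)


def _curve_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-split stream: per-curve reproducibility survives reordering."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_retract_curve(
    config: SimulationConfig,
    curve_class: str,
    rng: np.random.Generator,
    velocity: Optional[float] = None,
    curve_id: str = "curve",
) -> tuple[ForceCurve, GroundTruth]:
    """Simulate one retraction curve of the given class.

    The tethered classes solve the series system z = x_tether(F) + F/k_c
    at every sample (via a dense precomputed monotone table), integrate
    the Bell hazard along the force trajectory by the trapezoid rule, and
    rupture at the first sample where the integrated hazard exceeds a unit
    exponential variate. 30% of baseline-only trace is appended after the
    force ramp so detectors see the post-rupture baseline.
    """
    if curve_class not in CURVE_CLASSES:
        raise DomainError(f"unknown curve class {curve_class!r}")
    v = float(velocity if velocity is not None else config.velocities[0])
    k_c = config.spring_constant
    dt = 1.0 / config.sampling_rate

    if curve_class == "specific":
        tether, kin = config.tether, config.kin
        f_cap = config.f_cap
    elif curve_class == "nonspecific":
        lc = float(rng.uniform(*config.nonspecific_lc_range))
        tether = config.tether.with_contour_length(lc)
        kin = None
        f_cap = 1.2 * config.nonspecific_force_cap
    else:  # empty: trace as long as a specific curve at this velocity
        tether, kin = config.tether, config.kin
        f_cap = config.f_cap

    ztab, _ = _distance_force_table(tether, k_c, f_cap)
    z_max = float(ztab[-1])
    n_ramp = max(int(np.ceil(z_max / v / dt)), 32)
    n_total = int(np.ceil(1.3 * n_ramp))
    t = np.arange(n_total) * dt
    z = v * t

    truth: GroundTruth
    if curve_class == "empty":
        f_true = np.zeros(n_total)
        truth = GroundTruth(curve_id, "empty")
    else:
        f_true = np.zeros(n_total)
        ramp = _force_of_distance(z[:n_ramp], tether, k_c, f_cap)
        if curve_class == "specific":
            hazard = bell_off_rate(ramp, kin)
            cumulative = np.concatenate(
                ([0.0], np.cumsum(0.5 * (hazard[1:] + hazard[:-1]) * dt))
            )
            target = rng.exponential()
            cross = int(np.searchsorted(cumulative, target))
            if cross >= n_ramp:  # bond outlived the configured ramp (rare)
                cross = n_ramp - 1
            # rupture falls inside (t[cross-1], t[cross]]; the last loaded
            # sample is cross-1 and the true rupture force interpolates the
            # hazard-integral crossing
            if cross > 0:
                h0, h1 = cumulative[cross - 1], cumulative[cross]
                frac = (target - h0) / (h1 - h0) if h1 > h0 else 1.0
                frac = min(max(frac, 0.0), 1.0)
                f_rupture = float(ramp[cross - 1] + frac * (ramp[cross] - ramp[cross - 1]))
                idx = cross - 1
            else:
                f_rupture = float(ramp[0])
                idx = 0
        else:
            # truncated-exponential detachment force below the cap
            scale, cap = config.nonspecific_force_scale, config.nonspecific_force_cap
            u = rng.uniform()
            f_rup = -scale * np.log1p(-u * (1.0 - np.exp(-cap / scale)))
            above = np.nonzero(ramp >= f_rup)[0]
            idx = int(above[0]) if above.size else n_ramp - 1
        f_true[:idx + 1] = ramp[:idx + 1]
        if curve_class != "specific":
            f_rupture = float(ramp[idx])
        truth = GroundTruth(
            curve_id,
            curve_class,
            true_rupture_force=f_rupture,
            true_rupture_index=idx,
            true_lc=tether.contour_length,
        )

    force = f_true if config.noise_sd == 0 else f_true + rng.normal(0.0, config.noise_sd, n_total)
    curve = ForceCurve(
        curve_id=curve_id,
        time=t,
        tip_sample_distance=z,
        force=force,
        pulling_velocity=v,
        spring_constant=k_c,
    )
    return curve, truth


def simulate_experiment(config: SimulationConfig) -> tuple[list[ForceCurve], list[GroundTruth]]:
    """Simulate ``curves_per_velocity`` curves at each pulling velocity.

    Curve classes are drawn per curve from ``config.fractions``; each curve
    consumes its own counter-derived random stream, so the output is fully
    reproducible from ``config.seed`` and insensitive to reordering.
    """
    curves: list[ForceCurve] = []
    truths: list[GroundTruth] = []
    fractions = np.asarray(config.fractions, dtype=float)
    counter = 0
    for vi, v in enumerate(config.velocities):
        for ci in range(config.curves_per_velocity):
            rng = _curve_rng(config.seed, counter)
            cls = CURVE_CLASSES[int(rng.choice(3, p=fractions))]
            curve_id = f"v{vi:02d}_c{ci:05d}"
            curve, truth = simulate_retract_curve(config, cls, rng, velocity=v, curve_id=curve_id)
            curves.append(curve)
            truths.append(truth)
            counter += 1
    return curves, truths


def simulate_binding_outcomes(p: float, n: int, seed: int) -> np.ndarray:
    """n independent Bernoulli(p) contact-trial outcomes (1 = bond)."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"binding probability must lie in [0, 1], got {p}")
    if n < 1:
        raise DomainError(f"trial count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.binomial(1, p, size=int(n)).astype(np.int8)


def kinetics_study_config(
    kin: KineticParams,
    n_accepted_target: int,
    seed: int,
    analysis_min_force: float = 25.0,
    **overrides,
) -> SimulationConfig:
    """Conditions for a dynamic-force-spectroscopy study of a given bond.

    Kinetics datasets consist of curves that showed adhesion, so the class
    mixture is enriched to 75% specific / 5% nonspecific / 20% empty and
    the curve count is sized so that roughly ``n_accepted_target`` events
    survive the one-standard-deviation contour-length gate (~68% yield)
    and the ``analysis_min_force`` threshold (yield from the trajectory
    survival of the configured bond), split evenly over the velocities.
    """
    fractions = overrides.pop("fractions", (0.75, 0.05, 0.20))
    base = SimulationConfig(kin=kin, seed=seed, fractions=fractions, **overrides)

    from .physics import fjc_extension

    # fraction of specific ruptures above the analysis threshold
    f = np.linspace(0.0, base.f_cap, 800)
    compliance = np.gradient(fjc_extension(f, base.tether), f) + 1.0 / base.spring_constant
    hz = kin.k0_off * np.exp(np.minimum(f * kin.x_beta / kin.kBT, 700.0)) * compliance
    H = np.concatenate(([0.0], np.cumsum(0.5 * (hz[1:] + hz[:-1]) * np.diff(f))))
    Hm = np.interp(analysis_min_force, f, H)
    above = float(np.mean([np.exp(-Hm / v) for v in base.velocities]))

    per_velocity = int(np.ceil(
        n_accepted_target / (len(base.velocities) * fractions[0] * 0.68 * max(above, 0.05))
    ))
    return replace(base, curves_per_velocity=per_velocity)
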