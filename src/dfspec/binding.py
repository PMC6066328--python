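"""Adhesion-frequency (binding-probability) statistics.

Each tip-surface contact cycle either produces a detected unbinding event
or not; the binding probability p is the event fraction over n trials.
Standard errors are bootstrap-with-replacement. Nonspecific baselines
average two control measurements (functionalized tip vs bare surface, and
bare tip vs functionalized surface). The Poisson single-bond fraction is
the classic adhesion-frequency argument: if the number of bonds per
contact is Poisson with mean lambda = -ln(1-p), the probability that a
detected event involves exactly one bond is

    P(1 | >=1) = lambda * e^{-lambda} / (1 - e^{-lambda}) = lambda*(1-p)/p,

which exceeds 97% for p below ~5.5% -- the rationale for running
force-spectroscopy experiments at a few percent adhesion frequency.

All stochastic routines take an explicit seed; there is no hidden global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DomainError

__all__ = [
    "BindingResult",
    "BaselineResult",
    "ComparisonResult",
    "binding_probability",
    "nonspecific_baseline",
    "compare_binding",
    "poisson_single_bond_fraction",
]


@dataclass(frozen=True)
class BindingResult:
    """Binding-probability estimate with bootstrap standard error."""

    n_trials: int
    n_events: int
    p: float  # fraction in [0, 1]
    se: float  # bootstrap s.e., fraction
    B: int
    seed: int
    zero_events: bool = False  # p_hat = 0: bootstrap degenerates; consider a
    # rule-of-three upper bound ~ 3/n instead


@dataclass(frozen=True)
class BaselineResult:
    """Averaged nonspecific baseline from the two control measurements."""

    p_ns: float
    se_ns: float
    components: tuple[BindingResult, BindingResult]


@dataclass(frozen=True)
class ComparisonResult:
    """Specific-vs-nonspecific comparison (formal test; an extension of the
    qualitative comparison usually drawn from the bar plots)."""

    difference: float
    ci95: tuple[float, float]
    z: float
    verdict: str  # "specific" iff the 95% CI excludes 0


def _bootstrap_p_reps(n: int, p_hat: float, B: int, rng: np.random.Generator) -> np.ndarray:
    # Resampling n binary outcomes with replacement gives an event count
    # distributed exactly Binomial(n, p_hat); drawn directly for speed.
    return rng.binomial(n, p_hat, size=B) / n


def binding_probability(outcomes, *, B: int = 1000, seed: int) -> BindingResult:
    """Estimate p and its bootstrap standard error from 0/1 outcomes."""
    arr = np.asarray(outcomes)
    if arr.size < 1:
        raise DomainError("outcomes must contain at least one trial")
    if not np.isin(arr, (0, 1)).all():
        raise DomainError("outcomes must be binary (0 = no bond, 1 = bond)")
    if B < 2:
        raise DomainError(f"bootstrap replicate count must be >= 2, got {B}")
    n = int(arr.size)
    events = int(arr.sum())
    p_hat = events / n
    rng = np.random.default_rng(seed)
    reps = _bootstrap_p_reps(n, p_hat, B, rng)
    se = float(np.std(reps, ddof=1))
    return BindingResult(n, events, p_hat, se, B, seed, zero_events=(events == 0))


def nonspecific_baseline(
    control_tip_only, control_surface_only, *, B: int = 1000, seed: int
) -> BaselineResult:
    """Average the two control binding probabilities.

    p_ns = (p1 + p2)/2 with s.e. propagated as sqrt(se1^2 + se2^2)/2.
    """
    seq = np.random.SeedSequence(seed).spawn(2)
    r1 = binding_probability(control_tip_only, B=B, seed=int(seq[0].generate_state(1)[0] % 2**31))
    r2 = binding_probability(control_surface_only, B=B, seed=int(seq[1].generate_state(1)[0] % 2**31))
    p_ns = 0.5 * (r1.p + r2.p)
    se_ns = 0.5 * math.hypot(r1.se, r2.se)
    return BaselineResult(p_ns, se_ns, (r1, r2))


def compare_binding(
    specific: BindingResult,
    baseline: BaselineResult,
    *,
    B: int = 1000,
    seed: Optional[int] = None,
) -> ComparisonResult:
    """Difference p - p_ns with a combined-bootstrap 95% CI and z statistic.

    Bootstrap replicates of the specific estimate and of both baseline
    components are combined into difference replicates; the CI is their
    2.5/97.5 percentile interval. Verdict "specific" iff the CI excludes 0.
    """
    rng = np.random.default_rng(specific.seed if seed is None else seed)
    sp = _bootstrap_p_reps(specific.n_trials, specific.p, B, rng)
    c1, c2 = baseline.components
    b1 = _bootstrap_p_reps(c1.n_trials, c1.p, B, rng)
    b2 = _bootstrap_p_reps(c2.n_trials, c2.p, B, rng)
    diff_reps = sp - 0.5 * (b1 + b2)
    ci = tuple(float(q) for q in np.percentile(diff_reps, [2.5, 97.5]))
    difference = specific.p - baseline.p_ns
    pooled = math.hypot(specific.se, baseline.se_ns)
    z = difference / pooled if pooled > 0 else math.inf * np.sign(difference) if difference else 0.0
    verdict = "specific" if (ci[0] > 0 or ci[1] < 0) else "nonspecific"
    return ComparisonResult(difference, ci, float(z), verdict)


def poisson_single_bond_fraction(p: float) -> float:
    """Fraction of detected events that involve exactly one bond.

    Requires 0 < p < 1; strictly decreasing in p and -> 1 as p -> 0.
    """
    if not 0.0 < p < 1.0:
        raise DomainError(f"binding probability must lie strictly in (0, 1), got {p}")
    lam = -math.log1p(-p)
    return lam * math.exp(-lam) / -math.expm1(-lam)
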