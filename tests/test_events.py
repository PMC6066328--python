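"""Rupture detection, tether TLS fitting, Lc gating, loading rates."""

import numpy as np
import pytest

from dfspec import (
    DetectionParams,
    ForceCurve,
    KineticParams,
    SimulationConfig,
    TetherModel,
    detect_candidate_event,
    estimate_loading_rate,
    filter_by_contour_length,
    fit_tether_tls,
    simulate_retract_curve,
)
from dfspec.events import RuptureEvent, lc_within_band
from dfspec.exceptions import DomainError, EstimationError, FitError
from dfspec.physics import fjc_extension

from conftest import make_curve


def ramp_curve(slope_pn_per_s=5000.0, n=400, dt=5e-5, rupture_at=-1):
    """A synthetic linear force ramp (not FJC-shaped) for estimator tests."""
    t = np.arange(n) * dt
    f = slope_pn_per_s * t
    if rupture_at != -1:
        f[rupture_at + 1:] = 0.0
    return ForceCurve(
        curve_id="ramp", time=t, tip_sample_distance=1000.0 * t, force=f,
        pulling_velocity=1000.0, spring_constant=10.0,
    )


class TestDetection:
    def test_flat_curve_yields_none(self, kin, detection):
        curve, _ = make_curve(kin, "empty", noise_sd=0.0)
        assert detect_candidate_event(curve, detection) is None

    def test_noiseless_specific_detected_exactly(self, kin, detection):
        curve, truth = make_curve(kin, "specific", noise_sd=0.0, seed=3)
        event = detect_candidate_event(curve, detection)
        assert event is not None
        assert abs(event.rupture_index - truth.true_rupture_index) <= 2

    def test_noisy_detection_accuracy(self, kin, detection):
        hits = 0
        for seed in range(25):
            curve, truth = make_curve(kin, "specific", velocity=1000.0,
                                      noise_sd=5.0, seed=100 + seed)
            if truth.true_rupture_force < 30.0:
                continue
            event = detect_candidate_event(curve, detection)
            assert event is not None
            assert abs(event.rupture_index - truth.true_rupture_index) <= 2
            assert abs(event.rupture_force - truth.true_rupture_force) <= 3 * 5.0
            hits += 1
        assert hits >= 15

    def test_below_threshold_rejected(self, detection):
        # clean ramp rupturing at 8 pN, below the 15 pN threshold
        curve = ramp_curve(slope_pn_per_s=800.0, n=400, rupture_at=200)
        assert curve.force.max() < detection.min_force
        assert detect_candidate_event(curve, detection) is None

    def test_adaptive_threshold_from_noise(self, kin):
        det = DetectionParams(min_force=None, noise_mult=5.0)
        curve, truth = make_curve(kin, "specific", noise_sd=5.0, seed=7)
        if truth.true_rupture_force > 40:
            event = detect_candidate_event(curve, det)
            assert event is not None

    def test_min_points_invariant(self):
        with pytest.raises(DomainError):
            DetectionParams(min_points=4)


class TestTetherTls:
    def test_noiseless_recovery_within_0p1_percent(self, kin, tether, detection):
        curve, truth = make_curve(kin, "specific", velocity=1000.0, noise_sd=0.0, seed=4)
        event = detect_candidate_event(curve, detection)
        lc, resid = fit_tether_tls(curve, event, tether, detection)
        assert lc == pytest.approx(truth.true_lc, rel=1e-3)
        assert resid < 0.5

    def test_noisy_recovery_median_within_2_percent(self, kin, tether, detection):
        errs = []
        rng_seeds = range(200, 320)
        for seed in rng_seeds:
            curve, truth = make_curve(kin, "specific", velocity=1000.0,
                                      noise_sd=5.0, seed=seed)
            event = detect_candidate_event(curve, detection)
            if event is None or truth.true_rupture_force < 30:
                continue
            lc, _ = fit_tether_tls(curve, event, tether, detection)
            errs.append(abs(lc - truth.true_lc) / truth.true_lc)
            if len(errs) == 100:
                break
        assert len(errs) >= 60
        assert np.median(errs) < 0.02

    def test_short_segment_raises(self, tether, detection):
        curve = ramp_curve(n=40, rupture_at=20)
        event = RuptureEvent("ramp", rupture_force=float(curve.force[20]),
                            rupture_index=4)
        with pytest.raises(FitError, match="samples"):
            fit_tether_tls(curve, event, tether, detection)

    def test_force_capped_fit_matches_full_fit_noiseless(self, kin, tether, detection):
        curve, truth = make_curve(kin, "specific", velocity=1000.0, noise_sd=0.0, seed=6)
        event = detect_candidate_event(curve, detection)
        lc_full, _ = fit_tether_tls(curve, event, tether, detection)
        lc_cap, _ = fit_tether_tls(curve, event, tether, detection, f_fit_cap=25.0)
        assert lc_cap == pytest.approx(lc_full, rel=5e-3)
        assert lc_cap == pytest.approx(truth.true_lc, rel=5e-3)


class TestLcFilter:
    def test_gaussian_plus_uniform_mixture(self):
        rng = np.random.default_rng(5)
        events = [RuptureEvent(f"g{i}", 50.0, 0, contour_length=float(l))
                  for i, l in enumerate(rng.normal(80.0, 3.0, 300))]
        events += [RuptureEvent(f"u{i}", 20.0, 0, contour_length=float(l))
                   for i, l in enumerate(rng.uniform(5.0, 40.0, 40))]
        result = filter_by_contour_length(events)
        assert result.mu == pytest.approx(80.0, abs=1.0)
        accepted = [e for e in events if e.accepted]
        frac_gaussian = np.mean([e.curve_id.startswith("g") for e in accepted])
        assert frac_gaussian >= 0.90

    def test_identical_lcs_degenerate(self):
        events = [RuptureEvent(f"e{i}", 50.0, 0, contour_length=80.0) for i in range(20)]
        result = filter_by_contour_length(events)
        assert result.sigma == 0.0
        assert result.degenerate
        assert all(e.accepted for e in events)

    def test_fewer_than_ten_events_flagged(self):
        events = [RuptureEvent(f"e{i}", 50.0, 0, contour_length=80.0 + i) for i in range(5)]
        result = filter_by_contour_length(events)
        assert result.degenerate

    def test_acceptance_band_boundary_inclusive(self):
        assert lc_within_band(80.0 + 0.99 * 3.0, 80.0, 3.0)
        assert lc_within_band(80.0 + 1.00 * 3.0, 80.0, 3.0)
        assert not lc_within_band(80.0 + 1.01 * 3.0, 80.0, 3.0)


class TestLoadingRate:
    def test_exact_linear_ramp(self):
        curve = ramp_curve(slope_pn_per_s=5000.0, n=400, rupture_at=350)
        event = RuptureEvent("ramp", rupture_force=float(curve.force[350]),
                            rupture_index=350)
        rate = estimate_loading_rate(curve, event)
        assert rate.value == pytest.approx(5000.0, rel=1e-9)

    def test_matches_instantaneous_chain_rule(self, kin, tether, detection):
        """Noiseless curve: OLS slope over the final window approximates
        v/(1/k_c + dx/dF) at the rupture force."""
        curve, truth = make_curve(kin, "specific", velocity=100.0, noise_sd=0.0, seed=9)
        event = detect_candidate_event(curve, detection)
        rate = estimate_loading_rate(curve, event, det=detection)
        h = 1e-4
        dxdf = (fjc_extension(truth.true_rupture_force + h, tether)
                - fjc_extension(truth.true_rupture_force - h, tether)) / (2 * h)
        expected = 100.0 / (1.0 / curve.spring_constant + dxdf)
        assert rate.value == pytest.approx(expected, rel=0.05)

    def test_too_few_samples_raises(self):
        t = np.arange(4) * 1e-4
        curve = ForceCurve("tiny", t, 1000 * t, np.array([0.0, 10.0, 20.0, 0.0]),
                           1000.0, 10.0)
        event = RuptureEvent("tiny", rupture_force=10.0, rupture_index=1)
        with pytest.raises(EstimationError):
            estimate_loading_rate(curve, event, min_samples=10)

    def test_nonpositive_slope_raises(self):
        n = 60
        t = np.arange(n) * 1e-4
        f = np.concatenate((np.linspace(0, 40, n - 30), np.linspace(40, 38, 30)))
        curve = ForceCurve("dec", t, 1000 * t, f, 1000.0, 10.0)
        event = RuptureEvent("dec", rupture_force=38.0, rupture_index=n - 1)
        with pytest.raises(EstimationError):
            estimate_loading_rate(curve, event, window=0.999, min_samples=25)


class TestEndToEndExtraction:
    def test_noiseless_specifics_yield_one_event_empties_none(self, kin, detection, tether):
        from dfspec.pipeline import extract_events

        cfg = SimulationConfig(kin=kin, fractions=(0.5, 0.0, 0.5),
                               curves_per_velocity=6, noise_sd=0.0, seed=21)
        from dfspec import simulate_experiment

        curves, truths = simulate_experiment(cfg)
        events, counts = extract_events(curves, detection, tether)
        ids = {e.curve_id for e in events}
        for curve, truth in zip(curves, truths):
            if truth.true_class == "empty":
                assert curve.curve_id not in ids
            elif truth.true_class == "specific" and truth.true_rupture_force > 20:
                assert curve.curve_id in ids
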