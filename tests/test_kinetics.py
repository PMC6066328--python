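"""Loading-rate clustering and robust Bell-Evans inference."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from dfspec import (
    KineticParams,
    TetherModel,
    bootstrap_bell_evans,
    cluster_loading_rates,
    compute_cluster_stats,
    fit_bell_evans,
    rupture_force_pdf,
    sample_rupture_force,
)
from dfspec.events import RuptureEvent
from dfspec.exceptions import DomainError, FitError
from dfspec.kinetics import (
    bell_mean_force,
    censored_force_moments_trajectory,
    fit_bell_evans_censored,
)

from conftest import make_stage_events


def events_from_rates(rates, forces=None):
    forces = forces if forces is not None else [50.0] * len(rates)
    return [
        RuptureEvent(f"e{i}", float(f), 0, contour_length=80.0,
                     loading_rate=float(r), accepted=True)
        for i, (r, f) in enumerate(zip(rates, forces))
    ]


def wcss_1d(values, labels, k):
    total = 0.0
    for j in range(k):
        member = values[labels == j]
        total += float(np.sum((member - member.mean()) ** 2))
    return total


def brute_force_optimal_wcss(values, k):
    """Exhaustive enumeration of contiguous 1-D partitions (the optimum
    of 1-D k-means is contiguous in sorted order)."""
    x = np.sort(values)
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = sum(
            float(np.sum((x[a:b] - x[a:b].mean()) ** 2)) for a, b in zip(bounds, bounds[1:])
        )
        best = min(best, total)
    return best


class TestClustering:
    def test_two_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(0)
        r1 = 10 ** rng.normal(2.5, 0.15, 80)
        r2 = 10 ** rng.normal(4.0, 0.15, 80)
        events = events_from_rates(np.concatenate((r1, r2)))
        clusters = cluster_loading_rates(events, k=2, seed=1)
        labels = clusters.labels
        # adjusted Rand index 1 <=> partition identical to ground truth
        assert len(set(labels[:80])) == 1 and len(set(labels[80:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equal_one(self):
        events = events_from_rates([100.0, 300.0, 900.0])
        clusters = cluster_loading_rates(events, k=1, seed=0)
        assert np.all(clusters.labels == 0)

    @pytest.mark.parametrize("n,k", [(8, 2), (12, 3), (10, 3)])
    def test_matches_brute_force_optimum(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        rates = 10 ** rng.uniform(2.0, 4.5, n)
        events = events_from_rates(rates)
        clusters = cluster_loading_rates(events, k=k, seed=3)
        got = wcss_1d(np.log10(rates), clusters.labels, k)
        best = brute_force_optimal_wcss(np.log10(rates), k)
        assert got == pytest.approx(best, rel=1e-9, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        events = events_from_rates([100.0, 200.0])
        with pytest.raises(DomainError):
            cluster_loading_rates(events, k=3, seed=0)

    def test_invalid_scale_rejected(self):
        events = events_from_rates([100.0, 200.0, 400.0])
        with pytest.raises(DomainError):
            cluster_loading_rates(events, k=2, seed=0, scale="sqrt")


class TestClusterStats:
    def test_singleton_cluster(self):
        events = events_from_rates([100.0], forces=[42.0])
        clusters = cluster_loading_rates(events, k=1, seed=0)
        stats = compute_cluster_stats(clusters)
        assert stats[0][0] == 42.0
        assert stats[0][2] == 0.0
        assert stats[0][3] == 1

    def test_two_point_arithmetic(self):
        events = events_from_rates([100.0, 100.0], forces=[40.0, 60.0])
        clusters = cluster_loading_rates(events, k=1, seed=0)
        (mean_f, mean_r, sd, n), = compute_cluster_stats(clusters)
        assert mean_f == pytest.approx(50.0)
        assert sd == pytest.approx(14.142135, abs=1e-5)
        assert n == 2

    def test_large_cluster_mean_matches_density_integral(self, kin):
        r_f = 2000.0
        rng = np.random.default_rng(12)
        forces = sample_rupture_force(r_f, kin, rng.uniform(1e-12, 1, 20000))
        events = events_from_rates([r_f] * len(forces), forces=forces)
        clusters = cluster_loading_rates(events, k=1, seed=0)
        (mean_f, _, sd, n), = compute_cluster_stats(clusters)
        analytic, _ = quad(lambda f: f * rupture_force_pdf(f, r_f, kin), 0, np.inf, limit=200)
        assert mean_f == pytest.approx(analytic, abs=3 * sd / np.sqrt(n))


class TestFitBellEvans:
    def test_noiseless_modal_points_recovered_exactly(self):
        kin = KineticParams(1.26, 0.25)
        rates = np.geomspace(200.0, 50000.0, 6)
        from dfspec import most_probable_force

        points = [(most_probable_force(r, kin), r) for r in rates]
        fit = fit_bell_evans(points, kBT=kin.kBT, formula="most_probable")
        assert fit.converged
        assert fit.k0_off == pytest.approx(1.26, rel=1e-6)
        assert fit.x_beta == pytest.approx(0.25, rel=1e-6)

    def test_noiseless_mean_points_recovered_exactly(self):
        kin = KineticParams(0.8, 0.35)
        rates = np.geomspace(200.0, 50000.0, 6)
        points = [(float(bell_mean_force(r, kin.k0_off, kin.x_beta, kin.kBT)), r)
                  for r in rates]
        fit = fit_bell_evans(points, kBT=kin.kBT, formula="mean")
        assert fit.k0_off == pytest.approx(0.8, rel=1e-5)
        assert fit.x_beta == pytest.approx(0.35, rel=1e-5)

    def test_bisquare_resists_gross_outlier(self):
        kin = KineticParams(1.26, 0.25)
        rates = np.geomspace(200.0, 50000.0, 8)
        from dfspec import most_probable_force

        points = [(most_probable_force(r, kin), r) for r in rates]
        points[3] = (points[3][0] * 3.0, points[3][1])  # gross outlier
        robust = fit_bell_evans(points, kBT=kin.kBT)
        assert robust.k0_off == pytest.approx(1.26, rel=0.05)
        assert robust.x_beta == pytest.approx(0.25, rel=0.05)
        # unweighted OLS on the same points deviates more
        x = np.log([p[1] for p in points])
        y = [p[0] for p in points]
        b, a = np.polyfit(x, y, 1)
        k0_ols = np.exp(-a / b) / b
        assert abs(k0_ols - 1.26) > abs(robust.k0_off - 1.26)

    def test_single_point_rejected(self):
        with pytest.raises(FitError):
            fit_bell_evans([(50.0, 1000.0)])

    def test_identical_rates_rejected(self):
        with pytest.raises(FitError):
            fit_bell_evans([(50.0, 1000.0), (60.0, 1000.0)])

    def test_matches_statsmodels_rlm_on_noisy_line(self):
        """Independent cross-check of the hand-written bisquare IRLS
        against statsmodels RLM with a Tukey biweight norm."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        rates = np.geomspace(100.0, 1e5, 12)
        x = np.log(rates)
        y = 12.0 + 10.0 * x + rng.normal(0, 2.0, 12)
        fit = fit_bell_evans(list(zip(y, rates)), kBT=4.114)
        rlm = sm.RLM(y, np.column_stack((np.ones_like(x), x)),
                     M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(scale_est="mad")
        a, b = rlm.params
        assert fit.x_beta == pytest.approx(4.114 / b, rel=2e-2)
        assert fit.k0_off == pytest.approx(np.exp(-a / b) / b, rel=0.1)


class TestTrajectoryModel:
    def test_self_consistency_exact(self, tether):
        vels = np.geomspace(100.0, 10000.0, 6)
        mu, sd = censored_force_moments_trajectory(vels, 1.26, 0.3, tether, 10.0,
                                                   f_min=25.0, meas_noise_sd=5.0)
        pts = [(float(m), 3.0 * v, float(v), 100, float(s))
               for m, s, v in zip(mu, sd, vels)]
        fit = fit_bell_evans_censored(pts, tether, 10.0, f_min=25.0, meas_noise_sd=5.0)
        assert fit.k0_off == pytest.approx(1.26, rel=1e-4)
        assert fit.x_beta == pytest.approx(0.3, rel=1e-4)

    def test_uncensored_limit_matches_mean_formula_at_high_force(self, tether):
        # at high forces the tether is stiff, the loading rate nearly
        # constant, and the trajectory mean approaches the constant-rate mean
        kin = KineticParams(1e-3, 0.3)
        v = 1000.0
        mu = censored_force_moments_trajectory(v, kin.k0_off, kin.x_beta, tether,
                                               10.0, f_min=0.0)[0]
        # constant-rate mean at the effective rate near the mode
        from dfspec.physics import fjc_extension

        h = 1e-4
        dxdf = (fjc_extension(mu + h, tether) - fjc_extension(mu - h, tether)) / (2 * h)
        r_eff = v / (0.1 + dxdf)
        const_rate = float(bell_mean_force(r_eff, kin.k0_off, kin.x_beta, kin.kBT))
        assert mu == pytest.approx(const_rate, rel=0.02)


class TestBootstrap:
    def test_b_equal_one_degenerate(self, kin):
        rng = np.random.default_rng(1)
        events = make_stage_events(kin, rng, rates_per_group=20)
        fit = bootstrap_bell_evans(events, k=6, B=1, seed=0, formula="mean")
        assert fit.degenerate_ci
        assert fit.ci95_k0_off == (fit.k0_off, fit.k0_off)

    def test_same_seed_identical_cis(self, kin):
        rng = np.random.default_rng(2)
        events = make_stage_events(kin, rng, rates_per_group=25)
        f1 = bootstrap_bell_evans(events, k=6, B=50, seed=7, formula="mean")
        f2 = bootstrap_bell_evans(events, k=6, B=50, seed=7, formula="mean")
        assert f1.ci95_k0_off == f2.ci95_k0_off
        assert f1.ci95_x_beta == f2.ci95_x_beta

    def test_ci_ordering_and_point_containment(self, kin):
        rng = np.random.default_rng(3)
        events = make_stage_events(kin, rng, rates_per_group=40)
        fit = bootstrap_bell_evans(events, k=6, B=100, seed=5, formula="mean")
        lo, hi = fit.ci95_k0_off
        assert lo <= hi
        assert lo <= fit.k0_off * 1.5 and hi >= fit.k0_off * 0.5

    def test_recluster_mode_runs(self, kin):
        rng = np.random.default_rng(4)
        events = make_stage_events(kin, rng, rates_per_group=20)
        fit = bootstrap_bell_evans(events, k=3, B=20, seed=1, formula="mean",
                                   mode="recluster")
        assert fit.n_bootstrap == 20

    def test_event_order_invariance(self, kin):
        rng = np.random.default_rng(6)
        events = make_stage_events(kin, rng, rates_per_group=20)
        fit1 = bootstrap_bell_evans(events, k=6, B=1, seed=0, formula="mean")
        shuffled = list(events)
        np.random.default_rng(0).shuffle(shuffled)
        fit2 = bootstrap_bell_evans(shuffled, k=6, B=1, seed=0, formula="mean")
        assert fit1.k0_off == pytest.approx(fit2.k0_off, rel=1e-6)
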